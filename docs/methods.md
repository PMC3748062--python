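# Methods

## Model and assumptions

All computations operate on the allelic 2×2 contingency table (cases
*a, b*; controls *c, d*; column 1 = tested allele), with the Pearson χ²
statistic on 1 degree of freedom,

    χ² = N(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)],    N = a+b+c+d,

and the two-sided allelic p-value from its upper tail. No continuity
(Yates) or zero-cell (Haldane–Anscombe) correction is applied anywhere:
the closed-form identities below hold for the uncorrected statistic, and a
correction would silently break them. Zero cells raise errors instead.

The heterogeneity model assumes that cases outside the associated
subgroup — whether conceived as phenocopies, distinct subtypes, or members
of other genetic subclasses — carry **control** allele frequencies at the
locus. All three corrections follow from that single assumption:

* **OR error factor** (a₁/a)/(b₁/b): exact ratio of the subclass OR to the
  pooled OR; in frequency form odds(q)/odds(p), independent of subclass
  size. Values below 1 are legal and meaningful (protective direction);
  nothing is clamped.
* **Phenocopy reclassification** removes σ(a+b) case alleles at the control
  frequencies c/(c+d), d/(c+d) and adds them to the control row. Column
  margins and the grand total are conserved exactly, and the χ² ratio has
  the closed form [(c+d)+σ(a+b)] / [(1−σ)(c+d)] — the new controls:cases
  ratio normalised by the original one — reducing to (1+σ)/(1−σ) at equal
  group sizes.
* **Subgroup stripping** performs the same case-row removal but leaves
  controls untouched. This preserves the determinant ad−bc exactly. The
  sample-size multiplier is computed as γ = χ²(stripped)/χ²(original)
  rather than by transcribing expanded algebra: because χ² is homogeneous
  of degree 1 under uniform scaling of all four cells, γ is exactly the
  factor by which the original cohort must be scaled to match the
  subgroup's statistic. γ is strictly increasing in σ and diverges as the
  binding stripped cell approaches zero; the feasible supremum is
  σ* = min(a(c+d)/[(a+b)c], b(c+d)/[(a+b)d], 1).

Counts are real-valued throughout: the σ-transforms generically produce
fractional cells, and the closed forms are evaluated without rounding.
Display-mode rounding (half-away-from-zero on the allele-1 count, with
allele 2 as the complement) exists only for emitting integer-count scan
tables.

## Two parameterisations of "the subgroup"

σ always denotes the proportion of cases removed: phenocopies in the
reclassification scenario, non-subgroup cases in the stripping scenario —
numerically the same removal, differing only in whether the removed alleles
are added to controls. The σ-model *assumes* the removed cases sit at
control frequencies; `gamma_explicit_subclass` instead takes literal
subclass counts (a₁, b₁) and returns χ²(a₁,b₁,c,d)/χ²(a,b,c,d). The two
generally disagree (for the worked 1000/1000 cohort with a 200-case
subclass at MAF 0.5: σ-form γ ≈ 8.2 versus literal-subclass ≈ 16), because
the observed subclass row need not equal the control-frequency residue.
Both entry points are public; which is appropriate depends on whether the
analyst trusts the subclass counts or only the heterogeneity proportion.

A carriage-rate pair (e.g. 60% of cases vs 30% of controls carrying an
allele) can be treated as a 2×2 table per equal n through
`gamma_equal_n`; this substitutes carrier proportions for allele
frequencies and is an approximation, retained as a named entry point
because stratified-cohort examples are routinely quoted this way.

## Heterogeneity scans

`het_scan` fixes a control MAF p and a subgroup-case MAF q and blends the
pooled case MAF linearly, (1−h)q + hp, as the heterogeneity fraction h
grows. The scan's OR is reported as (control_a1·case_a2)/(control_a2·case_a1)
— controls as the "exposed" row — so a protective-direction tested allele
(q < p) still prints OR > 1; χ² and p are orientation-invariant. In exact
mode the h = 1 row is an exact null (OR 1, χ² 0); in display mode rounding
leaves it within one count of the null.

## Simulator

`CohortModel` draws two independent Bernoulli alleles per individual
(Hardy–Weinberg equilibrium, a single locus, no linkage disequilibrium, no
genotype-level penetrance), so group allele-1 counts are binomial. A
fraction π of cases forms the subgroup at frequency q; the rest sit at
`p_nonsubgroup` (default: the control frequency). The preset
`masked_subgroup_model` uses 1000 cases/1000 controls, π = 0.2, q = 0.5,
controls at 0.325 and non-subgroup cases at 0.3125, making the expected
pooled case MAF exactly 0.35 — a cohort whose pooled expected OR (≈1.12)
sits far below genome-wide detectability while the subclass alone tests at
p ≈ 10⁻¹¹. Default replicate counts are 10⁴ (Monte-Carlo SE on the pooled
OR ≈ 0.001); tests use 10³–10⁴. The generator's RNG is NumPy's default
(PCG64) seeded explicitly; a fixed seed reproduces cohorts bit-for-bit.

What passing simulation checks shows — and what it does not: the generator
matches the arithmetic the closed forms assume (binomial allele counts,
independent groups). Real cohorts add linkage disequilibrium, genotyping
error, population stratification, covariates and non-binary subgroup
membership, none of which are modelled; agreement here validates the
algebra, not robustness to those features.

## Numerical choices

* χ² is computed in the margin form N(ad−bc)²/…, which is exact for the
  scaling and determinant identities; the cell-wise Σ(obs−exp)²/exp form
  agrees to ≤1e-9 relative and is used only as a test oracle (alongside
  scipy's independent implementation).
* Infeasible σ (a transform driving a cell negative) raises
  `InfeasibleSigmaError` rather than truncating; batch mode converts this
  to NA + reason per row, scalar CLI mode to exit code 2.
* `gamma_equal_n` enforces a+b = c+d to 1e-9 relative; γ at σ = 0 is
  exactly 1 by construction.
* Curve grids stop strictly below the feasible σ supremum.

## Known limitations

Allele-level (1 df) tests only: no genotype tables, trend tests, logistic
regression or covariate adjustment. σ, subclass counts and subgroup MAFs
are *inputs* — the package quantifies consequences of assumed
heterogeneity, it does not estimate heterogeneity from data. Reclassifying
phenocopies as controls assumes the moved cases carry no disease
predisposition at the locus, which is optimistic for correctly diagnosed
patients; the no-reclassification γ is the conservative alternative.
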
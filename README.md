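# casehet

Closed-form corrections for how genetic subgroups and phenocopies attenuate
case-control allelic association statistics — for statistical geneticists
and epidemiologists who suspect that a weak GWAS signal is a strong signal
diluted by disease heterogeneity.

## The problem

Complex diseases are often syndromes: a SNP may confer risk only within a
genetic subclass of cases, while the remaining cases carry control-like
allele frequencies at that locus. Pooling all cases then regresses the case
allele frequency toward the population's, and the observed odds ratio and
χ² understate — sometimes drastically — the association present in the
subclass. `casehet` quantifies that attenuation exactly from the 2×2
allelic table (cases *a, b*; controls *c, d*; column 1 = tested allele).

Three closed forms:

1. **OR error factor.** If a subclass of cases has allele counts
   (*a₁*, *b₁*), its true OR against controls exceeds the pooled OR by

   OR_sub / OR_all = (a₁/a) / (b₁/b) = odds(q) / odds(p),

   where *p* is the pooled case MAF and *q* the subclass MAF — independent
   of subclass size.

2. **Phenocopy χ² ratio.** Reclassifying a proportion σ of cases as
   controls (moved at control allele frequencies) multiplies the χ²
   statistic by

   χ²ₙ / χ² = [(c+d) + σ(a+b)] / [(1−σ)(c+d)],

   which is (1+σ)/(1−σ) for equal numbers of cases and controls.

3. **Sample-size multiplier γ.** Without any reclassification, matching the
   χ² carried by the subgroup alone requires the whole cohort to grow by

   γ(σ) = χ²(subgroup table) / χ²(full table),

   exact because the Pearson statistic scales linearly under uniform count
   scaling; γ(0)=1, γ is strictly increasing in σ and diverges as the
   feasibility limit is approached.

A seeded Monte-Carlo cohort simulator validates the closed forms in
expectation and estimates empirical power of the pooled versus
subgroup-only test; heterogeneity scans, batch TSV processing and plotting
round out the toolkit.

## Worked example

A cohort of 1000 cases and 1000 controls shows a weak association (case MAF
0.35, control MAF 0.325) that is actually driven by a 200-case subclass at
MAF 0.5:

```python
import casehet as ch

table = ch.AlleleTable(700, 1300, 650, 1350)
rep = ch.subclass_workflow(table, ch.SubclassCounts(200, 200), sigma=0.8)
print(f"pooled   OR {rep.original.odds_ratio:.2f}  p {rep.original.p_value:.3g}")
print(f"subclass OR {rep.subclass.odds_ratio:.2f}  p {rep.subclass.p_value:.2g}")
print(f"error factor {rep.error_factor:.2f}   gamma {rep.gamma:.2f}")
```

prints

```
pooled   OR 1.12  p 0.0945
subclass OR 2.08  p 2.4e-11
error factor 1.86   gamma 8.24
```

The pooled test misses even single-SNP significance while the subclass
alone is genome-wide significant (OR understated 1.86-fold); to recover the
subgroup's χ² without stratifying, the cohort would have to grow 8.24-fold
(to roughly 8240 cases and 8240 controls). The `examples/` directory has
one short script per capability (error factor, phenocopy ratio, γ curves,
heterogeneity scans, simulation/power, batch processing), each printing and
explaining its numbers.

## Command line

```bash
casehet stats     --a 700 --b 1300 --c 650 --d 1350
casehet gamma     --a 700 --b 1300 --c 650 --d 1350 --sigma 0.8
casehet phenocopy --input snps.tsv --sigma 0.2 --out out.tsv
casehet het-scan  --q-subgroup 0.30 --p-control 0.38
casehet simulate  --preset masked-subgroup --replicates 10000
```

Batch input is a TSV with columns `snp_id, case_a1, case_a2, control_a1,
control_a2` (optional `sigma`, `sub_a1`, `sub_b1`); infeasible rows get NA
plus a reason instead of aborting.

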
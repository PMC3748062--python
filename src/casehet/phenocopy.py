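"""Phenocopy reclassification and the chi-square error ratio.

Model: a proportion ``sigma`` of cases are phenocopies — individuals whose
disease has a non-genetic cause or belongs to a distinct subtype — and so
carry control-like allele frequencies at the locus.  Reclassifying them as
controls removes ``sigma*(a+b)`` case alleles *at the control allele
frequencies* and adds them to the control row:

    a_n = a - sigma*(a+b)*c/(c+d)      c_n = c + sigma*(a+b)*c/(c+d)
    b_n = b - sigma*(a+b)*d/(c+d)      d_n = d + sigma*(a+b)*d/(c+d)

Column margins and the grand total are preserved, and the chi-square of the
adjusted table relates to the original by the closed form

    chi2_new / chi2 = [(c+d) + sigma*(a+b)] / [(1-sigma)*(c+d)],

the ratio of total controls to total cases in the new data normalised by the
same quantity in the original.  For equal numbers of cases and controls this
is simply (1+sigma)/(1-sigma).

Caveat: reclassification treats the moved cases as having no disease
predisposition at all, which is optimistic for correctly diagnosed patients;
the no-reclassification subgroup model in :mod:`casehet.samplesize` is the
conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, InfeasibleSigmaError
from .tables import AlleleTable, AssocStats, assoc_stats, chi2_statistic

__all__ = [
    "PhenocopyAdjustment",
    "reclassify_phenocopies",
    "chi2_ratio_general",
    "chi2_ratio_equal_n",
    "true_chi2_after_reclassification",
    "phenocopy_adjustment",
]


def _check_sigma(sigma: float) -> None:
    if not (0 <= sigma < 1):
        raise DomainError(f"sigma must lie in [0, 1), got {sigma!r}")


@dataclass(frozen=True)
class PhenocopyAdjustment:
    """Full record of one reclassification: transform, both chi-squares, ratio."""

    sigma: float
    adjusted: AlleleTable
    chi2_original: float
    chi2_new: float
    ratio: float
    stats: AssocStats


def reclassify_phenocopies(table: AlleleTable, sigma: float) -> AlleleTable:
    """Move a proportion ``sigma`` of case alleles to controls at control frequencies.

    Raises :class:`InfeasibleSigmaError` if the removal would drive a case
    cell negative (sigma too large for the observed case counts).
    """
    _check_sigma(sigma)
    removed = sigma * table.n_cases
    da = removed * table.c / table.n_controls
    db = removed * table.d / table.n_controls
    a_n, b_n = table.a - da, table.b - db
    if a_n < 0 or b_n < 0:
        raise InfeasibleSigmaError(
            f"sigma={sigma} removes more alleles than the case row holds "
            f"(a_n={a_n:.4g}, b_n={b_n:.4g})"
        )
    return AlleleTable(a_n, b_n, table.c + da, table.d + db)


def chi2_ratio_general(table: AlleleTable, sigma: float) -> float:
    """Closed-form chi2_new/chi2: [(c+d) + sigma*(a+b)] / [(1-sigma)*(c+d)].

    Equals the direct ratio of chi-square statistics before and after
    :func:`reclassify_phenocopies` whenever the original association is
    nonzero.
    """
    _check_sigma(sigma)
    return (table.n_controls + sigma * table.n_cases) / ((1 - sigma) * table.n_controls)


def chi2_ratio_equal_n(sigma: float) -> float:
    """Equal-n special case (a+b = c+d) of the ratio: (1+sigma)/(1-sigma)."""
    _check_sigma(sigma)
    return (1 + sigma) / (1 - sigma)


def phenocopy_adjustment(table: AlleleTable, sigma: float) -> PhenocopyAdjustment:
    """Run the reclassification and collect both chi-squares and their ratio."""
    adjusted = reclassify_phenocopies(table, sigma)
    chi2_orig = chi2_statistic(table)
    st = assoc_stats(adjusted)
    ratio = st.chi2 / chi2_orig if chi2_orig > 0 else float("nan")
    return PhenocopyAdjustment(
        sigma=sigma,
        adjusted=adjusted,
        chi2_original=chi2_orig,
        chi2_new=st.chi2,
        ratio=ratio,
        stats=st,
    )


def true_chi2_after_reclassification(table: AlleleTable, sigma: float) -> AssocStats:
    """Association statistics of the table after phenocopies are reclassified."""
    return assoc_stats(reclassify_phenocopies(table, sigma))
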
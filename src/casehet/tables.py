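"""Exact arithmetic on 2x2 allele-count contingency tables.

Everything downstream (odds-ratio error factors, phenocopy reclassification,
sample-size multipliers) is built on the allelic 2x2 table

    =========  ========  ========
               Allele 1  Allele 2
    Cases      a         b
    Controls   c         d
    =========  ========  ========

where column 1 holds the tested (minor) allele by convention.  Counts are
real-valued, not necessarily integers: the sigma-transforms used elsewhere in
the package remove ``sigma*(a+b)`` case alleles at control frequencies, which
is generically fractional.  The closed forms are exact in real arithmetic, so
no rounding is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "AlleleTable",
    "AssocStats",
    "minor_allele_freq",
    "odds_ratio",
    "expected_counts",
    "chi2_statistic",
    "chi2_pvalue",
    "scale_table",
    "assoc_stats",
]


@dataclass(frozen=True)
class AlleleTable:
    """Allele counts for cases (``a``, ``b``) and controls (``c``, ``d``).

    ``a`` and ``c`` count the tested (minor) allele; orientation is the
    caller's responsibility — no automatic minor-allele flipping is done.
    Entries may be fractional; each row must have a positive total.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"cell {name} must be finite and >= 0, got {v!r}")
        if self.a + self.b <= 0:
            raise DomainError("case row total a+b must be positive")
        if self.c + self.d <= 0:
            raise DomainError("control row total c+d must be positive")

    @property
    def n_cases(self) -> float:
        """Total case alleles (a+b)."""
        return self.a + self.b

    @property
    def n_controls(self) -> float:
        """Total control alleles (c+d)."""
        return self.c + self.d

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AssocStats:
    """Allelic association summary for one table: OR, chi-square (1 df), p."""

    odds_ratio: float
    chi2: float
    p_value: float


def minor_allele_freq(table: AlleleTable, row: str = "cases") -> float:
    """Frequency of allele 1 in the chosen row (``"cases"`` or ``"controls"``)."""
    if row == "cases":
        num, tot = table.a, table.n_cases
    elif row == "controls":
        num, tot = table.c, table.n_controls
    else:
        raise DomainError(f"row must be 'cases' or 'controls', got {row!r}")
    if tot <= 0:
        raise DomainError(f"{row} row total must be positive")
    return num / tot


def odds_ratio(table: AlleleTable) -> float:
    """Allelic odds ratio (a*d)/(b*c).

    Raises :class:`DomainError` on a zero denominator cell; no
    continuity / Haldane-Anscombe correction is applied.
    """
    if table.b == 0 or table.c == 0:
        raise DomainError("odds ratio undefined: b and c must be positive")
    return (table.a * table.d) / (table.b * table.c)


def expected_counts(table: AlleleTable) -> AlleleTable:
    """Expected cell counts under independence: row total * col total / N.

    The expected table has exactly the same margins as the observed one.
    """
    n = table.total
    r1, r2 = table.n_cases, table.n_controls
    c1, c2 = table.a + table.c, table.b + table.d
    return AlleleTable(r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


def chi2_statistic(table: AlleleTable) -> float:
    """Pearson chi-square statistic (1 df) for the allelic 2x2 table.

    Computed via the margin form N*(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)],
    algebraically identical to sum((obs-exp)^2/exp).  No Yates correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    m1, m2, m3, m4 = a + b, c + d, a + c, b + d
    if min(m1, m2, m3, m4) <= 0:
        raise DomainError("chi-square undefined: all four margins must be positive")
    n = table.total
    det = a * d - b * c
    return n * det * det / (m1 * m2 * m3 * m4)


def chi2_pvalue(chi2: float) -> float:
    """Two-sided allelic-test p-value: upper tail of chi-square with 1 df."""
    if chi2 < 0:
        raise DomainError(f"chi-square statistic must be >= 0, got {chi2!r}")
    return float(stats.chi2.sf(chi2, df=1))


def scale_table(table: AlleleTable, gamma: float) -> AlleleTable:
    """Multiply every cell by ``gamma`` (> 0).

    The chi-square statistic is homogeneous of degree 1 in the cell counts,
    so chi2(scaled) = gamma * chi2(original) exactly, while the odds ratio is
    unchanged.  This linearity is what makes the sample-size multiplier a
    simple ratio of chi-square statistics.
    """
    if not (gamma > 0) or not math.isfinite(gamma):
        raise DomainError(f"scale factor must be positive and finite, got {gamma!r}")
    return AlleleTable(table.a * gamma, table.b * gamma, table.c * gamma, table.d * gamma)


def assoc_stats(table: AlleleTable) -> AssocStats:
    """OR, chi-square and two-sided p for one table."""
    chi2 = chi2_statistic(table)
    return AssocStats(odds_ratio=odds_ratio(table), chi2=chi2, p_value=chi2_pvalue(chi2))
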
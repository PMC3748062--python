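"""Heterogeneity scans: attenuation of OR and p as case subgroups dilute.

A scan fixes the control MAF and a subgroup-case MAF, then lets a
heterogeneity proportion ``h`` of cases carry control-like frequencies.  The
pooled case MAF is the linear blend (1-h)*q_subgroup + h*p_control, and the
observed OR and p-value attenuate monotonically toward the null as h grows.

Orientation note: scans report the odds ratio as
(control_a1 * case_a2) / (control_a2 * case_a1) — i.e. with controls as the
"exposed" row — so that a protective-direction tested allele (subgroup MAF
below the control MAF) still prints OR > 1, matching the convention of
published attenuation grids.  The chi-square and p-value are orientation-
invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DomainError
from .samplesize import gamma as _gamma
from .subgroup import SubclassCounts, or_error_factor_counts
from .tables import (
    AlleleTable,
    AssocStats,
    assoc_stats,
    chi2_pvalue,
    chi2_statistic,
    odds_ratio,
)

__all__ = [
    "HetScanRow",
    "SubclassReport",
    "blend_case_maf",
    "het_scan",
    "scan_to_records",
    "subclass_workflow",
]

SCAN_COLUMNS = [
    "het",
    "control_maf",
    "control_a1",
    "control_a2",
    "case_maf",
    "case_a1",
    "case_a2",
    "OR",
    "p",
]


@dataclass(frozen=True)
class HetScanRow:
    """One grid point of a heterogeneity scan."""

    het: float
    control_maf: float
    control_a1: float
    control_a2: float
    case_maf: float
    case_a1: float
    case_a2: float
    or_value: float
    p_value: float


def blend_case_maf(q_subgroup: float, p_control: float, h: float) -> float:
    """Pooled case MAF when a fraction ``h`` of cases sit at the control MAF."""
    for name, v in (("q_subgroup", q_subgroup), ("p_control", p_control), ("h", h)):
        if not (0 <= v <= 1):
            raise DomainError(f"{name} must lie in [0, 1], got {v!r}")
    return (1 - h) * q_subgroup + h * p_control


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def het_scan(
    n_cases: float,
    n_controls: float,
    q_subgroup: float,
    p_control: float,
    h_grid: Sequence[float],
    *,
    exact: bool = False,
) -> list[HetScanRow]:
    """Build the attenuation grid over heterogeneity proportions ``h_grid``.

    Each individual contributes two alleles.  In display mode (default) the
    allele-1 counts are rounded half-away-from-zero and allele 2 takes the
    complement 2n - allele1, mirroring how published grids print integer
    counts; ``exact=True`` keeps real-valued counts so the h=1 row is an
    exact null (OR = 1, chi2 = 0).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise DomainError("sample sizes must be positive")
    if not (0 < q_subgroup < 1) or not (0 < p_control < 1):
        raise DomainError("frequencies must lie strictly in (0, 1)")

    ctrl_alleles = 2 * n_controls
    case_alleles = 2 * n_cases
    ctrl_a1 = ctrl_alleles * p_control
    if not exact:
        ctrl_a1 = _round_half_away(ctrl_a1)

    rows: list[HetScanRow] = []
    for h in h_grid:
        maf = blend_case_maf(q_subgroup, p_control, h)
        case_a1 = case_alleles * maf
        if not exact:
            case_a1 = _round_half_away(case_a1)
        case_a2 = case_alleles - case_a1
        ctrl_a2 = ctrl_alleles - ctrl_a1
        # controls as row 1 (orientation note in the module docstring)
        table = AlleleTable(ctrl_a1, ctrl_a2, case_a1, case_a2)
        chi2 = chi2_statistic(table)
        rows.append(
            HetScanRow(
                het=h,
                control_maf=p_control,
                control_a1=ctrl_a1,
                control_a2=ctrl_a2,
                case_maf=maf,
                case_a1=case_a1,
                case_a2=case_a2,
                or_value=odds_ratio(table) if case_a1 > 0 and ctrl_a2 > 0 else float("nan"),
                p_value=chi2_pvalue(chi2),
            )
        )
    return rows


def scan_to_records(rows: Sequence[HetScanRow]) -> list[dict]:
    """Scan rows as plain dicts in the TSV column order."""
    return [
        {
            "het": r.het,
            "control_maf": r.control_maf,
            "control_a1": r.control_a1,
            "control_a2": r.control_a2,
            "case_maf": r.case_maf,
            "case_a1": r.case_a1,
            "case_a2": r.case_a2,
            "OR": r.or_value,
            "p": r.p_value,
        }
        for r in rows
    ]


@dataclass(frozen=True)
class SubclassReport:
    """Forward worked example: pooled stats, subclass stats, factor, gamma."""

    original: AssocStats
    subclass: AssocStats
    error_factor: float
    sigma: float
    gamma: float


def subclass_workflow(
    table: AlleleTable, sub: SubclassCounts, sigma: float | None = None
) -> SubclassReport:
    """Complete forward workflow for one table with a known subclass.

    Reports the pooled association, the subclass-versus-controls association
    (both with two-sided allelic p-values), the OR error factor linking them,
    and the sample-size multiplier gamma at ``sigma`` (default: the
    non-subclass proportion of case alleles).
    """
    if sigma is None:
        sigma = 1 - (sub.a1 + sub.b1) / table.n_cases
    sub_table = AlleleTable(sub.a1, sub.b1, table.c, table.d)
    return SubclassReport(
        original=assoc_stats(table),
        subclass=assoc_stats(sub_table),
        error_factor=or_error_factor_counts(table, sub),
        sigma=sigma,
        gamma=_gamma(table, sigma).gamma,
    )
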
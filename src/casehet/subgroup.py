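"""Odds-ratio error factor due to a genetic subgroup of cases.

When a variant raises risk only within a subclass of cases, pooling all
cases regresses the case allele frequency toward the population's and the
observed odds ratio understates the subclass's true effect.  With subclass
allele counts (a1, b1) inside case counts (a, b), the true subclass-versus-
controls odds ratio OR_sub = (a1*d)/(b1*c) exceeds the pooled OR_all =
(a*d)/(b*c) by the *error factor*

    OR_sub / OR_all = (a1/a) / (b1/b),

which depends only on how allele 1 is over-represented in the subclass
relative to allele 2.  In frequency terms, for pooled case MAF ``p`` and
subclass MAF ``q`` the factor is odds(q)/odds(p) = q(1-p) / (p(1-q)),
independent of the subclass size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DomainError
from .tables import AlleleTable, odds_ratio

__all__ = [
    "SubclassCounts",
    "subgroup_true_or",
    "or_error_factor_counts",
    "or_error_factor_mafs",
    "error_factor_curve",
]


@dataclass(frozen=True)
class SubclassCounts:
    """Allele counts (a1, b1) of the subclass of cases carrying the effect."""

    a1: float
    b1: float

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.b1 < 0:
            raise DomainError("subclass counts must be non-negative")
        if self.a1 + self.b1 <= 0:
            raise DomainError("subclass must contain at least one allele")

    def remainder(self, table: AlleleTable) -> tuple[float, float]:
        """Allele counts (a2, b2) of the cases outside the subclass."""
        a2, b2 = table.a - self.a1, table.b - self.b1
        if a2 < 0 or b2 < 0:
            raise DomainError("subclass counts exceed whole-case counts")
        return a2, b2


def _check_within(table: AlleleTable, sub: SubclassCounts) -> None:
    if sub.a1 > table.a or sub.b1 > table.b:
        raise DomainError("subclass counts exceed whole-case counts")


def subgroup_true_or(table: AlleleTable, sub: SubclassCounts) -> float:
    """True odds ratio of the subclass against all controls: (a1*d)/(b1*c)."""
    _check_within(table, sub)
    if sub.b1 == 0 or table.c == 0:
        raise DomainError("subgroup OR undefined: b1 and c must be positive")
    return (sub.a1 * table.d) / (sub.b1 * table.c)


def or_error_factor_counts(table: AlleleTable, sub: SubclassCounts) -> float:
    """Error factor (a1/a)/(b1/b) = OR_sub / OR_all from explicit counts.

    Exactly equals ``subgroup_true_or(table, sub) / odds_ratio(table)``.
    Values < 1 are legal and meaningful (protective direction); nothing is
    clamped.
    """
    _check_within(table, sub)
    if min(table.a, table.b, sub.a1, sub.b1) <= 0:
        raise DomainError("error factor requires a, b, a1, b1 all positive")
    return (sub.a1 / table.a) / (sub.b1 / table.b)


def or_error_factor_mafs(p_cases: float, q_subgroup: float) -> float:
    """Error factor from frequencies alone: odds(q)/odds(p).

    ``p_cases`` is the MAF observed across all cases; ``q_subgroup`` the MAF
    within the subclass.  Independent of subclass size.  Exceeds 1 exactly
    when q > p.
    """
    for name, f in (("p_cases", p_cases), ("q_subgroup", q_subgroup)):
        if not (0 < f < 1):
            raise DomainError(f"{name} must lie strictly in (0, 1), got {f!r}")
    return (q_subgroup * (1 - p_cases)) / (p_cases * (1 - q_subgroup))


def error_factor_curve(
    p_cases: float, maf_increase_grid: Sequence[float]
) -> list[tuple[float, float]]:
    """Error factor along a grid of additive subgroup-MAF increases over ``p_cases``.

    Each grid entry ``delta`` maps to ``or_error_factor_mafs(p, p + delta)``;
    the curve is strictly increasing in the increment.
    """
    out: list[tuple[float, float]] = []
    for delta in maf_increase_grid:
        q = p_cases + delta
        if delta < 0 or not (q < 1):
            raise DomainError(
                f"MAF increment {delta!r} leaves the valid frequency range for p={p_cases}"
            )
        factor = 1.0 if delta == 0 else or_error_factor_mafs(p_cases, q)
        out.append((delta, factor))
    return out


def _consistency_check(table: AlleleTable, sub: SubclassCounts) -> float:
    # ratio form used by tests; kept next to the closed form it mirrors
    return subgroup_true_or(table, sub) / odds_ratio(table)
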
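"""Sample-size multiplier gamma(sigma) under unrecognised heterogeneity.

Here ``sigma`` is the proportion of cases *not* in the associated subgroup
(contrast the phenocopy model, where sigma is the reclassified proportion —
numerically the same removal).  The cases outside the subgroup are assumed
to sit at control allele frequencies, so stripping them removes
``sigma*(a+b)`` case alleles at control frequencies but, unlike phenocopy
reclassification, does NOT add them to the control row:

    a' = a - sigma*(a+b)*c/(c+d),   b' = b - sigma*(a+b)*d/(c+d),
    controls unchanged.

This removal preserves the determinant a'd - b'c = ad - bc exactly.  The
chi-square of the stripped table is the "true" statistic of the subgroup
alone.  Because the chi-square statistic is homogeneous of degree 1 under
uniform scaling of the cells, the factor gamma by which the *whole* cohort
must grow (at its original allele frequencies) to match the subgroup's
statistic is exactly

    gamma(sigma) = chi2(stripped) / chi2(original),

with gamma(0) = 1 and gamma strictly increasing in sigma up to the feasible
limit where a stripped cell reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, InfeasibleSigmaError
from .subgroup import SubclassCounts
from .tables import AlleleTable, chi2_statistic

__all__ = [
    "GammaResult",
    "GammaCurve",
    "strip_nonsubgroup",
    "chi2_subgroup",
    "gamma",
    "gamma_equal_n",
    "gamma_explicit_subclass",
    "gamma_curve",
    "feasible_sigma_max",
]


@dataclass(frozen=True)
class GammaResult:
    """gamma = chi2_subgroup / chi2_original at one heterogeneity level sigma."""

    sigma: float
    chi2_subgroup: float
    chi2_original: float
    gamma: float


@dataclass(frozen=True)
class GammaCurve:
    """gamma evaluated over a sigma grid for one table."""

    table: AlleleTable
    grid: list[tuple[float, float]]
    feasible_max_sigma: float


def _check_sigma(sigma: float) -> None:
    if not (0 <= sigma < 1):
        raise DomainError(f"sigma must lie in [0, 1), got {sigma!r}")


def strip_nonsubgroup(table: AlleleTable, sigma: float) -> AlleleTable:
    """Remove the non-subgroup cases (at control frequencies); controls unchanged."""
    _check_sigma(sigma)
    removed = sigma * table.n_cases
    a_p = table.a - removed * table.c / table.n_controls
    b_p = table.b - removed * table.d / table.n_controls
    if a_p < 0 or b_p < 0:
        raise InfeasibleSigmaError(
            f"sigma={sigma} exceeds the feasible maximum "
            f"{feasible_sigma_max(table):.4g} for this table"
        )
    return AlleleTable(a_p, b_p, table.c, table.d)


def chi2_subgroup(table: AlleleTable, sigma: float) -> float:
    """Chi-square of the stripped table: the subgroup's true statistic."""
    return chi2_statistic(strip_nonsubgroup(table, sigma))


def gamma(table: AlleleTable, sigma: float) -> GammaResult:
    """Sample-size multiplier needed to match the subgroup's chi-square.

    Computed as the ratio chi2(stripped)/chi2(original); exact because the
    statistic scales linearly under uniform count scaling.  Undefined when
    the original table carries no association (ad = bc).
    """
    chi2_orig = chi2_statistic(table)
    if chi2_orig == 0:
        raise DomainError("gamma undefined: original table has zero association (ad = bc)")
    chi2_sub = chi2_subgroup(table, sigma)
    return GammaResult(
        sigma=sigma,
        chi2_subgroup=chi2_sub,
        chi2_original=chi2_orig,
        gamma=chi2_sub / chi2_orig,
    )


def gamma_equal_n(table: AlleleTable, sigma: float, *, rel_tol: float = 1e-9) -> GammaResult:
    """gamma for the equal-n case (a+b = c+d); identical value to :func:`gamma`.

    Kept as a named entry point because the equal-n simplification is the
    form used in stratified-cohort examples (e.g. carriage-rate tables built
    per equal numbers of cases and controls).
    """
    n1, n2 = table.n_cases, table.n_controls
    if abs(n1 - n2) > rel_tol * max(n1, n2):
        raise DomainError(
            f"gamma_equal_n requires a+b = c+d, got {n1} cases vs {n2} control alleles"
        )
    return gamma(table, sigma)


def gamma_explicit_subclass(table: AlleleTable, sub: SubclassCounts) -> GammaResult:
    """gamma from explicit subclass counts: chi2(a1,b1,c,d)/chi2(a,b,c,d).

    Alternative to the sigma parameterisation: instead of assuming the
    removed cases sit exactly at control frequencies, use the literal
    subclass counts.  The two parameterisations generally disagree — the
    sigma model's stripped row (a', b') is what remains after a
    control-frequency removal, not the observed subclass row.
    """
    chi2_orig = chi2_statistic(table)
    if chi2_orig == 0:
        raise DomainError("gamma undefined: original table has zero association (ad = bc)")
    sub_table = AlleleTable(sub.a1, sub.b1, table.c, table.d)
    chi2_sub = chi2_statistic(sub_table)
    n_cases = table.n_cases
    sigma = 1 - (sub.a1 + sub.b1) / n_cases if n_cases > 0 else float("nan")
    return GammaResult(
        sigma=sigma,
        chi2_subgroup=chi2_sub,
        chi2_original=chi2_orig,
        gamma=chi2_sub / chi2_orig,
    )


def feasible_sigma_max(table: AlleleTable) -> float:
    """Supremum of sigma for which both stripped case cells stay non-negative.

    sigma* = min( a(c+d)/[(a+b)c], b(c+d)/[(a+b)d], 1 ); as sigma approaches
    sigma* (with ad != bc) gamma diverges.
    """
    n1, n2 = table.n_cases, table.n_controls
    bounds = [1.0]
    if table.c > 0:
        bounds.append(table.a * n2 / (n1 * table.c))
    if table.d > 0:
        bounds.append(table.b * n2 / (n1 * table.d))
    return min(bounds)


def gamma_curve(table: AlleleTable, grid_step: float) -> GammaCurve:
    """Evaluate gamma on sigma in {0, step, 2*step, ...} below the feasible limit."""
    if not (0 < grid_step < 1):
        raise DomainError(f"grid_step must lie in (0, 1), got {grid_step!r}")
    sigma_max = feasible_sigma_max(table)
    grid: list[tuple[float, float]] = []
    k = 0
    while True:
        sigma = k * grid_step
        if sigma >= sigma_max or sigma >= 1:
            break
        grid.append((sigma, gamma(table, sigma).gamma))
        k += 1
    return GammaCurve(table=table, grid=grid, feasible_max_sigma=sigma_max)
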
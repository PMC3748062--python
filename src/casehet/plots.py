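"""Curve plots for the three corrections, with numbers saved alongside.

Every plot writes its underlying curve data as a TSV next to the image
(same stem, ``.tsv`` suffix) so downstream checks can assert numbers rather
than pixels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .phenocopy import chi2_ratio_equal_n
from .samplesize import gamma_curve
from .subgroup import error_factor_curve
from .tables import AlleleTable

__all__ = [
    "or_error_factor_figure",
    "chi2_ratio_figure",
    "gamma_figure",
    "plot_figures",
]


def _save(fig, frame: pd.DataFrame, out: str | Path) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out)
    plt.close(fig)
    frame.to_csv(out.with_suffix(".tsv"), sep="\t", index=False)
    return out


def or_error_factor_figure(
    case_mafs: Sequence[float], out: str | Path, *, step: float = 0.01
) -> pd.DataFrame:
    """Error-factor curves versus additive subgroup-MAF increase, one per case MAF."""
    fig, ax = plt.subplots(figsize=(6, 4))
    rows = []
    for p in case_mafs:
        grid = np.arange(0, 1 - p - step / 2, step)
        curve = error_factor_curve(p, grid)
        ax.plot([x for x, _ in curve], [y for _, y in curve], label=f"case MAF {p:g}")
        rows += [{"case_maf": p, "maf_increase": x, "error_factor": y} for x, y in curve]
    ax.set_xlabel("increase in subgroup MAF over case MAF")
    ax.set_ylabel("OR error factor (OR_sub / OR_all)")
    ax.legend()
    frame = pd.DataFrame(rows)
    _save(fig, frame, out)
    return frame


def chi2_ratio_figure(out: str | Path, *, step: float = 0.01, sigma_max: float = 0.9) -> pd.DataFrame:
    """Equal-n chi-square ratio (1+sigma)/(1-sigma) over sigma."""
    sigmas = np.arange(0, sigma_max + step / 2, step)
    ratios = [chi2_ratio_equal_n(s) for s in sigmas]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sigmas, ratios)
    ax.set_xlabel("sigma (proportion of phenocopies among cases)")
    ax.set_ylabel("chi-square ratio (new / original)")
    frame = pd.DataFrame({"sigma": sigmas, "chi2_ratio": ratios})
    _save(fig, frame, out)
    return frame


def gamma_figure(table: AlleleTable, out: str | Path, *, step: float = 0.01) -> pd.DataFrame:
    """gamma(sigma) for one table, over the feasible sigma range."""
    curve = gamma_curve(table, step)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([s for s, _ in curve.grid], [g for _, g in curve.grid])
    ax.set_xlabel("sigma (proportion of cases not in the subgroup)")
    ax.set_ylabel("sample-size multiplier gamma")
    frame = pd.DataFrame(curve.grid, columns=["sigma", "gamma"])
    _save(fig, frame, out)
    return frame


def plot_figures(kind: str, params: dict, out: str | Path) -> pd.DataFrame:
    """Dispatch by kind: ``or-error`` | ``chi2-ratio`` | ``gamma``."""
    if kind == "or-error":
        return or_error_factor_figure(params.get("case_mafs", [0.05, 0.1, 0.2, 0.35, 0.5]), out)
    if kind == "chi2-ratio":
        return chi2_ratio_figure(out)
    if kind == "gamma":
        return gamma_figure(params["table"], out)
    raise ValueError(f"unknown figure kind {kind!r}")
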
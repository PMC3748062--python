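"""Batch TSV processing: per-SNP application of the three core calculators.

Input is a tab-separated summary table with a header row and the required
columns ``snp_id, case_a1, case_a2, control_a1, control_a2``; optional
columns ``sigma`` (per-SNP proportion) and ``sub_a1, sub_b1`` (explicit
subclass counts).  Rows violating the table invariants are skipped with a
line-numbered warning (or rejected outright in strict mode); per-SNP
infeasibility in a computation never aborts the batch — the offending row
gets NA results plus a ``reason`` column.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import DomainError, FormatError
from .phenocopy import chi2_ratio_general
from .samplesize import gamma as _gamma
from .subgroup import SubclassCounts, or_error_factor_counts, or_error_factor_mafs
from .tables import AlleleTable, assoc_stats, minor_allele_freq

__all__ = ["BatchRecord", "read_batch", "run_batch", "write_frame"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["snp_id", "case_a1", "case_a2", "control_a1", "control_a2"]
OPTIONAL_COLUMNS = ["sigma", "sub_a1", "sub_b1"]
MODES = ("or-error", "phenocopy", "gamma")


@dataclass(frozen=True)
class BatchRecord:
    """One SNP's summary counts, with optional per-SNP sigma / subclass counts."""

    snp_id: str
    a: float
    b: float
    c: float
    d: float
    sigma: float | None = None
    sub_a1: float | None = None
    sub_b1: float | None = None

    def table(self) -> AlleleTable:
        return AlleleTable(self.a, self.b, self.c, self.d)


def read_batch(path: str | Path, *, strict: bool = False) -> list[BatchRecord]:
    """Parse a TSV summary file into validated :class:`BatchRecord` rows."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no header row") from exc
    missing = [col for col in REQUIRED_COLUMNS if col not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[BatchRecord] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            counts = [float(row[col]) for col in REQUIRED_COLUMNS[1:]]
            if any(math.isnan(v) for v in counts):
                raise FormatError("non-numeric allele count")
            snp_id = str(row["snp_id"])
            if snp_id in seen:
                raise FormatError(f"duplicate snp_id {snp_id!r}")
            optional = {}
            for col in OPTIONAL_COLUMNS:
                if col in frame.columns and not pd.isna(row[col]):
                    optional[col] = float(row[col])
            rec = BatchRecord(snp_id, *counts, **optional)
            rec.table()  # invariant check
        except (ValueError, TypeError) as exc:
            if strict:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
            logger.warning("%s:%d: skipping row (%s)", path, line_no, exc)
            continue
        seen.add(snp_id)
        records.append(rec)
    if not records:
        logger.warning("%s: no valid data rows", path)
    return records


def _base_columns(rec: BatchRecord) -> dict:
    stats = assoc_stats(rec.table())
    return {
        "snp_id": rec.snp_id,
        "case_a1": rec.a,
        "case_a2": rec.b,
        "control_a1": rec.c,
        "control_a2": rec.d,
        "OR": stats.odds_ratio,
        "chi2": stats.chi2,
        "p": stats.p_value,
    }


def run_batch(
    records: Sequence[BatchRecord],
    mode: str,
    *,
    sigma: float | None = None,
    q_subgroup: float | None = None,
) -> pd.DataFrame:
    """Apply one calculator per SNP, appending the computed column.

    mode ``or-error``  -> ``error_factor`` from per-row ``sub_a1/sub_b1``
    counts, or from ``q_subgroup`` versus the row's case MAF;
    mode ``phenocopy`` -> ``chi2_ratio`` at the row's sigma (or the global
    ``sigma``); mode ``gamma`` -> ``gamma`` likewise.  Infeasible rows carry
    NA plus a ``reason``.
    """
    if mode not in MODES:
        raise DomainError(f"mode must be one of {MODES}, got {mode!r}")
    out_col = {"or-error": "error_factor", "phenocopy": "chi2_ratio", "gamma": "gamma"}[mode]
    rows = []
    for rec in records:
        row = _base_columns(rec)
        row[out_col], row["reason"] = _apply(rec, mode, sigma, q_subgroup)
        rows.append(row)
    return pd.DataFrame(rows)


def _apply(
    rec: BatchRecord, mode: str, sigma: float | None, q_subgroup: float | None
) -> tuple[float, str]:
    table = rec.table()
    try:
        if mode == "or-error":
            if rec.sub_a1 is not None and rec.sub_b1 is not None:
                return (
                    or_error_factor_counts(table, SubclassCounts(rec.sub_a1, rec.sub_b1)),
                    "",
                )
            if q_subgroup is not None:
                return or_error_factor_mafs(minor_allele_freq(table), q_subgroup), ""
            return float("nan"), "no sub_a1/sub_b1 columns and no q_subgroup given"
        s = rec.sigma if rec.sigma is not None else sigma
        if s is None:
            return float("nan"), "no sigma column and no global sigma given"
        if mode == "phenocopy":
            return chi2_ratio_general(table, s), ""
        return _gamma(table, s).gamma, ""
    except DomainError as exc:
        return float("nan"), str(exc)


def write_frame(frame: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write a result frame as TSV or JSON records."""
    path = Path(path)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise FormatError(f"format must be 'tsv' or 'json', got {fmt!r}")
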
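"""Reading and harmonising GWAS summary statistics.

Inputs are plain-text (optionally gzipped) TSVs with one row per variant
and configurable column names. Only p-values are used: rows with missing,
non-finite, non-positive or > 1 p-values are dropped (p = 0 is dropped
rather than clamped — the GPS statistic is rank-based and a clamp would
create a massive artificial tie at the minimum) and the drops are logged
by reason. Pairing is an exact-string inner join on variant ID after
whitespace trimming; duplicated IDs within a file are removed entirely.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    InputValidationError,
    InsufficientOverlapError,
    SchemaError,
)
from .pair import MIN_VARIANTS, HarmonizedPair


@dataclass
class ColumnMap:
    """Column names of one summary-statistics file."""

    variant_col: str = "variant_id"
    chrom_col: Optional[str] = "chrom"
    pos_col: Optional[str] = "pos"
    pval_col: str = "pval"

    def __post_init__(self) -> None:
        names = [n for n in (self.variant_col, self.chrom_col,
                             self.pos_col, self.pval_col) if n is not None]
        if any(not n for n in names):
            raise InputValidationError("column names must be non-empty")
        if len(set(names)) != len(names):
            raise InputValidationError(f"column names must be distinct: {names}")


@dataclass
class RegionFilter:
    """A genomic interval to exclude, 1-based inclusive at both ends."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputValidationError(
                f"region start {self.start} > end {self.end}"
            )

    @classmethod
    def parse(cls, text: str, label: str = "") -> "RegionFilter":
        """Parse ``chrom:start-end`` (e.g. ``6:25000000-35000000``)."""
        try:
            chrom, span = text.split(":")
            start, end = span.split("-")
            return cls(chrom=chrom, start=int(start), end=int(end), label=label)
        except ValueError as exc:
            raise InputValidationError(
                f"cannot parse region {text!r}; expected chrom:start-end"
            ) from exc


#: Default MHC interval (GRCh37); the paper of record for any analysis
#: should echo the region actually used, so callers must pass it
#: explicitly — this constant is a convenience, not an implicit default.
MHC_GRCH37 = RegionFilter(chrom="6", start=25_000_000, end=35_000_000,
                          label="MHC")


@dataclass
class IngestLog:
    """Row accounting from one file read."""

    path: str
    rows_read: int
    rows_kept: int
    dropped: dict[str, int] = field(default_factory=dict)


def read_sumstats(path, colmap: ColumnMap) -> tuple[pd.DataFrame, IngestLog]:
    """Read one summary-statistics TSV into canonical columns.

    Returns a table with columns ``variant_id``, ``pval`` and, when
    mapped, ``chrom`` and ``pos``, plus an :class:`IngestLog`.
    """
    df = pd.read_csv(path, sep="\t", compression="infer",
                     dtype={colmap.chrom_col: str} if colmap.chrom_col else None)
    needed = [colmap.variant_col, colmap.pval_col]
    optional = [c for c in (colmap.chrom_col, colmap.pos_col) if c]
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    keep = {colmap.variant_col: "variant_id", colmap.pval_col: "pval"}
    for col, canon in zip((colmap.chrom_col, colmap.pos_col), ("chrom", "pos")):
        if col and col in df.columns:
            keep[col] = canon
    out = df[list(keep)].rename(columns=keep)
    out["variant_id"] = out["variant_id"].astype(str).str.strip()
    p = pd.to_numeric(out["pval"], errors="coerce").to_numpy(dtype=float)
    rows_read = len(out)
    is_nan = ~np.isfinite(p)
    is_zero = ~is_nan & (p == 0.0)
    is_neg = ~is_nan & (p < 0.0)
    is_gt1 = ~is_nan & (p > 1.0)
    bad = is_nan | is_zero | is_neg | is_gt1
    dropped = {
        "nan": int(is_nan.sum()),
        "zero": int(is_zero.sum()),
        "negative": int(is_neg.sum()),
        "gt_one": int(is_gt1.sum()),
    }
    out = out.loc[~bad].copy()
    out["pval"] = p[~bad]
    if out.empty:
        raise EmptyInputError(f"no usable rows left after filtering {path}")
    log = IngestLog(path=str(path), rows_read=rows_read,
                    rows_kept=len(out), dropped=dropped)
    return out.reset_index(drop=True), log


def _drop_duplicates(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    dup = df["variant_id"].duplicated(keep=False)
    return df.loc[~dup], int(dup.sum())


def harmonize_pair(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    region_filters: Iterable[RegionFilter] = (),
    metadata: Optional[dict[str, Any]] = None,
) -> HarmonizedPair:
    """Inner-join two summary tables on variant ID into a test-ready pair.

    Duplicate IDs within a file are dropped entirely (all copies) and
    logged in the metadata; variants inside any region filter are removed;
    output is ordered by (chrom, pos) when positions are available in both
    tables, else by variant ID.
    """
    if table_a.empty or table_b.empty:
        raise EmptyInputError("cannot harmonise an empty table")
    region_filters = list(region_filters)
    a, dup_a = _drop_duplicates(table_a)
    b, dup_b = _drop_duplicates(table_b)
    merged = a.merge(b, on="variant_id", suffixes=("_a", "_b"))

    have_coords = "chrom_a" in merged.columns and "pos_a" in merged.columns
    n_filtered = 0
    if region_filters:
        if not have_coords:
            raise InputValidationError(
                "region filters need chromosome and position columns"
            )
        mask = np.zeros(len(merged), dtype=bool)
        for f in region_filters:
            mask |= (
                (merged["chrom_a"].astype(str) == str(f.chrom))
                & (merged["pos_a"] >= f.start)
                & (merged["pos_a"] <= f.end)
            )
        n_filtered = int(mask.sum())
        merged = merged.loc[~mask]

    if have_coords:
        merged = merged.sort_values(
            ["chrom_a", "pos_a"], kind="stable"
        )
    else:
        merged = merged.sort_values("variant_id", kind="stable")

    if len(merged) < MIN_VARIANTS:
        raise InsufficientOverlapError(
            f"only {len(merged)} variants shared after harmonisation "
            f"(minimum {MIN_VARIANTS})"
        )
    meta = dict(metadata or {})
    meta.update({
        "n_joined": len(merged),
        "n_duplicate_dropped_a": dup_a,
        "n_duplicate_dropped_b": dup_b,
        "n_region_filtered": n_filtered,
        "region_filters": [
            f"{f.label or 'region'}:{f.chrom}:{f.start}-{f.end}"
            for f in region_filters
        ],
    })
    return HarmonizedPair(
        variant_ids=merged["variant_id"].tolist(),
        u=merged["pval_a"].to_numpy(dtype=float),
        v=merged["pval_b"].to_numpy(dtype=float),
        metadata=meta,
    )


def write_pair(pair: HarmonizedPair, path) -> None:
    """Write a harmonised pair as TSV (variant_id, pval_a, pval_b)."""
    pd.DataFrame({
        "variant_id": pair.variant_ids,
        "pval_a": pair.u,
        "pval_b": pair.v,
    }).to_csv(path, sep="\t", index=False)


def read_pair(path) -> HarmonizedPair:
    """Read back a pair written by :func:`write_pair`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("variant_id", "pval_a", "pval_b"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    return HarmonizedPair(
        variant_ids=df["variant_id"].astype(str).tolist(),
        u=df["pval_a"].to_numpy(dtype=float),
        v=df["pval_b"].to_numpy(dtype=float),
        metadata={"source": str(path)},
    )
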
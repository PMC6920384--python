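"""Per-variant GFP scores from per-bin sequencing counts.

The score of a variant is the bin-index-weighted mean of its
bin-normalized read abundances: counts are first normalized within each
FACS bin by that bin's total depth, each variant's five normalized
abundances are renormalized to sum to one, and the score is the weighted
mean of the bin indices 1..5.  A score of 1 means all read mass in the
dimmest bin, 5 all mass in the brightest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    SchemaError,
    UndefinedScoreError,
    ZeroDepthBinError,
)

N_BINS = 5
BIN_INDICES = np.arange(1, N_BINS + 1, dtype=float)

SCORE_COLUMNS = (
    ["variant", "total_reads"]
    + [f"frac{b}" for b in range(1, N_BINS + 1)]
    + ["gfp_score"]
)


@dataclass
class BinCountMatrix:
    """Raw read counts for each variant in each of the five FACS bins."""

    variants: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_BINS:
            raise SchemaError(
                f"count matrix must be n x {N_BINS}, got {self.counts.shape}"
            )
        if len(self.variants) != self.counts.shape[0]:
            raise SchemaError(
                f"{len(self.variants)} variants vs {self.counts.shape[0]} count rows"
            )
        if (self.counts < 0).any():
            raise SchemaError("negative counts in matrix")
        if len(set(self.variants)) != len(self.variants):
            raise SchemaError("variant strings are not unique")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def bin_depths(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=[f"bin{b}" for b in range(1, N_BINS + 1)]
        )
        df.insert(0, "variant", self.variants)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BinCountMatrix":
        cols = [f"bin{b}" for b in range(1, N_BINS + 1)]
        missing = [c for c in ["variant", *cols] if c not in df.columns]
        if missing:
            raise SchemaError(f"count table missing column(s): {missing}")
        return cls(df["variant"].astype(str).tolist(), df[cols].to_numpy())


def filter_low_count(matrix: BinCountMatrix, min_total: int = 10) -> BinCountMatrix:
    """Drop variants with fewer than ``min_total`` reads summed over bins.

    The screen removed sequences with less than ten total counts across
    all bins; row order is preserved.
    """
    if min_total < 0:
        raise ValueError(f"min_total must be >= 0, got {min_total}")
    keep = matrix.counts.sum(axis=1) >= min_total
    return BinCountMatrix(
        [v for v, k in zip(matrix.variants, keep) if k], matrix.counts[keep]
    )


def normalize_bins(matrix: BinCountMatrix, allow_empty_bins: bool = False) -> np.ndarray:
    """Within-bin normalized abundances: counts / per-bin total depth.

    A bin with zero depth is an error by default; with
    ``allow_empty_bins`` (used by score_pipeline, where an unsequenced
    bin simply contributes no weight) its column is all zeros.
    """
    depths = matrix.counts.sum(axis=0)
    zero = np.flatnonzero(depths == 0)
    if zero.size and not allow_empty_bins:
        raise ZeroDepthBinError(
            f"bin(s) {[int(b) + 1 for b in zero]} have zero total counts"
        )
    safe = np.where(depths == 0, 1, depths)
    return matrix.counts / safe


def gfp_score(normalized_row: np.ndarray) -> float:
    """Weighted mean of bin indices for one variant's normalized row."""
    row = np.asarray(normalized_row, dtype=float)
    if row.shape != (N_BINS,):
        raise ValueError(f"expected a length-{N_BINS} row, got shape {row.shape}")
    if (row < 0).any():
        raise ValueError("normalized abundances must be non-negative")
    total = row.sum()
    if total == 0:
        raise UndefinedScoreError("variant has zero mass in every bin")
    return float((row / total) @ BIN_INDICES)


def gfp_scores(normalized: np.ndarray) -> np.ndarray:
    """Vectorized gfp_score over the rows of a normalized matrix."""
    normalized = np.asarray(normalized, dtype=float)
    totals = normalized.sum(axis=1)
    if (totals == 0).any():
        raise UndefinedScoreError(
            f"{int((totals == 0).sum())} variant(s) have zero mass in every bin"
        )
    return (normalized / totals[:, None]) @ BIN_INDICES


def score_pipeline(matrix: BinCountMatrix, min_total: int = 10) -> pd.DataFrame:
    """Filter, normalize, and score; returns the standard score table.

    Columns: variant, total_reads (raw), frac1..frac5 (per-variant
    renormalized bin fractions, summing to one), gfp_score in [1,5].
    Filtering precedes normalization (the screen's order is unstated;
    this choice is logged in the provenance of written outputs).
    """
    kept = filter_low_count(matrix, min_total)
    norm = normalize_bins(kept, allow_empty_bins=True)
    fractions = norm / norm.sum(axis=1, keepdims=True)
    table = pd.DataFrame({"variant": kept.variants})
    table["total_reads"] = kept.counts.sum(axis=1)
    for b in range(N_BINS):
        table[f"frac{b + 1}"] = fractions[:, b]
    table["gfp_score"] = fractions @ BIN_INDICES
    return table


def pool_counts(matrices: list[BinCountMatrix]) -> BinCountMatrix:
    """Sum counts across replicates (pooled-count scoring option)."""
    if not matrices:
        raise InsufficientDataError("no matrices to pool")
    index: dict[str, int] = {}
    for m in matrices:
        for v in m.variants:
            index.setdefault(v, len(index))
    counts = np.zeros((len(index), N_BINS), dtype=np.int64)
    for m in matrices:
        rows = np.fromiter((index[v] for v in m.variants), dtype=np.int64)
        np.add.at(counts, rows, m.counts.astype(np.int64))
    variants = [v for v, _ in sorted(index.items(), key=lambda kv: kv[1])]
    return BinCountMatrix(variants, counts)


def replicate_correlation(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, min_reads: int = 100
) -> tuple[float, int]:
    """Pearson r of GFP scores between replicates on well-read variants.

    Variants must have strictly more than ``min_reads`` raw reads in each
    replicate (the screen's reproducibility used sequences with >100
    reads).  Returns (r, number of shared variants).
    """
    a = scores_a[scores_a["total_reads"] > min_reads]
    b = scores_b[scores_b["total_reads"] > min_reads]
    merged = a.merge(b, on="variant", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} shared variants above {min_reads} reads "
            "(need at least 3)"
        )
    r, _ = stats.pearsonr(merged["gfp_score_a"], merged["gfp_score_b"])
    return float(r), len(merged)


def mean_scores(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted per-variant mean and sd of GFP scores across replicates.

    Variants are kept when present in every replicate; replicate-level
    filters have already been applied by score_pipeline.
    """
    if not tables:
        raise InsufficientDataError("no replicate score tables")
    merged = tables[0][["variant", "gfp_score"]].rename(
        columns={"gfp_score": "gfp_score_0"}
    )
    for i, t in enumerate(tables[1:], start=1):
        merged = merged.merge(
            t[["variant", "gfp_score"]].rename(
                columns={"gfp_score": f"gfp_score_{i}"}
            ),
            on="variant",
        )
    cols = [c for c in merged.columns if c.startswith("gfp_score_")]
    out = merged[["variant"]].copy()
    out["gfp_score"] = merged[cols].mean(axis=1)
    out["gfp_score_sd"] = merged[cols].std(axis=1, ddof=1) if len(cols) > 1 else 0.0
    return out
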
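"""Fragment-to-bin counting, background subtraction and quantile normalization.

The preprocessing chain is fixed: count fragments per bin (by midpoint), then
subtract a per-sample background level estimated from low-coverage bins, then
quantile-normalize across samples. Normalized values are rounded half-to-even
back to integers before negative-binomial testing, which consumes counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BinGrid

CONDITIONS = ("control", "case")


@dataclass
class CountMatrix:
    """Features x samples counts with a sample-to-condition map.

    ``features`` carries one row per feature (bins: chrom/start/end; genes:
    gene_id); ``values`` the numeric matrix with one column per sample.
    """

    features: pd.DataFrame
    values: pd.DataFrame
    conditions: dict[str, str]
    normalized: bool = False

    def __post_init__(self):
        if len(self.features) != len(self.values):
            raise ValueError("features and values row counts differ")
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        bad = {c for c in self.conditions.values()} - set(CONDITIONS)
        if bad:
            raise ValueError(f"conditions must be control/case, got {bad}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in count matrix")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]


@dataclass(frozen=True)
class BackgroundLevel:
    """Mean tags per bin among bins below the tag threshold, for one sample."""

    level: float
    threshold: int = 20
    n_bins_used: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("background level must be >= 0")


def count_fragments_per_bin(fragments: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    """Integer counts per grid bin; each fragment goes to its midpoint's bin.

    ``fragments`` needs columns chrom/start/end with half-open coordinates.
    Fragments on unknown chromosomes or outside the genome raise.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    if len(fragments) == 0:
        return counts
    mid = (
        fragments["start"].to_numpy(np.int64) + fragments["end"].to_numpy(np.int64)
    ) // 2
    for chrom, idx in fragments.groupby("chrom", sort=False).indices.items():
        if chrom not in grid.genome:
            raise ValueError(f"fragment on unknown chromosome {chrom}")
        bins = grid.bin_index(chrom, mid[idx])
        counts += np.bincount(bins, minlength=grid.n_bins)
    return counts


def estimate_background(
    raw_column: np.ndarray, threshold: int = 20
) -> BackgroundLevel:
    """Mean count among bins with fewer than ``threshold`` tags.

    Degenerate case (no bin below threshold) yields level 0 with a warning.
    """
    col = np.asarray(raw_column)
    low = col[col < threshold]
    if low.size == 0:
        warnings.warn(
            f"no bin below {threshold} tags; background set to 0", stacklevel=2
        )
        return BackgroundLevel(0.0, threshold, 0)
    return BackgroundLevel(float(low.mean()), threshold, int(low.size))


def subtract_background(
    raw_column: np.ndarray, bg: BackgroundLevel | float
) -> np.ndarray:
    """Per-bin ``max(raw - background, 0)``; zero floor keeps counts meaningful."""
    level = bg.level if isinstance(bg, BackgroundLevel) else float(bg)
    if level < 0:
        raise ValueError("background must be >= 0")
    return np.maximum(np.asarray(raw_column, dtype=float) - level, 0.0)


def quantile_normalize(matrix: pd.DataFrame, ties: str = "stable") -> pd.DataFrame:
    """Map every sample onto the mean of the per-sample order statistics.

    ``ties="stable"`` (default) assigns tied values consecutive reference
    values in stable (input) order; every sample then carries exactly the
    reference multiset and renormalizing is an exact no-op. ``ties="average"``
    instead gives every member of a tied run the mean of the reference values
    spanning its ranks — statistically symmetric, but on tied data the
    per-sample multisets then differ slightly and the map is not idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if ties not in ("stable", "average"):
        raise ValueError("ties must be 'stable' or 'average'")
    X = matrix.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        if ties == "stable":
            out[order, j] = ref
        else:
            xs = col[order]
            run_id = np.concatenate([[0], np.cumsum(np.diff(xs) != 0)])
            run_mean = np.bincount(run_id, weights=ref) / np.bincount(run_id)
            out[order, j] = run_mean[run_id]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def bin_count_matrix(
    fragments_by_sample: dict[str, pd.DataFrame],
    grid: BinGrid,
    conditions: dict[str, str],
) -> CountMatrix:
    """Raw bin x sample count matrix from per-sample fragment tables."""
    values = pd.DataFrame(
        {
            sample: count_fragments_per_bin(frags, grid)
            for sample, frags in fragments_by_sample.items()
        }
    )
    return CountMatrix(grid.to_frame(), values, dict(conditions), normalized=False)


def normalize_counts(
    cm: CountMatrix, background_threshold: int = 20
) -> tuple[CountMatrix, pd.DataFrame]:
    """Background-subtract, quantile-normalize and round a raw count matrix.

    Returns the normalized matrix (integer counts, ``normalized=True``) and a
    per-sample background report.
    """
    report_rows = []
    subtracted = {}
    for sample in cm.samples:
        col = cm.values[sample].to_numpy()
        bg = estimate_background(col, background_threshold)
        subtracted[sample] = subtract_background(col, bg)
        report_rows.append(
            dict(
                sample=sample,
                background=bg.level,
                threshold=bg.threshold,
                n_bins_used=bg.n_bins_used,
            )
        )
    sub = pd.DataFrame(subtracted, index=cm.values.index)
    normed = quantile_normalize(sub)
    rounded = pd.DataFrame(
        np.rint(normed.to_numpy()),
        index=normed.index,
        columns=normed.columns,
    )
    out = CountMatrix(cm.features, rounded, dict(cm.conditions), normalized=True)
    return out, pd.DataFrame(report_rows)
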
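"""Binned, normalized read-coverage tracks over repeat annotations.

Annotated regions (satellite arrays, TE insertions) are tiled into fixed
1-kb bins; per-bin per-base median depth is normalized to each sample's
genome-wide median depth, so a diploid-neutral bin sits near 1.0.  Coverage
dispersion between sample groups is compared with Levene's test.

Medians are "lower medians": on an even number of values the smaller middle
value is taken, so integer depths stay integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io import GenomicInterval

DEFAULT_BIN_WIDTH = 1000  # bp


@dataclass
class BinnedTrack:
    """Fixed-width bins with one value per bin per sample (NaN = missing)."""

    bins: list[GenomicInterval]
    values: pd.DataFrame  # rows = bins (positional), columns = sample ids

    def __post_init__(self):
        if len(self.values) != len(self.bins):
            raise ValueError("value rows must match bin count")

    @property
    def missing(self) -> pd.DataFrame:
        return self.values.isna()


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def make_bins(
    regions: Sequence[GenomicInterval],
    width: int = DEFAULT_BIN_WIDTH,
    partial: str = "merge",
) -> list[GenomicInterval]:
    """Tile each region into ``width``-bp bins, inheriting the region label.

    The final remainder shorter than ``width`` is, under the default
    ``partial="merge"`` dialect, merged into the previous bin when it is
    no longer than ``width/2`` and kept as its own bin otherwise; under
    ``partial="keep"`` every remainder is kept as its own bin.  A region
    shorter than ``width`` is always a single bin.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if partial not in {"merge", "keep"}:
        raise ValueError("partial must be 'merge' or 'keep'")
    bins: list[GenomicInterval] = []
    for region in regions:
        edges = list(range(region.start, region.end, width)) + [region.end]
        spans = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        if (
            partial == "merge"
            and len(spans) > 1
            and spans[-1][1] - spans[-1][0] <= width / 2
        ):
            last = spans.pop()
            spans[-1] = (spans[-1][0], last[1])
        bins.extend(GenomicInterval(region.chrom, s, e, region.label) for s, e in spans)
    return bins


# ---------------------------------------------------------------------------
# depth statistics
# ---------------------------------------------------------------------------

def _weighted_lower_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower median of a per-base expansion given interval weights."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    total = int(w.sum())
    if total == 0:
        raise ValueError("no covered bases")
    k = (total + 1) // 2  # 1-based rank of the lower median
    idx = int(np.searchsorted(np.cumsum(w), k))
    return float(v[idx])


def genome_median_depth(depth: pd.DataFrame) -> float:
    """Genome-wide per-base median depth (length-weighted across intervals)."""
    if len(depth) == 0:
        raise ValueError("empty depth track")
    values = depth["depth"].to_numpy(dtype=float)
    weights = (depth["end"] - depth["start"]).to_numpy(dtype=np.int64)
    return _weighted_lower_median(values, weights)


def bin_median_depth(depth: pd.DataFrame, bins: Sequence[GenomicInterval]) -> np.ndarray:
    """Per-base median depth within each bin; NaN where no depth overlaps."""
    out = np.full(len(bins), np.nan)
    for chrom, sub in depth.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        depths = sub["depth"].to_numpy(float)
        order = np.argsort(starts, kind="stable")
        starts, ends, depths = starts[order], ends[order], depths[order]
        for i, b in enumerate(bins):
            if b.chrom != chrom:
                continue
            lo = int(np.searchsorted(ends, b.start, side="right"))
            hi = int(np.searchsorted(starts, b.end, side="left"))
            if lo >= hi:
                continue
            ov = np.minimum(ends[lo:hi], b.end) - np.maximum(starts[lo:hi], b.start)
            mask = ov > 0
            if mask.any():
                out[i] = _weighted_lower_median(depths[lo:hi][mask], ov[mask])
    return out


def normalize_depth(bin_medians: np.ndarray, genome_median: float) -> np.ndarray:
    """Normalize per-bin medians to the sample's genome-wide median."""
    if genome_median <= 0:
        raise ValueError("genome-wide median depth must be positive; sample unusable")
    return np.asarray(bin_medians, dtype=float) / genome_median


def per_insertion_depth(
    depth: pd.DataFrame,
    insertions: Sequence[GenomicInterval],
    genome_median: float,
) -> np.ndarray:
    """Normalized per-base median depth over each whole insertion (AluY mode)."""
    return normalize_depth(bin_median_depth(depth, insertions), genome_median)


# ---------------------------------------------------------------------------
# annotation filters
# ---------------------------------------------------------------------------

#: full-length thresholds (strict >, bp) used for TE insertion selection
TE_LENGTH_THRESHOLDS = {"L1HS": 6000, "AluY": 300, "SVA": 1000, "ERV": 1000}


def filter_te_annotation(
    annotation: Sequence[GenomicInterval],
    te_class: str,
    min_length: int | None = None,
) -> list[GenomicInterval]:
    """Select full-length insertions of one TE class: length strictly greater
    than ``min_length`` (default: the class's standard threshold)."""
    known = sorted({iv.label for iv in annotation})
    if te_class not in known:
        raise ValueError(f"unknown class {te_class!r}; annotation has {known}")
    if min_length is None:
        if te_class not in TE_LENGTH_THRESHOLDS:
            raise ValueError(f"no default length threshold for {te_class!r}")
        min_length = TE_LENGTH_THRESHOLDS[te_class]
    return [iv for iv in annotation if iv.label == te_class and iv.length > min_length]


# ---------------------------------------------------------------------------
# group dispersion
# ---------------------------------------------------------------------------

def compare_variance(
    values_a: Sequence[float],
    values_b: Sequence[float],
    center: str = "mean",
) -> tuple[float, float]:
    """Levene's test for equality of variances between two groups.

    Classic Levene centers absolute deviations at the group mean
    (``center="median"`` gives the Brown–Forsythe variant).  Returns the W
    statistic and its p-value from F(1, n_a + n_b - 2).  Missing values are
    dropped; two groups whose deviation spread is degenerate (W = 0/0)
    return (0.0, 1.0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if center not in {"mean", "median"}:
        raise ValueError("center must be 'mean' or 'median'")
    loc = np.mean if center == "mean" else np.median
    za = np.abs(a - loc(a))
    zb = np.abs(b - loc(b))
    n_a, n_b = len(za), len(zb)
    n = n_a + n_b
    zbar = (za.sum() + zb.sum()) / n
    num = (n - 2) * (n_a * (za.mean() - zbar) ** 2 + n_b * (zb.mean() - zbar) ** 2)
    den = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    if num == 0:
        return 0.0, 1.0
    if den == 0:
        return float("inf"), 0.0
    w = num / den
    p = float(scipy.stats.f.sf(w, 1, n - 2))
    return float(w), p
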
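"""Binned CpG methylation, cohort matrix, PCA / Ward clustering, group tests.

The central quantity is the average 5mC ratio per 1-kb bin, computed as the
coverage-weighted pooled ratio sum(n_mod) / sum(n_valid) over the CpG sites
falling in the bin (an unweighted mean of site ratios is available via
``method="mean_of_sites"``).  Bin x sample matrices over satellite classes
feed PCA (samples as observations, centered, unscaled) and Ward
hierarchical clustering; tumor groups are assigned by HRD score against a
fixed cutoff and compared with t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats
from sklearn.decomposition import PCA

from .io import GenomicInterval, SampleMeta

logger = logging.getLogger(__name__)

HRD_CUTOFF = 63  # score >= cutoff defines the high-HRD group


@dataclass(frozen=True)
class HrdGroupLabel:
    sample_id: str
    group: str  # {"high", "low"}
    score: int


@dataclass
class MethylationMatrix:
    """Bins x samples mean-5mC matrix with per-bin class labels."""

    bins: list[GenomicInterval]
    values: pd.DataFrame  # index: bin key strings; columns: sample ids

    @property
    def classes(self) -> pd.Series:
        return pd.Series([b.label for b in self.bins], index=self.values.index)


def _bin_key(b: GenomicInterval) -> str:
    return f"{b.chrom}:{b.start}-{b.end}"


# ---------------------------------------------------------------------------
# per-bin methylation
# ---------------------------------------------------------------------------

def bin_methylation(
    records: pd.DataFrame,
    bins: Sequence[GenomicInterval],
    method: str = "pooled",
) -> np.ndarray:
    """Average 5mC ratio per bin over the CpG sites it contains.

    ``method="pooled"`` returns sum(n_mod)/sum(n_valid) (read-weighted);
    ``method="mean_of_sites"`` averages per-site ratios of covered sites.
    A site belongs to the bin containing its start.  Bins with no covered
    site are NaN, never zero.
    """
    if method not in {"pooled", "mean_of_sites"}:
        raise ValueError("method must be 'pooled' or 'mean_of_sites'")
    out = np.full(len(bins), np.nan)
    for chrom, sub in records.groupby("chrom", sort=False):
        pos = sub["start"].to_numpy(np.int64)
        n_valid = sub["n_valid"].to_numpy(np.int64)
        n_mod = sub["n_mod"].to_numpy(np.int64)
        order = np.argsort(pos, kind="stable")
        pos, n_valid, n_mod = pos[order], n_valid[order], n_mod[order]
        cum_valid = np.concatenate([[0], np.cumsum(n_valid)])
        cum_mod = np.concatenate([[0], np.cumsum(n_mod)])
        for i, b in enumerate(bins):
            if b.chrom != chrom:
                continue
            lo = int(np.searchsorted(pos, b.start, side="left"))
            hi = int(np.searchsorted(pos, b.end, side="left"))
            if lo >= hi:
                continue
            if method == "pooled":
                valid = cum_valid[hi] - cum_valid[lo]
                if valid > 0:
                    out[i] = (cum_mod[hi] - cum_mod[lo]) / valid
            else:
                v, m = n_valid[lo:hi], n_mod[lo:hi]
                covered = v > 0
                if covered.any():
                    out[i] = float(np.mean(m[covered] / v[covered]))
    return out


def genome_cpg_summary(records: pd.DataFrame, min_valid: int = 1) -> pd.Series:
    """Distribution summary of site-level 5mC ratios across the genome.

    Sites with ``n_valid < min_valid`` are excluded (default 1, i.e. any
    covered site counts).
    """
    if len(records) == 0:
        raise ValueError("empty record collection")
    covered = records[records["n_valid"] >= max(min_valid, 1)]
    ratios = covered["n_mod"].to_numpy(float) / covered["n_valid"].to_numpy(float)
    q1, q2, q3 = np.percentile(ratios, [25, 50, 75]) if len(ratios) else (np.nan,) * 3
    return pd.Series(
        {
            "n_sites": float(len(ratios)),
            "mean": float(np.mean(ratios)) if len(ratios) else np.nan,
            "q25": float(q1),
            "median": float(q2),
            "q75": float(q3),
        }
    )


def build_methylation_matrix(
    per_sample: Mapping[str, np.ndarray],
    bins: Sequence[GenomicInterval],
    classes: Sequence[str] = ("active_hor", "inactive_hor"),
) -> MethylationMatrix:
    """Assemble the bin x sample matrix restricted to the requested classes.

    Rows (bins) with a missing value in any sample are dropped
    (complete-case); the dropped count is logged.  At least two samples and
    one surviving row are required.
    """
    if len(per_sample) < 2:
        raise ValueError("need >= 2 samples")
    keep_idx = [i for i, b in enumerate(bins) if b.label in set(classes)]
    kept_bins = [bins[i] for i in keep_idx]
    data = {s: np.asarray(v, dtype=float)[keep_idx] for s, v in per_sample.items()}
    df = pd.DataFrame(data, index=[_bin_key(b) for b in kept_bins])
    complete = ~df.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d bin(s) with missing values (complete-case)", n_dropped)
    df = df.loc[complete]
    final_bins = [b for b, ok in zip(kept_bins, complete) if ok]
    if len(df) == 0:
        raise ValueError("no bins survive complete-case filtering")
    return MethylationMatrix(final_bins, df)


# ---------------------------------------------------------------------------
# ordination and clustering
# ---------------------------------------------------------------------------

def run_pca(matrix: MethylationMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with samples as observations and bins as (centered, unscaled)
    features.

    Returns per-sample coordinates and explained-variance fractions.  Sign
    is fixed per component so the largest-magnitude feature loading is
    positive.  A constant matrix yields all-zero coordinates (no crash).
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x bins
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    n_components = min(n_components, n_samples, X.shape[1])
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        coords = np.zeros((n_samples, n_components))
        ev = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        coords = pca.fit_transform(X)
        # deterministic sign: largest-|loading| feature positive
        for j in range(n_components):
            loading = pca.components_[j]
            if loading[np.argmax(np.abs(loading))] < 0:
                coords[:, j] *= -1
        ev = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=matrix.values.columns, columns=cols), ev


def ward_cluster(matrix: MethylationMatrix, k: int = 2) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of samples with Ward linkage on Euclidean
    distances between sample columns.

    Returns the k-cluster partition (labels relabeled by first appearance in
    column order, so the partition is invariant to sample ordering up to
    label names) and the scipy linkage matrix.
    """
    samples = list(matrix.values.columns)
    if k > len(samples):
        raise ValueError(f"k={k} exceeds sample count {len(samples)}")
    X = matrix.values.to_numpy(dtype=float).T
    Z = scipy.cluster.hierarchy.linkage(X, method="ward")
    raw = scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=samples, name="cluster"), Z


def hrd_group(
    metas: Sequence[SampleMeta],
    cutoff: int = HRD_CUTOFF,
) -> list[HrdGroupLabel]:
    """Label tumor samples high/low by HRD score against the cutoff
    (high iff score >= cutoff)."""
    labels = []
    for m in metas:
        if m.group != "tumor":
            continue
        if m.hrd_score is None:
            raise ValueError(f"sample {m.sample_id}: HRD score missing")
        labels.append(
            HrdGroupLabel(m.sample_id, "high" if m.hrd_score >= cutoff else "low", m.hrd_score)
        )
    return labels


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def group_mean_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided Student t-test between two groups (equal-variance when
    unpaired; paired requires matched order and equal length).

    Zero variance in both groups with equal means returns (0.0, 1.0) rather
    than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if paired:
        if len(values_a) != len(values_b):
            raise ValueError("paired test requires equal-length, matched groups")
        pair = np.column_stack([np.asarray(values_a, float), np.asarray(values_b, float)])
        pair = pair[~np.isnan(pair).any(axis=1)]
        a, b = pair[:, 0], pair[:, 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if paired:
        diff = a - b
        if np.all(diff == diff[0]):
            if diff[0] == 0:
                return 0.0, 1.0
            return float("inf") if diff[0] > 0 else float("-inf"), 0.0
        t, p = scipy.stats.ttest_rel(a, b)
    else:
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                return 0.0, 1.0
            return float("inf") if np.mean(a) > np.mean(b) else float("-inf"), 0.0
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
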
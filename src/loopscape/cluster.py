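"""Pairwise-correlation clustering of feature-by-sample matrices and
purity/entropy scoring against known class labels.

Samples are correlated feature-wise with pairwise-complete Pearson (each
sample pair uses only features observed in both), clustered hierarchically on
distance 1 - r, and the tree is cut at k = the number of unique class labels.
Purity and entropy then quantify how well clusters align with the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genome import GenomicInterval, overlap_map

logger = logging.getLogger(__name__)


@dataclass
class ClusterEval:
    correlation: pd.DataFrame
    labels: pd.Series  # cluster assignment per sample
    purity: Optional[float]
    entropy: Optional[float]
    n_features: int


def purity_entropy(
    cluster_labels: Sequence, true_labels: Sequence
) -> tuple[float, float]:
    """External clustering indices against known classes.

    purity = (1/n) * sum_k max_j n_kj;
    entropy = -(1 / (n log2 C)) * sum_k sum_j n_kj log2(n_kj / n_k),
    where C is the number of true classes and n_k the size of cluster k.
    Perfect clustering gives (1, 0); a single cluster over two balanced
    classes gives (0.5, 1).
    """
    cluster_labels = list(cluster_labels)
    true_labels = list(true_labels)
    if len(cluster_labels) != len(true_labels):
        raise ValueError("label vectors must have equal length")
    n = len(true_labels)
    classes = sorted(set(true_labels))
    C = len(classes)
    if C < 2:
        raise ValueError("entropy undefined with a single true class")
    ct = pd.crosstab(pd.Series(cluster_labels), pd.Series(true_labels))
    purity = float(ct.max(axis=1).sum() / n)
    entropy = 0.0
    for _, row in ct.iterrows():
        n_k = row.sum()
        for n_kj in row:
            if n_kj > 0:
                entropy -= n_kj * np.log2(n_kj / n_k)
    entropy /= n * np.log2(C)
    return purity, float(entropy)


def correlation_cluster(
    matrix: pd.DataFrame,
    labels: Optional[pd.Series] = None,
    feature_intervals: Optional[Sequence[GenomicInterval]] = None,
    excluded_regions: Sequence[GenomicInterval] = (),
    excluded_chroms: Sequence[str] = ("chrX", "chrY"),
    min_count: float = 3.0,
    min_samples: int = 2,
    prior: float = 1.0,
    n_clusters: Optional[int] = None,
    method: str = "complete",
) -> ClusterEval:
    """Hierarchical clustering of samples on pairwise-complete correlation.

    Features on excluded chromosomes or overlapping blacklist regions are
    dropped (when ``feature_intervals`` is given), then features must reach a
    normalized count >= ``min_count`` in >= ``min_samples`` samples. Values
    are log2(x + prior)-transformed. Missing values are handled by
    pairwise-complete Pearson; the tree (1 - r, ``method`` linkage) is cut at
    k = number of unique labels (or ``n_clusters``).
    """
    mat = matrix.copy()
    if feature_intervals is not None:
        if len(feature_intervals) != mat.shape[0]:
            raise ValueError("feature_intervals must match matrix rows")
        keep_mask = np.array(
            [iv.chrom not in excluded_chroms for iv in feature_intervals]
        )
        if len(excluded_regions):
            kept_idx = [i for i, k in enumerate(keep_mask) if k]
            hits = overlap_map(
                [feature_intervals[i] for i in kept_idx], list(excluded_regions)
            )
            for local_q in hits:
                keep_mask[kept_idx[local_q]] = False
        mat = mat.loc[keep_mask]

    reproducible = (mat >= min_count).sum(axis=1) >= min_samples
    mat = mat.loc[reproducible]
    if mat.shape[0] == 0:
        raise ValueError("no reproducible features remain after filtering")
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples")

    logged = np.log2(mat + prior)
    corr = logged.corr(method="pearson", min_periods=3)
    if corr.isna().any().any():
        bad = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if pd.isna(corr.at[a, b])
        ]
        raise ValueError(
            f"sample pairs with < 3 mutually observed features: {bad[:5]}"
        )

    if n_clusters is None:
        if labels is None:
            raise ValueError("provide labels or n_clusters to cut the tree")
        n_clusters = labels.nunique()
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard float asymmetry
    Z = linkage(squareform(dist, checks=False), method=method)
    assign = pd.Series(
        fcluster(Z, t=n_clusters, criterion="maxclust"),
        index=matrix.columns,
        name="cluster",
    )

    purity = entropy = None
    if labels is not None:
        purity, entropy = purity_entropy(
            assign.to_numpy(), labels.loc[assign.index].to_numpy()
        )
    return ClusterEval(
        correlation=corr,
        labels=assign,
        purity=purity,
        entropy=entropy,
        n_features=int(mat.shape[0]),
    )
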
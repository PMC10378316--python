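"""Unsupervised two-group clustering of samples and accuracy scoring.

Samples are clustered on a chosen marker subset with average-linkage
agglomerative clustering on correlation distance (1 - Pearson between
sample profiles), the common microarray-heatmap convention. The tree is
cut at its root split into exactly two groups, mirroring the binary
tumor-vs-normal reading of a clustered heatmap, and accuracy against known
labels is the best of the two possible cluster-to-label mappings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ValidationError

__all__ = ["ClusterAssignment", "hcluster_two_groups", "clustering_accuracy"]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> 0/1
    linkage: np.ndarray  # scipy linkage matrix over the ordered samples
    sample_order: list[str]


def _correlation_distance(values: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between sample columns.

    Zero-variance samples have undefined correlation; those entries are
    treated as distance 0 so degenerate inputs cluster deterministically.
    """
    X = values.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    dist = 1.0 - np.nan_to_num(corr, nan=1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return dist


def hcluster_two_groups(
    matrix: ExpressionMatrix,
    features=None,
    metric: str = "correlation",
    method: str = "average",
) -> ClusterAssignment:
    """Cluster samples into two groups on the given feature subset."""
    if features is not None:
        features = list(features)
        if not features:
            raise ValidationError("empty feature subset")
        matrix = matrix.subset_features(features)
    if matrix.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    # lexicographic sample order makes equal-distance merges deterministic
    order = sorted(matrix.sample_ids)
    values = matrix.values[order]
    if metric == "correlation":
        dist = _correlation_distance(values)
    elif metric == "euclidean":
        diff = values.to_numpy(float)
        dist = np.sqrt(
            ((diff.T[:, None, :] - diff.T[None, :, :]) ** 2).sum(axis=2)
        )
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(flat)) == 1:
        # fully degenerate tree (all heights equal/zero): single cluster
        labels = pd.Series(0, index=order)
    else:
        labels = pd.Series(flat - int(flat.min()), index=order)
    return ClusterAssignment(labels=labels, linkage=Z, sample_order=order)


def clustering_accuracy(assignment: ClusterAssignment, labels: pd.Series) -> float:
    """Best-of-two-mappings agreement between clusters and binary labels."""
    assigned = assignment.labels
    labels = labels.reindex(assigned.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()][0]
        raise ValidationError(f"no label for sample {missing!r}")
    values = sorted(labels.unique())
    if len(values) > 2:
        raise ValidationError(f"expected <= 2 label values, got {values}")
    if len(values) == 1:
        mapped = (labels == values[0]).astype(int)
        return float(max((assigned == mapped).mean(), (assigned != mapped).mean()))
    truth = (labels == values[1]).astype(int)
    acc_direct = (assigned == truth).mean()
    acc_flipped = (assigned == 1 - truth).mean()
    return float(max(acc_direct, acc_flipped))
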
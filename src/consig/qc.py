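"""Unsupervised QC: hierarchical clustering of samples and PCA variance.

Mirrors the usual microarray quality check: complete-linkage euclidean
clustering of samples (case and control should split into two clusters when
the signature carries signal) and the PCA variance spectrum (a dominant
first component, typically more than twice the second, indicates a strong
common axis of variation).  Samples that join the tree unusually late —
merge height above median + 3 x MAD — are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import DegenerateDataError


def hierarchical_cluster(matrix: pd.DataFrame) -> np.ndarray:
    """Complete-linkage euclidean clustering of rows (samples).

    Returns the scipy linkage matrix; merge heights are non-decreasing.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    if not np.isfinite(X).all():
        raise DegenerateDataError("missing values must be handled before clustering")
    return linkage(pdist(X, metric="euclidean"), method="complete")


def pca_variance_fractions(matrix: pd.DataFrame, n_components: int) -> np.ndarray:
    """Fractions of total variance per principal component, descending.

    PCA of samples (rows) over genes (columns) with gene-wise mean
    centering and no scaling.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(Xc, compute_uv=False)
    total = float(np.sum(sv**2))
    if total <= 0:
        raise DegenerateDataError("zero total variance")
    fractions = (sv**2) / total
    return fractions[:n_components]


def merge_heights(tree: np.ndarray, n_samples: int) -> np.ndarray:
    """Height at which each original sample first joins a cluster."""
    heights = np.full(n_samples, np.nan)
    for a, b, height, _ in tree:
        for node in (int(a), int(b)):
            if node < n_samples and np.isnan(heights[node]):
                heights[node] = height
    return heights


def flag_outliers(tree: np.ndarray, sample_ids: list[str]) -> list[str]:
    """Samples whose first merge height exceeds median + 3 x MAD.

    The rule is applied to log merge heights with the normal-consistent
    MAD (x 1.4826): nearest-merge distances are right-skewed, and the raw
    scale flags samples even in homogeneous clouds.  Needs at least 3
    samples; with fewer the MAD rule is undefined and nothing is flagged.
    """
    n = len(sample_ids)
    if n < 3:
        return []
    heights = np.log(merge_heights(tree, n) + 1e-12)
    med = float(np.median(heights))
    mad = 1.4826 * float(np.median(np.abs(heights - med)))
    cutoff = med + 3.0 * mad
    return [sid for sid, h in zip(sample_ids, heights) if h > cutoff and mad > 0]


def _two_cluster_agreement(labels: np.ndarray, classes: np.ndarray) -> float:
    """Best fraction of samples matched over the two label permutations."""
    classes = np.asarray(classes)
    a = float(np.mean((labels == 1) == (classes == classes[0])))
    return max(a, 1.0 - a)


@dataclass
class QCReport:
    """Clustering/PCA quality summary for a pooled sample matrix."""

    tree: np.ndarray
    two_cluster_labels: pd.Series
    cluster_vs_class_agreement: float
    pc_variance_fractions: np.ndarray
    pc1_pc2_ratio: float
    outlier_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "two_cluster_sizes": self.two_cluster_labels.value_counts()
            .sort_index()
            .to_dict(),
            "cluster_vs_class_agreement": round(self.cluster_vs_class_agreement, 6),
            "pc_variance_fractions": [
                round(float(f), 6) for f in self.pc_variance_fractions
            ],
            "pc1_pc2_ratio": round(self.pc1_pc2_ratio, 6),
            "outlier_samples": self.outlier_samples,
        }


def qc_report(
    matrix: pd.DataFrame, sample_class: pd.Series, n_components: int = 5
) -> QCReport:
    """Run clustering + PCA QC on a samples x genes matrix."""
    tree = hierarchical_cluster(matrix)
    labels = fcluster(tree, t=2, criterion="maxclust")
    classes = sample_class.reindex(matrix.index).to_numpy()
    agreement = _two_cluster_agreement(labels, classes)
    n_components = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
    fractions = pca_variance_fractions(matrix, n_components)
    ratio = float(fractions[0] / fractions[1]) if len(fractions) > 1 else np.inf
    return QCReport(
        tree=tree,
        two_cluster_labels=pd.Series(labels, index=matrix.index),
        cluster_vs_class_agreement=agreement,
        pc_variance_fractions=fractions,
        pc1_pc2_ratio=ratio,
        outlier_samples=flag_outliers(tree, list(matrix.index)),
    )
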
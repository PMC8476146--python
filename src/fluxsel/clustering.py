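"""Clustering of scaled piecewise-fitness profiles of oscillatory genotypes.

Genotypes whose frequencies oscillate with the environmental period are not a
uniform group: they differ in phase and amplitude of their short-term fitness
profile.  Z-scoring each genotype's piecewise fitness across intervals removes
amplitude and baseline, and Ward-linkage agglomerative clustering on the
scaled profiles groups the phase/shape archetypes (four clusters by default).
Labels are renumbered by the position of each cluster centroid's peak interval
so the numbering is stable across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

__all__ = ["ClusterResult", "scale_profiles", "cluster_profiles"]


@dataclass
class ClusterResult:
    """Cluster assignment of scaled piecewise-fitness profiles."""

    labels: pd.Series           # genotype_id -> cluster label in 1..k
    scaled: pd.DataFrame        # z-scored profiles (genotypes x intervals)
    centroids: pd.DataFrame     # cluster label x intervals
    linkage: np.ndarray
    silhouette: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(self.labels.max())


def scale_profiles(piecewise: pd.DataFrame, subset=None) -> tuple[pd.DataFrame, pd.Series]:
    """Z-score each genotype's piecewise-fitness profile across intervals.

    ``subset`` restricts the rows (e.g. to the periodic-class genotypes).
    Rows are centered to mean 0 and scaled to sample SD 1; constant profiles
    cannot be scaled and become all-zero rows, flagged in the returned
    boolean series.  Scaling is idempotent on already-scaled rows.
    """
    mat = piecewise.loc[subset] if subset is not None else piecewise
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 intervals to scale a profile")
    if mat.shape[0] == 0:
        raise ValueError("empty genotype subset")
    vals = mat.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True, ddof=1)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[constant] = 1.0
    scaled = (vals - mean) / sd
    scaled[np.isnan(scaled)] = 0.0
    return (pd.DataFrame(scaled, index=mat.index, columns=mat.columns),
            pd.Series(constant, index=mat.index, name="constant_profile"))


def cluster_profiles(scaled: pd.DataFrame, k: int = 4) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of scaled profiles cut at ``k``.

    Deterministic given the input. Labels are renumbered by the centroid's
    peak (argmax) interval so cluster 1 peaks earliest.  A silhouette score is
    reported when 2 <= k < n_rows.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(scaled) < k:
        raise ValueError(f"cannot form {k} clusters from {len(scaled)} profiles")
    x = scaled.to_numpy(dtype=float)
    z = linkage(x, method="ward", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    # stable renumbering: order clusters by the argmax interval of the centroid
    order = {}
    for label in np.unique(raw):
        centroid = x[raw == label].mean(axis=0)
        order[label] = (int(np.argmax(centroid)), -float(centroid.max()))
    relabel = {old: new + 1 for new, old in
               enumerate(sorted(order, key=order.get))}
    labels = pd.Series([relabel[v] for v in raw], index=scaled.index,
                       name="cluster")
    centroids = pd.DataFrame(
        {lab: x[labels.to_numpy() == lab].mean(axis=0)
         for lab in sorted(relabel.values())},
        index=scaled.columns,
    ).T
    sil = None
    if 2 <= k < len(scaled) and len(np.unique(labels)) > 1:
        sil = float(silhouette_score(x, labels.to_numpy()))
    return ClusterResult(labels=labels, scaled=scaled, centroids=centroids,
                         linkage=z, silhouette=sil, meta={"k": k})
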
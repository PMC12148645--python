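"""Streamline clustering with the MDF metric and outlier rejection.

QuickBundles is a single-pass clustering of streamlines under the
minimum-average-direct-flip (MDF) distance: both streamlines are resampled
to the same number of equidistant points and compared point-by-point in the
direct and the flipped orientation, taking the smaller mean distance.

The outlier filter runs QuickBundles across a geometric ladder of distance
thresholds and scores each streamline by how often it lands in a cluster
holding at least 5% of the bundle; streamlines whose score falls below
``outlier_alpha`` (default 0.6) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .tractometry import resample_streamline


def mdf_distance(a: np.ndarray, b: np.ndarray, n_points: int = 12) -> float:
    """Minimum average direct-flip distance (mm) between two streamlines."""
    ra = resample_streamline(a, n_points)
    rb = resample_streamline(b, n_points)
    direct = float(np.linalg.norm(ra - rb, axis=1).mean())
    flipped = float(np.linalg.norm(ra - rb[::-1], axis=1).mean())
    return min(direct, flipped)


def _mdf_resampled(ra: np.ndarray, rb: np.ndarray) -> tuple[float, bool]:
    """MDF between pre-resampled arrays; also report whether the flip won."""
    direct = float(np.linalg.norm(ra - rb, axis=1).mean())
    flipped = float(np.linalg.norm(ra - rb[::-1], axis=1).mean())
    return (flipped, True) if flipped < direct else (direct, False)


@dataclass
class Cluster:
    centroid: np.ndarray  # (n_points, 3) running mean
    indices: list[int]

    @property
    def size(self) -> int:
        return len(self.indices)


class QuickBundles(ClusterMixin, BaseEstimator):
    """Single-pass streamline clustering under the MDF metric.

    Streamlines are visited in input order; each joins the first existing
    cluster whose running centroid lies within ``threshold_mm`` (ties go to
    the lowest cluster id), otherwise it founds a new cluster.  Before being
    averaged into the centroid a streamline is flipped to the orientation
    closer to the centroid, so centroids stay coherent.

    Parameters
    ----------
    threshold_mm : float
        MDF distance threshold for joining a cluster.
    n_points : int
        Number of equidistant points used for resampling (the MDF grid).

    Attributes
    ----------
    labels_ : ndarray of shape (n_streamlines,)
        Cluster id per streamline, in founding order.
    clusters_ : list of Cluster
        Centroid and member indices per cluster.
    """

    def __init__(self, threshold_mm: float = 10.0, n_points: int = 12):
        self.threshold_mm = threshold_mm
        self.n_points = n_points

    def fit(self, X: list[np.ndarray], y=None) -> "QuickBundles":
        if self.threshold_mm <= 0:
            raise ValueError("threshold_mm must be positive")
        resampled = [resample_streamline(s, self.n_points) for s in X]
        clusters: list[Cluster] = []
        labels = np.empty(len(resampled), dtype=int)
        for i, r in enumerate(resampled):
            joined = False
            for cid, cluster in enumerate(clusters):
                dist, flip = _mdf_resampled(cluster.centroid, r)
                if dist <= self.threshold_mm:
                    member = r[::-1] if flip else r
                    k = cluster.size
                    cluster.centroid = (cluster.centroid * k + member) / (k + 1)
                    cluster.indices.append(i)
                    labels[i] = cid
                    joined = True
                    break
            if not joined:
                clusters.append(Cluster(centroid=r.copy(), indices=[i]))
                labels[i] = len(clusters) - 1
        self.labels_ = labels
        self.clusters_ = clusters
        self.n_clusters_ = len(clusters)
        return self


def quickbundles(
    streamlines: list[np.ndarray],
    threshold_mm: float,
    n_points: int = 12,
) -> list[Cluster]:
    """Functional wrapper over :class:`QuickBundles`."""
    return QuickBundles(threshold_mm=threshold_mm, n_points=n_points).fit(streamlines).clusters_


def default_threshold_ladder(
    low_mm: float = 2.0, high_mm: float = 16.0, n_levels: int = 8
) -> np.ndarray:
    """Geometric ladder of clustering thresholds spanning [low, high] mm."""
    return np.geomspace(low_mm, high_mm, n_levels)


class StreamlineOutlierFilter(BaseEstimator):
    """Multi-scale QuickBundles outlier rejection for one bundle.

    At each threshold of a geometric ladder the bundle is re-clustered; a
    streamline earns a point when its cluster holds at least
    ``min_cluster_fraction`` of the bundle.  The score is the mean over
    levels, and streamlines scoring below ``outlier_alpha`` are dropped —
    gross outliers sit in tiny clusters at every scale, so their score is 0.

    Attributes
    ----------
    scores_ : ndarray in [0, 1] per streamline.
    keep_mask_ : boolean ndarray, True for retained streamlines.
    """

    def __init__(
        self,
        outlier_alpha: float = 0.6,
        threshold_ladder: np.ndarray | None = None,
        min_cluster_fraction: float = 0.05,
        n_points: int = 12,
    ):
        self.outlier_alpha = outlier_alpha
        self.threshold_ladder = threshold_ladder
        self.min_cluster_fraction = min_cluster_fraction
        self.n_points = n_points

    def fit(self, X: list[np.ndarray], y=None) -> "StreamlineOutlierFilter":
        if len(X) < 2:
            raise ValueError("outlier filtering needs at least 2 streamlines")
        ladder = (
            default_threshold_ladder()
            if self.threshold_ladder is None
            else np.asarray(self.threshold_ladder, dtype=float)
        )
        if ladder.size == 0:
            raise ValueError("threshold ladder is empty")
        n = len(X)
        min_size = self.min_cluster_fraction * n
        scores = np.zeros(n)
        for threshold in ladder:
            qb = QuickBundles(threshold_mm=float(threshold), n_points=self.n_points).fit(X)
            sizes = np.array([c.size for c in qb.clusters_])
            scores += (sizes[qb.labels_] >= min_size).astype(float)
        scores /= ladder.size
        self.scores_ = scores
        self.keep_mask_ = scores >= self.outlier_alpha
        return self

    def fit_predict(self, X: list[np.ndarray], y=None) -> np.ndarray:
        return self.fit(X).keep_mask_


def remove_outliers(
    streamlines: list[np.ndarray],
    outlier_alpha: float = 0.6,
    threshold_ladder: np.ndarray | None = None,
) -> set[int]:
    """Indices of streamlines kept by the multi-scale outlier filter."""
    keep = StreamlineOutlierFilter(
        outlier_alpha=outlier_alpha, threshold_ladder=threshold_ladder
    ).fit_predict(streamlines)
    return set(np.flatnonzero(keep).tolist())
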
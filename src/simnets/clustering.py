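"""k-means clustering of map coordinates with silhouette-based model selection.

The number of putative subnetworks is not known in advance, so k-means is run
for every k in a range and the mean silhouette value (Silhouette Coefficient,
SC) is computed for each partition; the k maximizing SC — denoted Ksc — is
selected, with ties broken toward the smallest k. Silhouettes are computed
with Euclidean distance in map space by default; a precomputed dissimilarity
matrix can be supplied instead (used by the shuffle test's fast mode, where
labels come from k-means on a classical-MDS projection but cohesion/separation
are measured on the CS distances themselves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .embedding import MapCoordinates

__all__ = ["SilhouetteCurve", "ClusterResult", "cluster", "silhouette_curve",
           "select_k"]


@dataclass(frozen=True)
class SilhouetteCurve:
    """Mean silhouette (SC) as a function of candidate cluster number k.

    ``labels_per_k`` keeps the best k-means labeling found for every k
    (1-based cluster ids), so the selected partition can be recovered without
    re-running k-means. ``point_silhouettes`` holds per-point silhouettes at
    the selected k.
    """

    ks: tuple[int, ...]
    mean_sc: np.ndarray
    labels_per_k: dict[int, np.ndarray] = field(repr=False)
    point_silhouettes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "ks", tuple(int(k) for k in self.ks))
        object.__setattr__(self, "mean_sc",
                           np.asarray(self.mean_sc, dtype=np.float64))
        if len(self.ks) != self.mean_sc.size or not self.ks:
            raise ValueError("ks and mean_sc must be non-empty and same length")
        if np.any(self.mean_sc < -1 - 1e-9) or np.any(self.mean_sc > 1 + 1e-9):
            raise ValueError("silhouette values must lie in [-1, 1]")

    def sc_at(self, k: int) -> float:
        return float(self.mean_sc[self.ks.index(k)])


@dataclass(frozen=True)
class ClusterResult:
    """Selected cluster count Ksc, 1-based labels, and the SC achieved."""

    ksc: int
    labels: np.ndarray
    sc: float

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.min() < 1 or labels.max() > self.ksc:
            raise ValueError("labels must lie in [1, Ksc]")
        if len(np.unique(labels)) != self.ksc:
            raise ValueError("every cluster must be non-empty")


def _coords_array(coords) -> np.ndarray:
    if isinstance(coords, MapCoordinates):
        return coords.values
    x = np.asarray(coords, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("coordinates must be 2-D (points x dims)")
    return x


def cluster(coords, k: int, restarts: int = 20, seed: int = 0) -> ClusterResult:
    """Best-of-``restarts`` k-means partition at a fixed k (k-means++ seeding).

    Deterministic for a fixed seed. k = 1 is rejected: the silhouette that
    validates the partition is undefined for a single cluster.
    """
    x = _coords_array(coords)
    if k < 2:
        raise ValueError("k must be >= 2 (silhouette undefined for k = 1)")
    if k > x.shape[0] - 1:
        raise ValueError(f"k = {k} too large for {x.shape[0]} points")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels0 = km.fit_predict(x)
    sil = silhouette_samples(x, labels0)
    return ClusterResult(ksc=k, labels=labels0 + 1, sc=float(sil.mean()))


def silhouette_curve(
    coords,
    k_range=None,
    restarts: int = 20,
    seed: int = 0,
    dissimilarity: np.ndarray | None = None,
) -> SilhouetteCurve:
    """Silhouette curve over a k range with k-means labelings.

    For each k, the best of ``restarts`` k-means++ runs (by inertia, all
    drawn from one seeded RNG stream) provides labels; the mean silhouette is
    computed in Euclidean map space, or on ``dissimilarity`` (a precomputed
    square matrix over the same points) if given. ``k_range`` is an inclusive
    ``(k_min, k_max)`` pair, default ``(2, min(20, P - 1))``; a k_max at or
    above the point count is clamped with a warning.
    """
    x = _coords_array(coords)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to cluster")
    if np.ptp(x, axis=0).max() <= 1e-12:
        raise ValueError(
            "all points are identical: no cluster structure to evaluate"
        )
    if k_range is None:
        k_range = (2, min(20, n - 1))
    k_min, k_max = int(k_range[0]), int(k_range[-1])
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max >= n:
        warnings.warn(
            f"k_max = {k_max} >= {n} points; clamped to {n - 1}", stacklevel=2
        )
        k_max = n - 1
    if k_max < k_min:
        raise ValueError(f"empty k range ({k_min}..{k_max})")

    if dissimilarity is not None:
        dissimilarity = np.asarray(dissimilarity, dtype=np.float64)
        if dissimilarity.shape != (n, n):
            raise ValueError("dissimilarity must be square over the same points")

    ks = list(range(k_min, k_max + 1))
    means = np.empty(len(ks))
    labels_per_k: dict[int, np.ndarray] = {}
    sil_per_k: dict[int, np.ndarray] = {}
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels0 = km.fit_predict(x)
        if len(np.unique(labels0)) < k:  # collapsed solution on degenerate data
            means[i] = -1.0
            labels_per_k[k] = labels0 + 1
            sil_per_k[k] = np.full(n, -1.0)
            continue
        if dissimilarity is not None:
            sil = silhouette_samples(dissimilarity, labels0, metric="precomputed")
        else:
            sil = silhouette_samples(x, labels0)
        means[i] = sil.mean()
        labels_per_k[k] = labels0 + 1
        sil_per_k[k] = sil

    best_k = ks[int(np.argmax(means))]  # first max -> smallest k on ties
    return SilhouetteCurve(
        ks=tuple(ks),
        mean_sc=means,
        labels_per_k=labels_per_k,
        point_silhouettes=sil_per_k[best_k],
    )


def select_k(curve: SilhouetteCurve) -> int:
    """Ksc: the k with the highest mean silhouette, smallest k on ties."""
    return int(curve.ks[int(np.argmax(curve.mean_sc))])
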
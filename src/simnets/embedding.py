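"""Low-dimensional maps of precomputed distance matrices.

Both map types in the pipeline (the per-neuron SSIM map of spike trains and
the population CS map of neurons) are embeddings of a symmetric, zero-diagonal
dissimilarity matrix. The default method is t-SNE run in precomputed-distance
mode with a deterministic initialization taken from classical multidimensional
scaling (Torgerson double-centering) of the same matrix. Because the input is
a distance matrix rather than a feature table, classical MDS plays the role a
PCA initialization plays for feature data: it injects the global shape, makes
runs reproducible, and removes the dependence on a random start. Exact
classical MDS is also available as a stand-alone method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.manifold import TSNE

__all__ = ["EmbeddingParams", "MapCoordinates", "classical_mds",
           "pca_initialize", "embed", "default_perplexity"]


@dataclass(frozen=True)
class EmbeddingParams:
    """t-SNE / MDS embedding parameters.

    dims: output dimensionality, 2 (SSIM maps) or 3 (CS maps).
    perplexity: t-SNE neighborhood size; ``None`` selects
        ``min(30, floor((P - 1) / 3))`` for P points, and any larger request
        is clamped to that ceiling with a warning.
    seed: RNG seed passed to t-SNE (the run is deterministic anyway thanks to
        the MDS initialization, but the seed is recorded for provenance).
    max_iter: gradient-descent iterations.
    early_exaggeration: attraction multiplier for the first optimization
        phase. The library default of 12 is tuned for large feature tables
        with a random start; with a deterministic small-magnitude MDS
        initialization on the few-hundred-point distance matrices used here
        it over-compresses the start configuration and the optimizer fails
        to unfold it (final KL divergence an order of magnitude higher). A
        small value preserves the initialization's global structure.
    """

    dims: int = 2
    perplexity: float | None = None
    seed: int = 0
    max_iter: int = 1000
    early_exaggeration: float = 2.0

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        if self.perplexity is not None and self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.max_iter < 250:
            raise ValueError("max_iter must be >= 250")
        if self.early_exaggeration < 1:
            raise ValueError("early_exaggeration must be >= 1")


@dataclass(frozen=True)
class MapCoordinates:
    """Embedded coordinates: one row per point."""

    values: np.ndarray
    point_ids: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "point_ids", tuple(str(p) for p in self.point_ids))
        if v.ndim != 2:
            raise ValueError("coordinates must be 2-D (points x dims)")
        if len(self.point_ids) != v.shape[0]:
            raise ValueError("point_ids length must match point count")
        if not np.all(np.isfinite(v)):
            raise ValueError("coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def dims(self) -> int:
        return self.values.shape[1]


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix must be finite")
    return 0.5 * (d + d.T)


def default_perplexity(n_points: int) -> float:
    """Default/ceiling perplexity for ``n_points``: min(30, floor((P-1)/3))."""
    return float(max(1.0, min(30.0, (n_points - 1) // 3)))


def classical_mds(dist: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of a distance matrix.

    Double-centers the squared distances into a Gram matrix, takes the top
    ``dims`` eigenpairs, and scales eigenvectors by sqrt of the (clamped
    non-negative) eigenvalues. For a Euclidean distance matrix this recovers
    the generating configuration exactly, up to rigid motion. Axis signs are
    fixed so the largest-magnitude loading on each axis is positive, making
    the output fully deterministic.
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if dims < 1 or dims >= n:
        raise ValueError(f"dims must be in [1, {n - 1}], got {dims}")
    d2 = d ** 2
    # B = -1/2 J D^2 J with J the centering matrix
    row = d2.mean(axis=0)
    b = -0.5 * (d2 - row[None, :] - row[:, None] + d2.mean())
    vals, vecs = eigh(b, subset_by_index=(n - dims, n - 1))
    order = np.argsort(vals)[::-1]  # descending eigenvalues
    vals, vecs = vals[order], vecs[:, order]
    # axes whose eigenvalue is numerically zero carry no geometry; zero them
    # so duplicate points get bitwise-identical coordinates
    vals = np.clip(vals, 0.0, None)
    vals[vals < vals.max(initial=0.0) * 1e-12] = 0.0
    coords = vecs * np.sqrt(vals)[None, :]
    for k in range(dims):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def pca_initialize(dist: np.ndarray, dims: int) -> np.ndarray:
    """Deterministic small-magnitude t-SNE initialization from classical MDS.

    Follows the usual t-SNE convention of starting from a configuration whose
    first axis has standard deviation 1e-4.
    """
    coords = classical_mds(dist, dims)
    sd = coords[:, 0].std()
    if sd > 0:
        coords = coords / sd * 1e-4
    return coords


def embed(
    dist: np.ndarray,
    params: EmbeddingParams = EmbeddingParams(),
    method: str = "tsne",
    point_ids=None,
) -> MapCoordinates:
    """Embed a symmetric zero-diagonal distance matrix into 2-D/3-D.

    ``method="tsne"`` (default): t-SNE with ``metric="precomputed"`` and the
    classical-MDS initialization — deterministic for fixed input, parameters
    and library versions. ``method="mds"``: exact classical MDS coordinates.
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if point_ids is None:
        point_ids = [str(i) for i in range(n)]
    if len(point_ids) != n:
        raise ValueError("point_ids length must match distance matrix size")

    if method == "mds":
        return MapCoordinates(classical_mds(d, params.dims), point_ids)
    if method != "tsne":
        raise ValueError(f"unknown embedding method {method!r}")

    ceiling = default_perplexity(n)
    perplexity = params.perplexity
    if perplexity is None:
        perplexity = ceiling
    elif perplexity > ceiling:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} points; clamped to "
            f"{ceiling}",
            stacklevel=2,
        )
        perplexity = ceiling

    init = pca_initialize(d, params.dims)
    tsne = TSNE(
        n_components=params.dims,
        metric="precomputed",
        init=init,
        perplexity=perplexity,
        random_state=params.seed,
        max_iter=params.max_iter,
        early_exaggeration=params.early_exaggeration,
        method="barnes_hut" if params.dims < 4 else "exact",
    )
    with warnings.catch_warnings():
        # sklearn warns that an array init bypasses its own PCA scaling;
        # our init already follows the 1e-4 convention.
        warnings.filterwarnings("ignore", message=".*array.*init.*")
        coords = tsne.fit_transform(d)
    return MapCoordinates(np.asarray(coords, dtype=np.float64), point_ids)
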
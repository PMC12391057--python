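"""Second-order comparison of neuron fingerprints: the CS matrix.

Two neurons are "computationally similar" when their SSIM matrices agree on
which windows produced similar spike trains — regardless of absolute firing
scale or coding format. The computational-similarity (CS) score of a neuron
pair is the Pearson correlation between the vectorized strict upper triangles
of their SSIM matrices (the diagonal is identically zero in every SSIM matrix
and is excluded so it cannot mechanically inflate the correlation). Scores for
all pairs form the symmetric N x N CS matrix; ``1 - r`` converts it to the
dissimilarity form consumed by embedding and clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ssim import SSIMMatrix, SSIMSet

logger = logging.getLogger("simnets")

__all__ = ["CSMatrix", "CSDistance", "cs_score", "cs_matrix", "cs_to_distance",
           "cs_matrix_from_offdiagonals"]

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class CSMatrix:
    """Symmetric N x N matrix of pairwise CS scores (Pearson r, unit diagonal)."""

    values: np.ndarray
    neuron_ids: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...] = ()  # (neuron_id, reason)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "neuron_ids", tuple(self.neuron_ids))
        object.__setattr__(self, "excluded", tuple(tuple(e) for e in self.excluded))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("CS matrix must be square")
        if len(self.neuron_ids) != v.shape[0]:
            raise ValueError("neuron_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("CS matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("CS matrix must have unit diagonal")
        if np.any(v < -1 - 1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("CS entries must lie in [-1, 1]")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CSDistance:
    """Dissimilarity form of a CS matrix: d = 1 - r, in [0, 2], zero diagonal."""

    values: np.ndarray
    neuron_ids: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "neuron_ids", tuple(self.neuron_ids))


def cs_score(a: SSIMMatrix, b: SSIMMatrix) -> float:
    """Pearson correlation between two SSIM matrices' strict upper triangles.

    Invariant to positive affine transforms of either matrix, so neurons with
    proportional output-space geometries but different absolute firing scales
    score 1. Returns NaN when either off-diagonal is constant (degenerate
    fingerprint, correlation undefined).
    """
    if a.window_ids != b.window_ids:
        raise ValueError("SSIM matrices must share the same window ordering")
    x, y = a.off_diagonal, b.off_diagonal
    xc, yc = x - x.mean(), y - y.mean()
    vx, vy = float(xc @ xc), float(yc @ yc)
    if vx <= _VAR_TOL or vy <= _VAR_TOL:
        return float("nan")
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def cs_matrix_from_offdiagonals(
    offdiags: np.ndarray,
    neuron_ids,
    degenerate_policy: str = "exclude",
) -> CSMatrix:
    """Build a CS matrix from pre-extracted (N, S(S-1)/2) upper triangles.

    Vectorized core shared by :func:`cs_matrix` and the shuffle test's
    surrogate loop; results equal pairwise :func:`cs_score` calls in any
    evaluation order.
    """
    if degenerate_policy not in ("exclude", "zero-fill"):
        raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")
    offdiags = np.asarray(offdiags, dtype=np.float64)
    neuron_ids = [str(n) for n in neuron_ids]
    centered = offdiags - offdiags.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms <= np.sqrt(_VAR_TOL)
    excluded = tuple(
        (neuron_ids[i], "constant SSIM off-diagonal (degenerate fingerprint)")
        for i in np.flatnonzero(degenerate)
    )

    if degenerate_policy == "exclude":
        keep = ~degenerate
        if int(keep.sum()) < 2:
            raise ValueError(
                "fewer than 2 non-degenerate neurons; cannot build a CS matrix"
            )
        for nid, reason in excluded:
            logger.info("cs_matrix: excluding neuron %s: %s", nid, reason)
        centered, norms = centered[keep], norms[keep]
        ids = tuple(n for n, k in zip(neuron_ids, keep) if k)
        unit = centered / norms[:, None]
        r = np.clip(unit @ unit.T, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return CSMatrix(r, ids, excluded)

    # zero-fill: degenerate neurons stay with r = 0 against everyone
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    unit[degenerate] = 0.0
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CSMatrix(r, tuple(neuron_ids), excluded)


def cs_matrix(ssims: SSIMSet, degenerate_policy: str = "exclude") -> CSMatrix:
    """All-pairs CS matrix from a set of per-neuron SSIM matrices.

    ``degenerate_policy`` controls neurons whose fingerprint is constant
    (e.g., fully silent): ``"exclude"`` (default) drops them, recording the
    reason; ``"zero-fill"`` keeps them with CS = 0 against every other neuron.
    """
    return cs_matrix_from_offdiagonals(
        ssims.off_diagonals(), ssims.neuron_ids, degenerate_policy
    )


def cs_to_distance(cs: CSMatrix) -> CSDistance:
    """Map correlations to dissimilarities, d = 1 - r.

    Anticorrelated fingerprints (r = -1) map to the maximum distance 2:
    neurons whose output-space geometries are inverted are treated as
    computationally dissimilar, not similar.
    """
    d = 1.0 - cs.values
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return CSDistance(d, cs.neuron_ids)
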
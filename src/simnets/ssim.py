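"""Per-neuron spike-train similarity (SSIM) matrices.

A neuron's SSIM matrix is the S x S table of Victor-Purpura distances among
its S spike trains — a non-parametric "computational fingerprint" of the
intrinsic geometry of the neuron's output space that requires no condition
labels or tuning model. The set of all N fingerprints (one per neuron,
sharing the same window ordering) is the input to the second-order
computational-similarity comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import EnsembleRecording
from .vp_metric import VPParams, vp_distance_batch

__all__ = ["SSIMMatrix", "SSIMSet", "compute_ssims", "ssim_map", "subset_ssim"]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class SSIMMatrix:
    """S x S symmetric matrix of VP distances for one neuron.

    ``degenerate`` is True when the off-diagonal is constant (e.g., a fully
    silent neuron gives an all-zero matrix), in which case the fingerprint
    carries no geometry and downstream Pearson correlation is undefined.
    """

    values: np.ndarray
    window_ids: tuple[str, ...]
    neuron_id: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "window_ids", tuple(self.window_ids))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"SSIM matrix must be square, got shape {v.shape}")
        if len(self.window_ids) != v.shape[0]:
            raise ValueError("window_ids length must match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("SSIM matrix must be finite")
        if np.any(v < -1e-12):
            raise ValueError("SSIM distances must be non-negative")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("SSIM matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("SSIM matrix must have zero diagonal")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def off_diagonal(self) -> np.ndarray:
        """Strict upper-triangle entries as a flat vector (S(S-1)/2,)."""
        iu = np.triu_indices(self.n_windows, k=1)
        return self.values[iu]

    @property
    def degenerate(self) -> bool:
        off = self.off_diagonal
        return bool(off.size == 0 or np.ptp(off) <= _DEGENERATE_TOL)


@dataclass(frozen=True)
class SSIMSet:
    """One SSIM matrix per neuron, all with the same window ordering."""

    matrices: tuple[SSIMMatrix, ...]
    params: VPParams
    n_comparisons: int = 0

    def __post_init__(self):
        object.__setattr__(self, "matrices", tuple(self.matrices))
        if not self.matrices:
            raise ValueError("SSIMSet needs at least one matrix")
        wids = self.matrices[0].window_ids
        for m in self.matrices:
            if m.window_ids != wids:
                raise ValueError("all SSIM matrices must share one window ordering")

    @property
    def neuron_ids(self) -> list[str]:
        return [m.neuron_id for m in self.matrices]

    @property
    def window_ids(self) -> tuple[str, ...]:
        return self.matrices[0].window_ids

    @property
    def n_neurons(self) -> int:
        return len(self.matrices)

    @property
    def n_windows(self) -> int:
        return self.matrices[0].n_windows

    def stacked(self) -> np.ndarray:
        """(N, S, S) array of all matrices."""
        return np.stack([m.values for m in self.matrices])

    def off_diagonals(self) -> np.ndarray:
        """(N, S(S-1)/2) array of strict upper triangles, one row per neuron."""
        s = self.n_windows
        iu = np.triu_indices(s, k=1)
        return np.stack([m.values[iu] for m in self.matrices])

    @property
    def degenerate_neurons(self) -> list[str]:
        return [m.neuron_id for m in self.matrices if m.degenerate]


def compute_ssims(rec: EnsembleRecording, params: VPParams | float) -> SSIMSet:
    """Compute every neuron's SSIM matrix.

    Performs exactly N * S(S-1)/2 spike-train comparisons (recorded in the
    returned set's ``n_comparisons``), which is what makes the analysis scale
    linearly in neuron count.
    """
    if not isinstance(params, VPParams):
        params = VPParams(q=float(params))
    wids = tuple(rec.window_ids)
    matrices = []
    for nid, row in zip(rec.neuron_ids, rec.trains):
        values = vp_distance_batch(row, params)
        matrices.append(SSIMMatrix(values, wids, neuron_id=nid))
    s = rec.n_windows
    return SSIMSet(matrices, params,
                   n_comparisons=rec.n_neurons * s * (s - 1) // 2)


def ssim_map(m: SSIMMatrix, embed_params=None, method: str = "tsne"):
    """Low-dimensional map of one SSIM matrix (one point per spike train).

    Thin delegation to :func:`simnets.embedding.embed` on the distance
    matrix; see that module for parameters and determinism guarantees.
    """
    from .embedding import EmbeddingParams, embed

    if embed_params is None:
        embed_params = EmbeddingParams(dims=2)
    return embed(m.values, embed_params, method=method,
                 point_ids=list(m.window_ids))


def subset_ssim(
    rec: EnsembleRecording, neuron_subset: Sequence[str], params: VPParams | float
) -> SSIMMatrix:
    """Combined (meso/population-level) SSIM matrix for a subset of neurons.

    Entry (i, j) is the sum over the subset of each neuron's VP distance
    between its trains in windows i and j — the additive labeled-line
    extension of the single-neuron fingerprint. For a singleton subset this
    equals that neuron's own SSIM matrix.
    """
    subset = list(neuron_subset)
    if not subset:
        raise ValueError("neuron_subset must be non-empty")
    if not isinstance(params, VPParams):
        params = VPParams(q=float(params))
    total = np.zeros((rec.n_windows, rec.n_windows))
    for nid in subset:
        row = rec.trains_for(nid)  # KeyError for unknown ids
        total += vp_distance_batch(row, params)
    label = "+".join(str(n) for n in subset)
    return SSIMMatrix(total, tuple(rec.window_ids), neuron_id=label)
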
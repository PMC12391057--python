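"""Victor-Purpura edit distance between spike trains.

The distance is the minimum total cost of transforming one spike train into
another using three elementary edits: insert a spike (cost 1), delete a spike
(cost 1), shift a spike by dt seconds (cost q*|dt|). The single parameter q
(units 1/s) sets the temporal accuracy of the comparison, ~1/q: at q = 0 the
distance reduces to the absolute spike-count difference (a pure rate
comparison), while large q makes the metric sensitive to fine spike timing
(only spikes within 2/q of each other are worth shifting rather than
deleting and re-inserting).

Computed with the standard O(n*m) dynamic program
``D[i,j] = min(D[i-1,j] + 1, D[i,j-1] + 1, D[i-1,j-1] + q*|a_i - b_j|)``
with base cases ``D[i,0] = i``, ``D[0,j] = j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import SpikeTrain

__all__ = ["VPParams", "vp_distance", "vp_distance_batch"]


@dataclass(frozen=True)
class VPParams:
    """Victor-Purpura metric parameters.

    q is the cost rate for shifting a spike in time, in 1/seconds; insert and
    delete cost are fixed at 1 each. q = 0 compares spike counts only.
    """

    q: float = 10.0

    def __post_init__(self):
        if not np.isfinite(self.q) or self.q < 0:
            raise ValueError(f"q must be finite and non-negative, got {self.q}")


def _vp_dp_numpy(a: np.ndarray, b: np.ndarray, q: float) -> float:
    # Row-wise vectorized DP. Within row i the horizontal recurrence
    # D[i,j] = min(E[j], D[i,j-1] + 1) with E[j] = min(D[i-1,j] + 1,
    # D[i-1,j-1] + q|a_i - b_j|) unrolls to
    # D[i,j] = j + min_{k<=j} (E[k] - k), a prefix-minimum scan.
    n, m = a.size, b.size
    if n == 0 or m == 0:
        return float(n + m)
    idx = np.arange(m + 1, dtype=np.float64)
    prev = idx.copy()
    for i in range(1, n + 1):
        shift = prev[:-1] + q * np.abs(a[i - 1] - b)
        e = np.empty(m + 1)
        e[0] = i
        np.minimum(prev[1:] + 1.0, shift, out=e[1:])
        prev = np.minimum.accumulate(e - idx) + idx
    return float(prev[m])


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _vp_dp_kernel(a, b, q):  # noqa: ANN001 - numba signature
        n = a.shape[0]
        m = b.shape[0]
        if n == 0 or m == 0:
            return float(n + m)
        prev = np.empty(m + 1, dtype=np.float64)
        cur = np.empty(m + 1, dtype=np.float64)
        for j in range(m + 1):
            prev[j] = j
        for i in range(1, n + 1):
            cur[0] = i
            ai = a[i - 1]
            for j in range(1, m + 1):
                c = prev[j - 1] + q * abs(ai - b[j - 1])
                d = prev[j] + 1.0
                if d < c:
                    c = d
                d = cur[j - 1] + 1.0
                if d < c:
                    c = d
                cur[j] = c
            prev, cur = cur, prev
        return prev[m]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _vp_dp_kernel = _vp_dp_numpy
    _HAVE_NUMBA = False


def _coerce(train) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return train.times
    arr = np.asarray(train, dtype=np.float64).ravel()
    if arr.size and np.any(np.diff(arr) < 0):
        raise ValueError("spike times must be sorted (non-decreasing)")
    return arr


def vp_distance(a, b, params: VPParams | float = VPParams()) -> float:
    """Victor-Purpura distance between two spike trains.

    Parameters
    ----------
    a, b
        :class:`~simnets.data_model.SpikeTrain` or sorted 1-D arrays of spike
        times (seconds).
    params
        :class:`VPParams` or a bare q value (1/s).

    Returns
    -------
    float
        Minimum edit cost; lies in ``[||a|-|b||, |a|+|b|]``.
    """
    if not isinstance(params, VPParams):
        params = VPParams(q=float(params))
    ta, tb = _coerce(a), _coerce(b)
    return float(_vp_dp_kernel(ta, tb, params.q))


def vp_distance_batch(trains, params: VPParams | float = VPParams()) -> np.ndarray:
    """All-pairs VP distance matrix over a list of S >= 3 spike trains.

    Returns the S x S symmetric zero-diagonal matrix, evaluating the
    S(S-1)/2 unique pairs; results are identical to element-wise
    :func:`vp_distance` calls.
    """
    if not isinstance(params, VPParams):
        params = VPParams(q=float(params))
    arrs = [_coerce(t) for t in trains]
    s = len(arrs)
    if s < 3:
        raise ValueError(f"need at least 3 trains, got {s}")
    out = np.zeros((s, s), dtype=np.float64)
    for i in range(s):
        for j in range(i + 1, s):
            try:
                d = _vp_dp_kernel(arrs[i], arrs[j], params.q)
            except Exception as exc:  # pragma: no cover
                raise RuntimeError(f"vp_distance failed for pair ({i}, {j})") from exc
            out[i, j] = out[j, i] = d
    return out
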
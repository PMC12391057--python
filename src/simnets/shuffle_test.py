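"""Shuffle-based validation of detected neuron clusters.

k-means will happily partition structureless data, so an apparent subnetwork
decomposition needs a null model. The null is built by Mantel-style
permutation: for each surrogate dataset, every neuron's SSIM matrix has its
rows and columns permuted *together* by an independent random permutation.
This preserves each fingerprint's internal statistics exactly (symmetry, zero
diagonal, off-diagonal value multiset) while destroying the across-neuron
correspondence of windows that any genuine computational similarity relies
on. Re-running the CS-matrix -> map -> silhouette pipeline on each surrogate
yields an empirical null distribution of silhouette curves, from which a
central confidence band ("acceptance band") per k and an add-one permutation
p-value for the observed SC are derived.

The headline p-value is conservative: each surrogate contributes the maximum
of its silhouette curve over k, and the observed statistic is the observed SC
at its own selected Ksc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import SilhouetteCurve, select_k, silhouette_curve
from .compsim import cs_matrix_from_offdiagonals, cs_to_distance
from .embedding import EmbeddingParams, classical_mds, embed
from .ssim import SSIMMatrix, SSIMSet

__all__ = ["ShuffleTestResult", "SignificanceVerdict", "permute_ssim",
           "null_distribution", "decide"]


@dataclass(frozen=True)
class ShuffleTestResult:
    """Empirical null of silhouette curves from M surrogate datasets."""

    m: int
    ks: tuple[int, ...]
    surrogate_curves: np.ndarray = field(repr=False)  # (M, len(ks))
    band_lower: np.ndarray
    band_upper: np.ndarray
    confidence: float
    observed: SilhouetteCurve
    observed_ksc: int
    observed_sc: float
    p_value: float
    mode: str

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")
        if np.any(self.band_lower > self.band_upper):
            raise ValueError("band quantiles out of order")


@dataclass(frozen=True)
class SignificanceVerdict:
    """Per-k band exceedance plus the overall verdict at Ksc."""

    per_k: dict[int, bool]
    ksc: int
    p_value: float
    alpha: float
    significant: bool


def permute_ssim(m: SSIMMatrix, rng: np.random.Generator) -> SSIMMatrix:
    """Mantel permutation of one SSIM matrix: rows and columns together."""
    pi = rng.permutation(m.n_windows)
    return SSIMMatrix(
        m.values[np.ix_(pi, pi)], m.window_ids, neuron_id=m.neuron_id
    )


def _stat_curve(
    dist: np.ndarray,
    mode: str,
    k_range,
    restarts: int,
    seed: int,
    embed_params: EmbeddingParams,
) -> SilhouetteCurve:
    """Silhouette curve of one (observed or surrogate) CS distance matrix."""
    if mode == "fast":
        coords = classical_mds(dist, 3)
        return silhouette_curve(coords, k_range=k_range, restarts=restarts,
                                seed=seed, dissimilarity=dist)
    coords = embed(dist, embed_params, method="tsne")
    return silhouette_curve(coords, k_range=k_range, restarts=restarts,
                            seed=seed)


def null_distribution(
    ssims: SSIMSet,
    m_surrogates: int = 1000,
    confidence: float = 0.99,
    seed: int = 0,
    mode: str = "auto",
    k_range=None,
    restarts: int = 5,
    embed_params: EmbeddingParams | None = None,
    degenerate_policy: str = "exclude",
    debug_checks: bool = False,
) -> ShuffleTestResult:
    """Build the surrogate silhouette null and score the observed data.

    Each of the ``m_surrogates`` surrogates independently permutes every
    neuron's SSIM matrix (one RNG stream per surrogate index, derived from
    the master seed, so results do not depend on evaluation order), rebuilds
    the CS distance matrix, and computes a silhouette curve. Two statistic
    modes exist: ``"full"`` re-embeds every surrogate with t-SNE;
    ``"fast"`` takes k-means labels in a classical-MDS 3-D projection and
    measures silhouettes on the CS distances directly. ``"auto"`` selects
    fast for m >= 1000. The observed data are pushed through the *same*
    statistic path, keeping observed and surrogates exchangeable under the
    null.

    The add-one estimator ``p = (1 + #{max_k surrogate SC >= observed SC at
    Ksc}) / (1 + M)`` guarantees ``p >= 1/(M+1)``.
    """
    if m_surrogates < 1:
        raise ValueError("m_surrogates must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    if mode == "auto":
        mode = "fast" if m_surrogates >= 1000 else "full"
    if mode not in ("fast", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    if embed_params is None:
        embed_params = EmbeddingParams(dims=3, seed=seed)

    stacked = ssims.stacked()  # (N, S, S)
    n, s, _ = stacked.shape
    iu = np.triu_indices(s, k=1)
    if k_range is None:
        k_range = (2, min(10, n - 1))

    def curve_from_offdiags(offdiags, km_seed):
        cs = cs_matrix_from_offdiagonals(offdiags, ssims.neuron_ids,
                                         degenerate_policy)
        dist = cs_to_distance(cs).values
        return _stat_curve(dist, mode, k_range, restarts, km_seed,
                           embed_params)

    observed = curve_from_offdiags(stacked[:, iu[0], iu[1]], seed)
    observed_ksc = select_k(observed)
    observed_sc = observed.sc_at(observed_ksc)

    children = np.random.SeedSequence(seed).spawn(m_surrogates)
    curves = np.empty((m_surrogates, len(observed.ks)))
    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        offdiags = np.empty((n, iu[0].size))
        for i in range(n):
            pi = rng.permutation(s)
            perm = stacked[i][np.ix_(pi, pi)]
            if debug_checks:
                assert np.allclose(perm, perm.T)
                assert np.allclose(np.diag(perm), 0.0)
                assert np.allclose(
                    np.sort(perm[iu]), np.sort(stacked[i][iu])
                )
            offdiags[i] = perm[iu]
        km_seed = int(child.generate_state(1)[0] % np.uint32(2**31))
        surrogate = curve_from_offdiags(offdiags, km_seed)
        curves[idx] = surrogate.mean_sc

    tail = (1.0 - confidence) / 2.0
    lower = np.quantile(curves, tail, axis=0)
    upper = np.quantile(curves, 1.0 - tail, axis=0)
    exceed = int(np.sum(curves.max(axis=1) >= observed_sc))
    p_value = (1.0 + exceed) / (1.0 + m_surrogates)

    return ShuffleTestResult(
        m=m_surrogates,
        ks=observed.ks,
        surrogate_curves=curves,
        band_lower=lower,
        band_upper=upper,
        confidence=confidence,
        observed=observed,
        observed_ksc=observed_ksc,
        observed_sc=observed_sc,
        p_value=p_value,
        mode=mode,
    )


def decide(
    observed: SilhouetteCurve, null: ShuffleTestResult, alpha: float = 0.01
) -> SignificanceVerdict:
    """Significance verdict: per-k band exceedance and overall test at Ksc.

    ``observed`` must cover the same k range as the null. A k is flagged when
    the observed SC exceeds the upper edge of the acceptance band; the overall
    verdict uses the conservative max-statistic permutation p-value.
    """
    if tuple(observed.ks) != tuple(null.ks):
        raise ValueError(
            f"k ranges differ: observed {observed.ks} vs null {null.ks}"
        )
    per_k = {
        k: bool(observed.mean_sc[i] > null.band_upper[i])
        for i, k in enumerate(observed.ks)
    }
    ksc = select_k(observed)
    return SignificanceVerdict(
        per_k=per_k,
        ksc=ksc,
        p_value=null.p_value,
        alpha=alpha,
        significant=bool(null.p_value <= alpha),
    )
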
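"""End-to-end orchestration of the similarity-network analysis.

``run_simnets`` chains the four pipeline stages — per-neuron SSIM matrices,
the N x N CS matrix, the low-dimensional CS map, and cluster detection with
shuffle-based validation — under a single :class:`RunConfig`, records stage
timings and the exact number of spike-train comparisons performed
(N * S(S-1)/2), and emits a JSON-serializable manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ClusterResult, SilhouetteCurve, select_k, silhouette_curve
from .compsim import CSDistance, CSMatrix, cs_matrix, cs_to_distance
from .data_model import EnsembleRecording, write_matrix
from .embedding import EmbeddingParams, MapCoordinates, embed
from .shuffle_test import ShuffleTestResult, SignificanceVerdict, decide, \
    null_distribution
from .ssim import SSIMSet, compute_ssims
from .vp_metric import VPParams

logger = logging.getLogger("simnets")

__all__ = ["RunConfig", "SimnetsResult", "run_simnets", "write_result"]


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration.

    q: VP temporal-accuracy parameter (1/s); the comparison resolves spike
        timing differences down to roughly 1/q seconds.
    dims: CS-map dimensionality (3 by default; SSIM maps default to 2).
    perplexity: t-SNE perplexity, ``None`` for the automatic default.
    k_range: inclusive (k_min, k_max) for the silhouette sweep; ``None``
        selects (2, min(20, N - 1)).
    restarts: k-means restarts per k for the observed data.
    shuffles: number of surrogates M for the cluster-validation null
        (0 skips the shuffle test entirely).
    confidence: width of the acceptance band (0.99 -> 99% band).
    shuffle_mode: "fast", "full", or "auto" (fast when M >= 1000).
    degenerate_policy: "exclude" or "zero-fill" for constant fingerprints.
    seed: master seed for embedding, k-means, and the shuffle null.
    """

    q: float = 10.0
    dims: int = 3
    perplexity: float | None = None
    max_iter: int = 1000
    embed_method: str = "tsne"
    k_range: tuple[int, int] | None = None
    restarts: int = 20
    shuffles: int = 1000
    confidence: float = 0.99
    shuffle_mode: str = "auto"
    shuffle_restarts: int = 5
    degenerate_policy: str = "exclude"
    alpha: float = 0.01
    seed: int = 0


@dataclass(frozen=True)
class SimnetsResult:
    """Everything one analysis run produced, plus its manifest."""

    ssims: SSIMSet
    cs: CSMatrix
    cs_dist: CSDistance
    coords: MapCoordinates
    curve: SilhouetteCurve
    clusters: ClusterResult
    shuffle: ShuffleTestResult | None
    verdict: SignificanceVerdict | None
    manifest: dict

    @property
    def neuron_ids(self) -> tuple[str, ...]:
        return self.cs.neuron_ids


def run_simnets(rec: EnsembleRecording, cfg: RunConfig = RunConfig()) -> SimnetsResult:
    """Run the full analysis on a recording; deterministic for a fixed seed."""
    timings: dict[str, float] = {}

    def tick(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
        timings[stage] = round(time.perf_counter() - t0, 4)
        logger.info("stage %-12s %.3fs", stage, timings[stage])
        return out

    ssims = tick("ssim", lambda: compute_ssims(rec, VPParams(q=cfg.q)))
    cs = tick("cs_matrix", lambda: cs_matrix(ssims, cfg.degenerate_policy))
    cs_dist = cs_to_distance(cs)

    embed_params = EmbeddingParams(dims=cfg.dims, perplexity=cfg.perplexity,
                                   seed=cfg.seed, max_iter=cfg.max_iter)
    coords = tick("embed", lambda: embed(
        cs_dist.values, embed_params, method=cfg.embed_method,
        point_ids=list(cs.neuron_ids)))

    n = cs.n_neurons
    k_range = cfg.k_range if cfg.k_range is not None else (2, min(20, n - 1))
    curve = tick("silhouette", lambda: silhouette_curve(
        coords, k_range=k_range, restarts=cfg.restarts, seed=cfg.seed))
    ksc = select_k(curve)
    clusters = ClusterResult(ksc=ksc, labels=curve.labels_per_k[ksc],
                             sc=curve.sc_at(ksc))

    shuffle = verdict = None
    if cfg.shuffles > 0:
        shuffle = tick("shuffle", lambda: null_distribution(
            ssims,
            m_surrogates=cfg.shuffles,
            confidence=cfg.confidence,
            seed=cfg.seed,
            mode=cfg.shuffle_mode,
            k_range=k_range,
            restarts=cfg.shuffle_restarts,
            embed_params=embed_params,
            degenerate_policy=cfg.degenerate_policy,
        ))
        verdict = decide(shuffle.observed, shuffle, alpha=cfg.alpha)

    import scipy
    import sklearn

    s = rec.n_windows
    manifest = {
        "simnets_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pd.__version__,
        },
        "params": {**asdict(cfg), "k_range": list(k_range)},
        "n_neurons": rec.n_neurons,
        "n_windows": s,
        "duration_s": rec.duration,
        "vp_comparisons": ssims.n_comparisons,
        "excluded_neurons": [list(e) for e in cs.excluded],
        "ksc": ksc,
        "sc": clusters.sc,
        "p_value": shuffle.p_value if shuffle else None,
        "significant": verdict.significant if verdict else None,
        "shuffle_mode": shuffle.mode if shuffle else None,
        "timings_s": timings,
    }
    return SimnetsResult(ssims=ssims, cs=cs, cs_dist=cs_dist, coords=coords,
                         curve=curve, clusters=clusters, shuffle=shuffle,
                         verdict=verdict, manifest=manifest)


def write_result(result: SimnetsResult, outdir: str | Path) -> None:
    """Write a run's matrices, coordinates, labels, curves, and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = list(result.cs.neuron_ids)

    write_matrix(result.cs.values, outdir / "cs_matrix.csv", ids)
    write_matrix(result.cs_dist.values, outdir / "cs_distance.csv", ids)

    coords = result.coords
    cols = ["x", "y", "z"][: coords.dims]
    pd.DataFrame(coords.values, columns=cols).assign(
        point_id=list(coords.point_ids)
    )[["point_id", *cols]].to_csv(outdir / "cs_map_coords.csv", index=False)

    pd.DataFrame(
        {"neuron_id": ids, "cluster": result.clusters.labels}
    ).to_csv(outdir / "cluster_labels.csv", index=False)

    curve_df = pd.DataFrame({"k": result.curve.ks,
                             "mean_silhouette": result.curve.mean_sc})
    if result.shuffle is not None:
        curve_df["band_lower"] = result.shuffle.band_lower
        curve_df["band_upper"] = result.shuffle.band_upper
    curve_df.to_csv(outdir / "silhouette_curve.csv", index=False)

    if result.shuffle is not None:
        pd.DataFrame(result.shuffle.surrogate_curves,
                     columns=[f"k{k}" for k in result.shuffle.ks]
                     ).to_csv(outdir / "surrogate_curves.csv", index=False)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
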
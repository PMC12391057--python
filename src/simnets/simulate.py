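"""Ground-truth synthetic spike-train populations.

The flagship generator builds a population organized into computationally
distinct subnetworks. Each subnetwork responds selectively to one "preferred"
experimental condition and emits a shared baseline pattern for the others,
and each subnetwork contains equal numbers of neurons using three encoding
formats for that selectivity:

* rate coders — homogeneous Poisson, firing at ``preferred_rate_hz`` on
  preferred-condition windows and ``baseline_rate_hz`` otherwise;
* temporal coders — the same expected spike count on every window, but the
  spikes follow a frozen per-neuron *template*: one template shared by the
  non-preferred conditions and a different one for the preferred condition,
  re-emitted each trial with small Gaussian jitter (plus a low-rate Poisson
  background, so spike counts fluctuate trial to trial and a q = 0 analysis
  sees featureless count noise);
* mixed coders — template structure *and* a rate increase on preferred
  windows.

Neurons in one subnetwork therefore carry the same information (which
condition occurred) in different codes: a temporal-accuracy-aware analysis
should group them by subnetwork, while a pure rate analysis (q = 0) should
separate rate and mixed coders but leave temporal coders unresolvable.

A second, simpler generator produces orientation-tuned Poisson neurons for
documentation examples of single-neuron SSIM maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import EnsembleRecording, SpikeTrain, Window

__all__ = ["SimConfig", "GroundTruth", "simulate_population",
           "simulate_tuned_poisson"]

SCHEMES = ("rate", "temporal", "mixed")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the subnetwork population generator.

    Defaults give 3 subnetworks x 3 schemes x 20 neurons = 180 neurons and
    3 conditions x 10 trials = 30 one-second windows. Rates and jitter are
    implementation defaults chosen to give clean subnetwork separation for
    q > 0 and temporal-coder collapse at q = 0.
    """

    n_subnetworks: int = 3
    neurons_per_scheme: int = 20
    conditions: int = 3
    trials_per_condition: int = 10
    duration_s: float = 1.0
    baseline_rate_hz: float = 10.0
    preferred_rate_hz: float = 20.0
    template_jitter_ms: float = 3.0
    noise_rate_hz: float = 2.0
    shuffle_windows: bool = False
    seed: int = 0

    def __post_init__(self):
        problems = []
        for name in ("n_subnetworks", "neurons_per_scheme", "conditions",
                     "trials_per_condition"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.conditions < self.n_subnetworks:
            problems.append("conditions must be >= n_subnetworks "
                            "(subnetwork i prefers condition i)")
        if self.duration_s <= 0:
            problems.append("duration_s must be > 0")
        for name in ("baseline_rate_hz", "preferred_rate_hz"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.template_jitter_ms < 0:
            problems.append("template_jitter_ms must be >= 0")
        if not (0 <= self.noise_rate_hz < self.baseline_rate_hz):
            problems.append("noise_rate_hz must lie in [0, baseline_rate_hz)")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    @property
    def n_neurons(self) -> int:
        return self.n_subnetworks * len(SCHEMES) * self.neurons_per_scheme

    @property
    def n_windows(self) -> int:
        return self.conditions * self.trials_per_condition


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels: per-neuron subnetwork/scheme, per-window condition."""

    neuron_ids: tuple[str, ...]
    subnetwork: np.ndarray  # 1-based subnetwork id per neuron
    scheme: tuple[str, ...]
    window_ids: tuple[str, ...]
    condition: tuple[str, ...]  # condition label per window

    def __post_init__(self):
        object.__setattr__(self, "subnetwork",
                           np.asarray(self.subnetwork, dtype=int))
        n = len(self.neuron_ids)
        if self.subnetwork.size != n or len(self.scheme) != n:
            raise ValueError("incomplete per-neuron labeling")
        if len(self.condition) != len(self.window_ids):
            raise ValueError("incomplete per-window labeling")

    def neuron_mask(self, scheme: str) -> np.ndarray:
        return np.array([s == scheme for s in self.scheme])


def _poisson_train(rng: np.random.Generator, rate_hz: float,
                   duration: float) -> np.ndarray:
    count = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0.0, duration, size=count))


def _jittered(rng: np.random.Generator, template: np.ndarray,
              jitter_s: float, duration: float) -> np.ndarray:
    if template.size == 0:
        return template
    times = template + rng.normal(0.0, jitter_s, size=template.size)
    return np.clip(times, 0.0, duration)


def simulate_population(cfg: SimConfig = SimConfig()) -> tuple[EnsembleRecording, GroundTruth]:
    """Generate the subnetwork population and its ground-truth labels.

    Windows are condition-blocked by default (all trials of condition 1,
    then condition 2, ...); ``cfg.shuffle_windows`` interleaves them
    randomly. Because every downstream comparison is made within matched
    windows, the ordering cannot affect results (it only permutes SSIM rows
    and columns identically for all neurons).
    """
    rng = np.random.default_rng(cfg.seed)
    dur = cfg.duration_s
    jitter = cfg.template_jitter_ms / 1000.0

    cond_of_window = np.repeat(np.arange(cfg.conditions),
                               cfg.trials_per_condition)
    windows = [
        Window(id=f"w{j:03d}", start_s=j * dur, duration_s=dur,
               label=f"C{c + 1}")
        for j, c in enumerate(cond_of_window)
    ]

    neuron_ids, subnet, scheme_of = [], [], []
    trains: list[list[SpikeTrain]] = []
    idx = 0
    for sn in range(cfg.n_subnetworks):
        for scheme in SCHEMES:
            for _ in range(cfg.neurons_per_scheme):
                nid = f"n{idx:03d}"
                idx += 1
                neuron_ids.append(nid)
                subnet.append(sn + 1)
                scheme_of.append(scheme)
                trains.append(
                    _simulate_neuron(rng, cfg, scheme, sn, cond_of_window,
                                     dur, jitter)
                )

    if cfg.shuffle_windows:
        order = rng.permutation(cfg.n_windows)
        windows = [windows[j] for j in order]
        trains = [[row[j] for j in order] for row in trains]
        cond_of_window = cond_of_window[order]

    rec = EnsembleRecording(neuron_ids, windows, trains)
    truth = GroundTruth(
        neuron_ids=tuple(neuron_ids),
        subnetwork=np.asarray(subnet),
        scheme=tuple(scheme_of),
        window_ids=tuple(w.id for w in windows),
        condition=tuple(w.label for w in windows),
    )
    return rec, truth


def _simulate_neuron(rng, cfg: SimConfig, scheme: str, sn: int,
                     cond_of_window: np.ndarray, dur: float,
                     jitter: float) -> list[SpikeTrain]:
    base_rate = cfg.baseline_rate_hz
    pref_rate = cfg.preferred_rate_hz
    noise = cfg.noise_rate_hz

    if scheme == "rate":
        row = []
        for c in cond_of_window:
            rate = pref_rate if c == sn else base_rate
            row.append(SpikeTrain(_poisson_train(rng, rate, dur), dur))
        return row

    # temporal / mixed: frozen per-neuron templates, jittered per trial,
    # on top of a low-rate Poisson background.
    tmpl_base_rate = base_rate - noise
    tmpl_pref_rate = (pref_rate - noise) if scheme == "mixed" else tmpl_base_rate
    n_base = max(1, rng.poisson(tmpl_base_rate * dur))
    if scheme == "mixed":
        n_pref = max(1, rng.poisson(tmpl_pref_rate * dur))
    else:
        n_pref = n_base  # pure timing code: identical counts, new timing
    base_template = np.sort(rng.uniform(0.0, dur, size=n_base))
    pref_template = np.sort(rng.uniform(0.0, dur, size=n_pref))

    row = []
    for c in cond_of_window:
        template = pref_template if c == sn else base_template
        times = _jittered(rng, template, jitter, dur)
        if noise > 0:
            times = np.concatenate([times, _poisson_train(rng, noise, dur)])
        row.append(SpikeTrain(np.sort(times), dur))
    return row


def simulate_tuned_poisson(
    n_neurons: int = 4,
    orientations=(0.0, 45.0, 90.0, 135.0),
    trials: int = 10,
    duration_s: float = 1.0,
    baseline_hz: float = 5.0,
    amplitude_hz: float = 15.0,
    width_deg: float = 30.0,
    seed: int = 0,
) -> tuple[EnsembleRecording, GroundTruth]:
    """Orientation-tuned Poisson demo population.

    Each neuron fires homogeneous-Poisson spikes at a rate given by a
    Gaussian tuning curve over stimulus orientation (period 180 degrees),
    centered on a preferred orientation assigned round-robin across the
    stimulus set. ``amplitude_hz`` may be a scalar or a per-neuron sequence;
    an amplitude of 0 gives an untuned neuron. Intended for documentation
    examples of single-neuron SSIM maps, not for benchmark claims.
    """
    orientations = np.asarray(orientations, dtype=float)
    amps = np.broadcast_to(np.asarray(amplitude_hz, dtype=float),
                           (n_neurons,))
    rng = np.random.default_rng(seed)
    preferred = orientations[np.arange(n_neurons) % orientations.size]

    cond_of_window = np.repeat(np.arange(orientations.size), trials)
    windows = [
        Window(id=f"w{j:03d}", start_s=j * duration_s, duration_s=duration_s,
               label=f"{orientations[c]:g}deg")
        for j, c in enumerate(cond_of_window)
    ]

    neuron_ids = [f"n{i:02d}" for i in range(n_neurons)]
    trains = []
    for i in range(n_neurons):
        row = []
        for c in cond_of_window:
            diff = np.abs(orientations[c] - preferred[i]) % 180.0
            diff = min(diff, 180.0 - diff)
            rate = baseline_hz + amps[i] * np.exp(-0.5 * (diff / width_deg) ** 2)
            row.append(SpikeTrain(_poisson_train(rng, rate, duration_s),
                                  duration_s))
        trains.append(row)

    rec = EnsembleRecording(neuron_ids, windows, trains)
    truth = GroundTruth(
        neuron_ids=tuple(neuron_ids),
        subnetwork=np.arange(n_neurons) % orientations.size + 1,
        scheme=tuple("tuned" if a > 0 else "untuned" for a in amps),
        window_ids=tuple(w.id for w in windows),
        condition=tuple(w.label for w in windows),
    )
    return rec, truth
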
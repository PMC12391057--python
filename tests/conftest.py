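import numpy as np
import pytest

from simnets import (
    EnsembleRecording,
    SimConfig,
    SpikeTrain,
    Window,
    compute_ssims,
    simulate_population,
)
from simnets.simulate import _poisson_train


def poisson_population(n_neurons, n_windows, rate_hz=10.0, duration=1.0,
                       seed=0) -> EnsembleRecording:
    """Structureless homogeneous-Poisson population (no condition structure)."""
    rng = np.random.default_rng(seed)
    windows = [Window(id=f"w{j:03d}", start_s=j * duration, duration_s=duration)
               for j in range(n_windows)]
    trains = [
        [SpikeTrain(_poisson_train(rng, rate_hz, duration), duration)
         for _ in range(n_windows)]
        for _ in range(n_neurons)
    ]
    return EnsembleRecording([f"n{i:03d}" for i in range(n_neurons)], windows,
                             trains)


def random_train(rng, max_spikes=6, duration=1.0) -> np.ndarray:
    n = rng.integers(0, max_spikes + 1)
    return np.sort(rng.uniform(0.0, duration, size=n))


@pytest.fixture(scope="session")
def toy_recording() -> EnsembleRecording:
    """2 neurons x 4 one-second windows with hand-written spike times."""
    windows = [Window(id=f"w{j}", start_s=float(j), duration_s=1.0)
               for j in range(4)]
    trains = [
        [SpikeTrain([0.1, 0.5], 1.0), SpikeTrain([0.2], 1.0),
         SpikeTrain([], 1.0), SpikeTrain([0.3, 0.6, 0.9], 1.0)],
        [SpikeTrain([0.4], 1.0), SpikeTrain([0.1, 0.9], 1.0),
         SpikeTrain([0.5], 1.0), SpikeTrain([], 1.0)],
    ]
    return EnsembleRecording(["a", "b"], windows, trains)


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down subnetwork population: 3 subnets x 3 schemes x 4 neurons."""
    cfg = SimConfig(neurons_per_scheme=4, seed=7)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def fig_population():
    """Default-size ground-truth population (180 neurons, 30 windows)."""
    return simulate_population(SimConfig(seed=1))


@pytest.fixture(scope="session")
def fig_ssims_q10(fig_population):
    rec, _ = fig_population
    return compute_ssims(rec, 10.0)
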
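"""Victor-Purpura distance: oracle agreement, metric axioms, limit behavior.

Two independent references live in this file and nowhere else:

* ``matching_oracle`` — brute-force minimization over every monotone spike
  matching (cost q * sum |dt| + number of unmatched spikes), feasible for
  trains of up to ~8 spikes;
* ``naive_dp`` — a plain nested-loop textbook dynamic program, sharing no
  code with the package's vectorized kernel.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simnets import SpikeTrain, VPParams, vp_distance, vp_distance_batch

from conftest import random_train


def matching_oracle(a, b, q):
    """Minimum cost over all monotone matchings between trains a and b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    best = float(n + m)  # empty matching: delete everything, insert everything
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for ib in combinations(range(m), k):
                # monotone by construction: combinations are increasing
                cost = q * sum(abs(a[i] - b[j]) for i, j in zip(ia, ib))
                cost += (n - k) + (m - k)
                best = min(best, cost)
    return best


def naive_dp(a, b, q):
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    d = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = float(i)
    for j in range(m + 1):
        d[0][j] = float(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i][j] = min(
                d[i - 1][j] + 1.0,
                d[i][j - 1] + 1.0,
                d[i - 1][j - 1] + q * abs(a[i - 1] - b[j - 1]),
            )
    return d[n][m]


class TestKnownValues:
    def test_identical_trains_have_zero_distance(self):
        t = [0.05, 0.3, 0.77]
        assert vp_distance(t, t, 10.0) == 0.0
        assert vp_distance([], [], 10.0) == 0.0

    def test_count_difference_at_q_zero(self):
        # with free shifts the minimum cost is the spike-count difference
        a, b = [0.1, 0.2, 0.3, 0.4, 0.5], [0.15, 0.85]
        assert vp_distance(a, b, 0.0) == 3.0

    @pytest.mark.parametrize(
        "q,expected", [(2.0, 0.4), (20.0, 2.0)],
        ids=["shift-cheaper", "delete-insert-cheaper"],
    )
    def test_single_spike_crossover(self, q, expected):
        # min(2, q * 0.2), by enumeration of all edit scripts
        assert vp_distance([0.1], [0.3], q) == pytest.approx(expected, abs=1e-12)

    def test_empty_vs_nonempty_costs_spike_count(self):
        assert vp_distance([], [0.2, 0.4, 0.9], 5.0) == 3.0


class TestOracles:
    def test_matches_bruteforce_matching_on_1000_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = random_train(rng, max_spikes=4)
            b = random_train(rng, max_spikes=4)
            q = float(rng.uniform(0, 50))
            assert vp_distance(a, b, q) == pytest.approx(
                matching_oracle(a, b, q), abs=1e-9
            )

    def test_matches_independent_dp_on_1000_random_pairs(self):
        rng = np.random.default_rng(43)
        for _ in range(1000):
            a = random_train(rng, max_spikes=12)
            b = random_train(rng, max_spikes=12)
            q = float(rng.uniform(0, 200))
            assert vp_distance(a, b, q) == pytest.approx(
                naive_dp(a, b, q), abs=1e-9
            )


@st.composite
def spike_train(draw, max_spikes=6):
    times = draw(st.lists(
        st.floats(0.0, 1.0, allow_nan=False, allow_infinity=False),
        max_size=max_spikes))
    return np.sort(np.asarray(times))


class TestMetricAxioms:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=spike_train(), b=spike_train(),
           q=st.floats(0.0, 100.0, allow_nan=False))
    def test_nonnegative_symmetric_bounded(self, a, b, q):
        d = vp_distance(a, b, q)
        assert 0.0 <= d <= len(a) + len(b) + 1e-9
        assert d == pytest.approx(vp_distance(b, a, q), abs=1e-9)
        assert abs(len(a) - len(b)) <= d + 1e-9

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=spike_train(max_spikes=4), b=spike_train(max_spikes=4),
           c=spike_train(max_spikes=4), q=st.floats(0.0, 100.0, allow_nan=False))
    def test_triangle_inequality(self, a, b, c, q):
        dab = vp_distance(a, b, q)
        dbc = vp_distance(b, c, q)
        dac = vp_distance(a, c, q)
        assert dac <= dab + dbc + 1e-9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=spike_train(), b=spike_train(),
           q1=st.floats(0.0, 100.0, allow_nan=False),
           q2=st.floats(0.0, 100.0, allow_nan=False))
    def test_monotone_in_q(self, a, b, q1, q2):
        lo, hi = sorted([q1, q2])
        assert vp_distance(a, b, lo) <= vp_distance(a, b, hi) + 1e-9

    def test_identity_of_indiscernibles(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = random_train(rng)
            b = random_train(rng)
            d = vp_distance(a, b, 30.0)
            if np.array_equal(a, b):
                assert d == 0.0
            elif len(a) != len(b) or not np.allclose(a, b):
                assert d > 0.0


class TestLimits:
    def test_q_zero_equals_count_difference(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b = random_train(rng), random_train(rng)
            assert vp_distance(a, b, 0.0) == abs(len(a) - len(b))

    def test_large_q_counts_non_coincident_spikes(self):
        # as q -> inf, only exactly coincident spikes remain matchable
        a = np.array([0.1, 0.2, 0.5, 0.9])
        b = np.array([0.1, 0.35, 0.5])
        d = vp_distance(a, b, 1e9)
        assert d == pytest.approx(len(a) + len(b) - 2 * 2, abs=1e-9)


class TestValidationAndBatch:
    def test_negative_q_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            vp_distance([0.1], [0.2], -1.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            vp_distance([0.5, 0.1], [0.2], 1.0)

    def test_batch_matches_elementwise_calls(self):
        rng = np.random.default_rng(7)
        trains = [random_train(rng, max_spikes=8) for _ in range(6)]
        params = VPParams(q=17.0)
        mat = vp_distance_batch(trains, params)
        assert mat.shape == (6, 6)
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        for i in range(6):
            for j in range(6):
                assert mat[i, j] == vp_distance(trains[i], trains[j], params)

    def test_batch_of_identical_trains_is_zero(self):
        t = np.array([0.2, 0.6])
        assert np.all(vp_distance_batch([t, t, t, t], 50.0) == 0.0)

    def test_batch_count_differences_at_q_zero(self):
        trains = [np.array([]), np.array([0.5]), np.array([0.2, 0.8])]
        mat = vp_distance_batch(trains, 0.0)
        expected = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        assert np.array_equal(mat, expected)

    def test_batch_requires_three_trains(self):
        with pytest.raises(ValueError, match="at least 3"):
            vp_distance_batch([np.array([0.1]), np.array([0.2])], 1.0)

    def test_spike_train_objects_accepted(self):
        a = SpikeTrain([0.1, 0.4], 1.0)
        b = SpikeTrain([0.2], 1.0)
        assert vp_distance(a, b, 0.0) == 1.0
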
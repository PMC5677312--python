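import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from slowstep import (
    FeatureConfig,
    TransitionFeature,
    candidate_features,
    discretize_states,
    extract_window,
    transition_matrix,
)
from slowstep.errors import BoundaryError, InputError
from slowstep.signal_model import DerivedSignals


def band_oracle(window, ddof=1):
    """Direct transcription of the 8-state band inequalities."""
    w = np.asarray(window, dtype=float)
    m = w.mean()
    std = w.std(ddof=ddof)
    states = []
    for x in w:
        d = x - m
        if std == 0:
            states.append(4)
        elif d <= -1.5 * std:
            states.append(1)
        elif d <= -std:
            states.append(2)
        elif d <= -0.5 * std:
            states.append(3)
        elif d <= 0:
            states.append(4)
        elif d <= 0.5 * std:
            states.append(5)
        elif d <= std:
            states.append(6)
        elif d <= 1.5 * std:
            states.append(7)
        else:
            states.append(8)
    return states


class TestExtractWindow:
    def test_centered_slice(self):
        np.testing.assert_array_equal(
            extract_window(np.arange(20), 10, 2), [8, 9, 10, 11, 12]
        )

    def test_boundary_error(self):
        with pytest.raises(BoundaryError):
            extract_window(np.arange(20), 0, 1)
        with pytest.raises(BoundaryError):
            extract_window(np.arange(20), 19, 1)

    def test_degenerate_single_sample(self):
        np.testing.assert_array_equal(extract_window(np.arange(5), 3, 0), [3])


class TestDiscretize:
    def test_three_point_window(self):
        s = discretize_states([1, 2, 3])
        assert s.m == pytest.approx(2.0) and s.std == pytest.approx(1.0)
        np.testing.assert_array_equal(s.states, [2, 4, 6])

    def test_constant_window_all_fourth_state(self):
        s = discretize_states([5.0] * 13)
        assert s.std == 0.0
        np.testing.assert_array_equal(s.states, 4)

    def test_exact_zero_deviation_in_fourth_state(self):
        s = discretize_states([1.0, 2.0, 3.0])  # middle sample has deviation 0
        assert s.states[1] == 4

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=25))
    def test_matches_band_inequality_oracle(self, window):
        np.testing.assert_array_equal(discretize_states(window).states, band_oracle(window))

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=25))
    def test_negation_symmetry_off_edges(self, window):
        """Negating the window mirrors states k <-> 9-k away from exact band edges."""
        w = np.asarray(window)
        std = w.std(ddof=1)
        assume(std > 1e-6)
        dev = (w - w.mean()) / std
        edges = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
        assume(np.all(np.abs(dev[:, None] - edges) > 1e-9))
        s_pos = discretize_states(w).states
        s_neg = discretize_states(-w).states
        np.testing.assert_array_equal(s_neg, 9 - s_pos)

    def test_thousand_random_windows_against_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            window = rng.normal(0, rng.uniform(0.1, 5), size=rng.integers(3, 20))
            np.testing.assert_array_equal(
                discretize_states(window).states, band_oracle(window)
            )


class TestTransitionMatrix:
    def test_chain_2_4_6(self):
        f = transition_matrix(np.array([2, 4, 6]))
        expected = np.zeros((8, 8))
        expected[1, 3] = 1.0
        expected[3, 5] = 1.0
        np.testing.assert_array_equal(f.matrix, expected)
        # 1-based vector positions 12 and 30
        assert f.vector[11] == 1.0 and f.vector[29] == 1.0
        assert f.vector.sum() == 2.0

    def test_self_loop(self):
        f = transition_matrix(np.array([5, 5, 5]))
        assert f.matrix[4, 4] == 1.0 and f.matrix.sum() == 1.0

    def test_alternating_states(self):
        # pairs (1,2),(2,1),(1,2): each visited row has a single transition type
        f = transition_matrix(np.array([1, 2, 1, 2]))
        assert f.matrix[0, 1] == 1.0 and f.matrix[1, 0] == 1.0
        assert f.matrix.sum() == 2.0

    def test_oracle_pair_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            states = rng.integers(1, 9, size=rng.integers(2, 14))
            counts = np.zeros((8, 8))
            for a, b in zip(states[:-1], states[1:]):
                counts[a - 1, b - 1] += 1
            expected = np.where(
                counts.sum(1, keepdims=True) > 0,
                counts / np.maximum(counts.sum(1, keepdims=True), 1),
                0.0,
            )
            np.testing.assert_allclose(
                transition_matrix(states).matrix, expected, atol=1e-15
            )

    @given(st.lists(st.integers(1, 8), min_size=2, max_size=13))
    def test_rows_stochastic_or_zero_and_counts_conserved(self, states):
        s = np.asarray(states)
        f = transition_matrix(s)
        rows = f.matrix.sum(axis=1)
        assert np.all((np.abs(rows - 1.0) < 1e-12) | (rows == 0.0))
        # recover the count matrix: each row total equals its occurrence count
        occ = np.bincount(s[:-1] - 1, minlength=8)
        counts = f.matrix * occ[:, None]
        assert counts.sum() == pytest.approx(len(s) - 1)

    def test_vector_matrix_round_trip(self):
        f = transition_matrix(np.array([1, 3, 3, 8, 2]))
        back = TransitionFeature.from_vector(f.vector)
        np.testing.assert_array_equal(back.matrix, f.matrix)


class TestCandidateFeatures:
    def make_signals(self, ag, ahx):
        return DerivedSignals(ag=ag, ahx=ahx, sample_rate=50.0)

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(9)
        ag = rng.normal(0, 1, 100)
        ahx = rng.normal(0, 1, 100)
        f0 = candidate_features(self.make_signals(ag, ahx), 50)
        f1 = candidate_features(self.make_signals(3.7 * ag + 11.0, 0.2 * ahx - 4.0), 50)
        np.testing.assert_allclose(f1[0].matrix, f0[0].matrix, atol=1e-12)
        np.testing.assert_allclose(f1[1].matrix, f0[1].matrix, atol=1e-12)

    def test_identical_channels_identical_features(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 60)
        f_ag, f_ahx = candidate_features(self.make_signals(x, x.copy()), 30)
        np.testing.assert_array_equal(f_ag.matrix, f_ahx.matrix)

    def test_channels_discretized_independently(self):
        rng = np.random.default_rng(11)
        ag = rng.normal(0, 1, 60)
        ahx = np.linspace(-1, 1, 60)
        f_ag, f_ahx = candidate_features(self.make_signals(ag, ahx), 30)
        assert not np.array_equal(f_ag.matrix, f_ahx.matrix)

    def test_out_of_bounds_candidate_raises(self):
        with pytest.raises(BoundaryError):
            candidate_features(self.make_signals(np.zeros(20), np.zeros(20)), 2)


def test_feature_config_validates_band_count():
    with pytest.raises(InputError):
        FeatureConfig(n_states=6)  # three edges imply 8 states
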
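import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis

from slowstep import (
    DerivedSignals,
    OutlierConfig,
    consolidate_candidates,
    derive_signals,
    mahalanobis_stat,
    match_to_truth,
    scan_outliers,
)
from slowstep.errors import InputError
from slowstep.signal_model import SLOW_WALK_LABELS


class TestMahalanobisStat:
    def test_point_at_mean_is_zero(self):
        window = [(0, 0), (1, 0), (0, 1), (1, 1)]
        assert mahalanobis_stat((0.5, 0.5), window) == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_quadratic_form(self):
        # four symmetric points with sample covariance exactly I
        c = np.sqrt(1.5)
        window = [(c, 0), (-c, 0), (0, c), (0, -c)]
        assert mahalanobis_stat((3, 0), window) == pytest.approx(9.0)
        assert mahalanobis_stat((3, 0), window, "distance") == pytest.approx(3.0)

    def test_matches_explicit_inverse_oracle(self):
        window = np.array([(0, 0), (1, 0), (0, 1), (1, 1), (2, 2)], dtype=float)
        point = np.array([2.0, 2.0])
        # oracle: hand-computed mean, covariance, closed-form 2x2 inverse
        mu = window.sum(axis=0) / len(window)
        dev = window - mu
        cov = dev.T @ dev / (len(window) - 1)
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
        d = point - mu
        expected = float(d @ inv @ d)
        assert mahalanobis_stat(point, window) == pytest.approx(expected, rel=1e-12)
        # independent cross-check against scipy's distance implementation
        assert mahalanobis_stat(point, window, "distance") == pytest.approx(
            scipy_mahalanobis(point, mu, inv), rel=1e-9
        )

    def test_short_window_rejected(self):
        with pytest.raises(InputError):
            mahalanobis_stat((0, 0), [(0, 0), (1, 1)])

    @given(
        data=st.lists(
            st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=6, max_size=20
        ),
        a=st.tuples(*[st.floats(-2, 2)] * 4),
        b=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
    )
    def test_affine_invariance(self, data, a, b):
        """The statistic is unchanged by any invertible affine map of the plane."""
        window = np.asarray(data)
        A = np.asarray(a).reshape(2, 2)
        assume(abs(np.linalg.det(A)) > 0.1)
        cov = np.cov(window, rowvar=False, ddof=1)
        assume(np.linalg.det(cov) > 1e-6 and np.linalg.cond(cov) < 1e6)
        point = window[0] + np.array([1.0, -0.5])
        d0 = mahalanobis_stat(point, window)
        d1 = mahalanobis_stat(A @ point + b, window @ A.T + b)
        assert d1 == pytest.approx(d0, rel=1e-6, abs=1e-9)


class TestScanOutliers:
    def make_signals(self, ag, ahx, rate=50.0):
        return DerivedSignals(ag=ag, ahx=ahx, sample_rate=rate)

    def test_injected_impulse_is_flagged(self):
        rng = np.random.default_rng(0)
        n = 500
        sigma = 0.01
        ag = rng.normal(0, sigma, n)
        ahx = rng.normal(0, sigma, n)
        ag[250] += 10 * sigma
        idx, stats = scan_outliers(self.make_signals(ag, ahx), OutlierConfig())
        assert 250 in idx
        assert np.all(stats > 3.0)

    def test_infinite_threshold_flags_nothing(self):
        rng = np.random.default_rng(1)
        sig = self.make_signals(rng.normal(0, 1, 400), rng.normal(0, 1, 400))
        idx, _ = scan_outliers(sig, OutlierConfig(threshold=np.inf))
        assert len(idx) == 0

    def test_flagged_set_invariant_to_joint_scaling(self):
        rng = np.random.default_rng(2)
        ag = rng.normal(0, 1, 600)
        ahx = rng.normal(0, 1, 600)
        idx1, _ = scan_outliers(self.make_signals(ag, ahx))
        idx2, _ = scan_outliers(self.make_signals(10 * ag, 10 * ahx))
        np.testing.assert_array_equal(idx1, idx2)

    def test_border_samples_skipped(self):
        rng = np.random.default_rng(3)
        sig = self.make_signals(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        cfg = OutlierConfig()
        half = (cfg.window_samples(50.0) - 1) // 2
        idx, _ = scan_outliers(sig, cfg)
        assert np.all(idx >= half) and np.all(idx < 200 - half)


class TestConsolidate:
    CFG = OutlierConfig()  # refractory 0.75 s

    def consolidate(self, idx, stats, rate=50.0):
        return consolidate_candidates(np.asarray(idx), np.asarray(stats), rate, self.CFG)

    def test_contiguous_run_collapses_to_argmax(self):
        # stats [1,4,5,4,1] with threshold 3 -> flags at offsets 1..3, peak at 2
        cands = self.consolidate([11, 12, 13], [4.0, 5.0, 4.0])
        assert len(cands) == 1
        assert cands[0].index == 12 and cands[0].stat == 5.0

    def test_distant_impulses_both_kept(self):
        cands = self.consolidate([100, 200], [6.0, 7.0])  # 2 s apart at 50 Hz
        assert [c.index for c in cands] == [100, 200]

    def test_close_pair_keeps_larger_stat(self):
        # 0.1 s apart with stats (5, 7): suppression keeps the 7
        cands = self.consolidate([100, 105], [5.0, 7.0])
        assert len(cands) == 1
        assert cands[0].index == 105 and cands[0].stat == 7.0

    def test_tie_keeps_earlier_index(self):
        cands = self.consolidate([100, 105], [5.0, 5.0])
        assert len(cands) == 1 and cands[0].index == 100

    @given(
        st.lists(
            st.tuples(st.integers(0, 400), st.floats(3.01, 50)),
            min_size=1, max_size=30, unique_by=lambda p: p[0],
        )
    )
    def test_spacing_and_subset_invariants(self, flags):
        flags.sort()
        idx = np.array([f[0] for f in flags])
        stats = np.array([f[1] for f in flags])
        cands = self.consolidate(idx, stats)
        times = [c.index for c in cands]
        assert all(b - a >= 0.75 * 50 for a, b in zip(times, times[1:]))
        assert set(times) <= set(idx.tolist())
        assert all(c.stat > self.CFG.threshold for c in cands)


class TestMatchToTruth:
    def test_single_match_within_tolerance(self):
        m, unmatched, missed = match_to_truth([1.00], [1.05], 0.2)
        assert m == [(0, 0)] and not unmatched and not missed

    def test_one_to_one_with_surplus_candidate(self):
        m, unmatched, missed = match_to_truth([1.0, 1.1], [1.05], 0.2)
        assert len(m) == 1 and len(unmatched) == 1 and not missed
        # brute-force optimal one-to-one assignment also yields 1 match
        assert m[0] == (0, 0)  # tie on |dt|=0.05 resolved to the earlier candidate

    def test_empty_candidates_all_missed(self):
        m, unmatched, missed = match_to_truth([], [0.5, 1.5], 0.2)
        assert not m and not unmatched and missed == [0, 1]

    def test_out_of_tolerance_not_matched(self):
        m, unmatched, missed = match_to_truth([1.0], [1.5], 0.2)
        assert not m and unmatched == [0] and missed == [0]

    @given(
        truth_gaps=st.lists(st.floats(0.5, 3.0), min_size=1, max_size=15),
        offsets=st.lists(st.floats(-0.3, 0.3), min_size=15, max_size=15),
    )
    def test_greedy_is_optimal_for_separated_truths(self, truth_gaps, offsets):
        """With truths spaced > 2*tol apart, each candidate can match at most one
        truth, so greedy matching attains the maximum one-to-one cardinality."""
        tol = 0.2
        truths = np.cumsum(truth_gaps)  # spacing >= 0.5 > 2*tol
        cands = [t + o for t, o in zip(truths, offsets)]
        m, _, _ = match_to_truth(sorted(cands), truths, tol)
        expected = sum(1 for t, o in zip(truths, offsets) if abs(o) <= tol)
        assert len(m) == expected


def test_candidates_cover_slow_walk_ground_contacts(cohort3):
    """Pre-detection aligns a candidate to >= 95% of slow-walk contacts."""
    cfg = OutlierConfig()
    matched = total = 0
    for session in cohort3:
        signals = derive_signals(session)
        idx, stats = scan_outliers(signals, cfg)
        cands = consolidate_candidates(idx, stats, session.sample_rate, cfg)
        truth = session.truth_in_labels(SLOW_WALK_LABELS)
        m, _, _ = match_to_truth([c.time for c in cands], truth, 0.2)
        matched += len(m)
        total += len(truth)
    assert matched / total >= 0.95
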
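"""Dwell-time survival analysis and bias-corrected residence times."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smtk.residence_time import (
    SurvivalCurve,
    correct_bias,
    fit_double_exponential,
    residence_time_pipeline,
    survival_from_durations,
    survival_from_tracks,
    threshold_convergence,
)
from smtk.simulate import simulate_dwells
from smtk.trajectories import Trajectory, TrajectorySet


class TestSurvival:
    def test_counting(self):
        sc = survival_from_durations([1.0, 2.0, 3.0])
        assert sc.evaluate(1.5) == pytest.approx(2 / 3)

    def test_all_equal_is_step(self):
        sc = survival_from_durations([2.0] * 10)
        assert sc.evaluate(1.9) == 1.0
        assert sc.evaluate(2.0) == 1.0  # left-continuous: survive >= t
        assert sc.evaluate(2.1) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.1, 50.0), min_size=1, max_size=40), st.floats(0.0, 60.0))
    def test_matches_brute_force_ecdf(self, durations, t):
        sc = survival_from_durations(durations)
        brute = sum(d >= t for d in durations) / len(durations)
        assert sc.evaluate(t) == pytest.approx(brute)

    def test_exponential_within_dkw_band(self, rng):
        n, rate = 5000, 0.02
        sc = survival_from_durations(rng.exponential(1 / rate, n))
        t = np.linspace(0.1, 200, 100)
        eps = np.sqrt(np.log(2 / 0.001) / (2 * n))  # 99.9% DKW band
        assert np.all(np.abs(sc.evaluate(t) - np.exp(-rate * t)) < eps)

    def test_from_tracks_duration_is_span(self):
        t = Trajectory(0, np.arange(5), np.zeros(5), np.zeros(5), 0.5)
        ts = TrajectorySet([t], frame_interval=0.5, mode="slow", exposure=0.5)
        sc = survival_from_tracks(ts)
        assert sc.durations == pytest.approx([2.0])  # (5-1) * 0.5 s

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            survival_from_tracks(TrajectorySet([], frame_interval=0.5))


class TestDoubleExponential:
    def test_single_exponential_data_recovers_rate(self, rng):
        dur = rng.exponential(50.0, 5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k_ns, k_s, A, B = fit_double_exponential(survival_from_durations(dur), seed=0)
        assert k_s == pytest.approx(0.02, rel=0.05)

    def test_mixture_recovers_slow_rate(self, rng):
        n = 10_000
        fast = rng.random(n) < 0.7
        dur = np.where(fast, rng.exponential(1.0, n), rng.exponential(100.0, n))
        k_ns, k_s, A, B = fit_double_exponential(survival_from_durations(dur), seed=0)
        assert k_s == pytest.approx(0.01, rel=0.15)
        assert k_ns > k_s
        assert A >= 0 and B >= 0

    def test_all_below_threshold_rejected(self):
        sc = survival_from_durations([0.5, 1.0, 1.5])
        with pytest.raises(ValueError):
            fit_double_exponential(sc, n_min=2.5)


class TestThresholdConvergence:
    def test_contaminated_data_stabilizes_past_contaminant(self, rng):
        d, c = simulate_dwells(1 / 60, 1 / 300, 8000, 0.5, seed=9, f_fast=0.5, k_fast=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_star, taus = threshold_convergence(
                survival_from_durations(d),
                survival_from_durations(c),
                [0.5, 1.0, 1.5, 2.0, 2.5, 3.5, 5.0],
            )
        stable = taus[4:]  # thresholds >= 2.5 s, past the contaminant scale
        assert np.nanstd(stable) / np.nanmean(stable) < 0.1

    def test_clean_data_flat_in_threshold(self, rng):
        d, c = simulate_dwells(1 / 60, 1 / 300, 8000, 0.5, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, taus = threshold_convergence(
                survival_from_durations(d), survival_from_durations(c), [0.5, 1.5, 2.5, 3.5]
            )
        finite = taus[np.isfinite(taus)]
        assert np.ptp(finite) / np.mean(finite) < 0.25

    def test_threshold_in_frames(self):
        # 2.5 s at 500 ms exposure keeps only tracks of >= 5 measured intervals
        sc = survival_from_durations([0.5, 1.0, 2.0, 2.5, 3.0, 4.0])
        restricted = sc.restrict(2.5)
        assert np.all(restricted.durations >= 5 * 0.5)
        assert len(restricted.durations) == 3


class TestCorrectBias:
    def test_arithmetic(self):
        k_true, tau = correct_bias(0.02, 0.005)
        assert tau == pytest.approx(66.7, abs=0.05)

    def test_zero_bias(self):
        _, tau = correct_bias(0.02, 0.0)
        assert tau == pytest.approx(50.0)

    def test_bias_dominates_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            correct_bias(0.004, 0.005)

    def test_cohesin_mean_residence_time(self):
        # mean of the two replicate estimates feeds the search analysis
        assert np.mean([19.51, 24.16]) == pytest.approx(21.8, abs=0.05)


class TestEndToEndRecovery:
    def test_tau_recovery_over_seeds(self):
        """Dwell data = sum of independent Poisson losses (unbinding + bias)
        with a bias-only control; corrected τ within 15% of truth."""
        errs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(10):
                d, c = simulate_dwells(
                    1 / 60, 1 / 300, 5000, 0.5, seed=seed, f_fast=0.3, k_fast=1.0
                )
                res = residence_time_pipeline(
                    survival_from_durations(d), survival_from_durations(c), n_min=2.5
                )
                errs.append(abs(res.tau_s - 60.0) / 60.0)
        assert np.median(errs) < 0.15

    def test_exposure_invariance(self):
        """τ̂ does not depend on the camera exposure when the threshold is
        fixed in seconds."""
        taus = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for exposure in (0.3, 0.5, 0.8):
                d, c = simulate_dwells(
                    1 / 60, 1 / 300, 8000, exposure, seed=21, f_fast=0.3, k_fast=1.0
                )
                res = residence_time_pipeline(
                    survival_from_durations(d), survival_from_durations(c), n_min=2.5
                )
                taus.append(res.tau_s)
        assert max(taus) / min(taus) < 1.25
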
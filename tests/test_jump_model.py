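"""Two-state displacement model: densities, CDFs and parameter recovery."""

import numpy as np
import pytest
from scipy.integrate import quad

import smtk
from smtk.jump_model import TwoStateFit, fit_two_state, model_cdf, model_pdf, state_switch_probability
from smtk.simulate import sample_model_jumps
from smtk.trajectories import JumpData

DT = 0.0044477


def make_fit(D_bound=0.0025, D_free=2.5, F_bound=0.5, sigma=0.035):
    return TwoStateFit(D_bound=D_bound, D_free=D_free, F_bound=F_bound, sigma=sigma, frame_interval=DT)


class TestModelDensity:
    @pytest.mark.parametrize("dt_index", [1, 4, 7])
    @pytest.mark.parametrize("F_bound", [0.0, 0.3, 1.0])
    def test_pdf_integrates_to_one(self, defoc, dt_index, F_bound):
        fit = make_fit(F_bound=F_bound)
        total, _ = quad(lambda r: model_pdf(r, dt_index, fit, defoc), 0, 5.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_all_bound_reduces_to_rayleigh_mode(self, defoc):
        fit = make_fit(F_bound=1.0)
        r = np.linspace(0, 0.3, 3001)
        pdf = model_pdf(r, 1, fit, defoc)
        expected_mode = np.sqrt(2 * (fit.D_bound * DT + fit.sigma**2))
        assert r[np.argmax(pdf)] == pytest.approx(expected_mode, abs=1e-3)

    def test_bound_peak_near_sqrt2_sigma(self, defoc):
        # D_bound*dt << sigma^2 puts the bound peak at ~sqrt(2)*sigma ~ 49 nm
        fit = make_fit(D_bound=0.0005, D_free=2.5, F_bound=0.5)
        r = np.linspace(0, 0.2, 4001)
        pdf = model_pdf(r, 1, fit, defoc)
        assert r[np.argmax(pdf)] == pytest.approx(np.sqrt(2) * 0.035, abs=0.005)

    @pytest.mark.parametrize("dt_index", [1, 3, 7])
    def test_cdf_monotone_zero_to_one(self, defoc, dt_index):
        fit = make_fit(F_bound=0.4)
        r = np.linspace(0, 6, 2000)
        cdf = model_cdf(r, dt_index, fit, defoc)
        assert cdf[0] == pytest.approx(0.0)
        assert cdf[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(cdf) >= 0)

    def test_later_lags_carry_smaller_free_weight(self, defoc):
        # free-term depletion: at fixed r in the free tail, later-lag CDFs
        # sit higher because less free mass remains
        fit = make_fit(F_bound=0.5)
        from smtk.jump_model import _weights

        wfs = [_weights(fit, k, defoc)[1] for k in range(1, 8)]
        assert np.all(np.diff(wfs) < 0)


class TestStateSwitchProbability:
    def test_zero_rate(self):
        assert state_switch_probability(0.0, DT) == 0.0

    def test_small_rate_linearization(self):
        k, dt = 0.01, 0.0315
        p = state_switch_probability(k, dt)
        assert abs(p - k * dt) / (k * dt) < k * dt / 2

    def test_exact_form(self):
        k = 2.2e-3  # a rate giving the ~7e-5 scale at the longest lag
        assert state_switch_probability(k, 0.0315) == pytest.approx(1 - np.exp(-k * 0.0315))
        assert state_switch_probability(k, 0.0315) == pytest.approx(7e-5, rel=0.02)


class TestFitTwoState:
    def test_self_consistency_recovery(self, defoc):
        jd = sample_model_jumps(100_000, F_bound=0.5, D_free=2.5, seed=3, defoc=defoc)
        fit = fit_two_state(jd, sigma=0.035, defoc=defoc, n_restarts=6, seed=1)
        assert fit.F_bound == pytest.approx(0.5, abs=0.02)
        assert fit.D_free == pytest.approx(2.5, rel=0.05)

    def test_all_bound_degenerate_case(self, defoc):
        jd = sample_model_jumps(30_000, F_bound=1.0, D_free=2.5, seed=4, defoc=defoc)
        fit = fit_two_state(jd, sigma=0.035, defoc=defoc, n_restarts=6, seed=1)
        assert fit.F_bound > 0.97

    def test_duplication_invariance(self, defoc):
        jd = sample_model_jumps(20_000, F_bound=0.4, D_free=2.0, seed=5, defoc=defoc)
        doubled = JumpData(
            frame_interval=jd.frame_interval,
            displacements={k: np.concatenate([v, v]) for k, v in jd.displacements.items()},
        )
        f1 = fit_two_state(jd, sigma=0.035, defoc=defoc, n_restarts=5, seed=2)
        f2 = fit_two_state(doubled, sigma=0.035, defoc=defoc, n_restarts=5, seed=2)
        assert f1.F_bound == pytest.approx(f2.F_bound, abs=1e-3)
        assert f1.D_free == pytest.approx(f2.D_free, rel=1e-2)

    def test_histogram_vs_cdf_fit_agreement(self, defoc):
        """Fitting 10-nm binned histogram CDFs instead of exact empirical
        CDFs moves the bound fraction by less than 0.02."""
        jd = sample_model_jumps(60_000, F_bound=0.5, D_free=2.5, seed=6, defoc=defoc)
        binned = JumpData(
            frame_interval=jd.frame_interval,
            displacements={
                k: (np.floor(v / 0.010) + 0.5) * 0.010 for k, v in jd.displacements.items()
            },
        )
        f_cdf = fit_two_state(jd, sigma=0.035, defoc=defoc, n_restarts=5, seed=2)
        f_hist = fit_two_state(binned, sigma=0.035, defoc=defoc, n_restarts=5, seed=2)
        assert abs(f_cdf.F_bound - f_hist.F_bound) < 0.02

    def test_too_few_lags_rejected(self, defoc):
        jd = JumpData(frame_interval=DT, displacements={1: np.full(200, 0.05)})
        with pytest.raises(ValueError, match="2 lags"):
            fit_two_state(jd, sigma=0.035, defoc=defoc)

    def test_constraint_box_respected(self, defoc):
        jd = sample_model_jumps(10_000, F_bound=0.2, D_free=0.5, seed=7, defoc=defoc)
        fit = fit_two_state(jd, sigma=0.035, defoc=defoc, n_restarts=5, seed=0)
        assert 0.0005 <= fit.D_bound <= 0.08
        assert fit.D_free > 0.15
        assert 0.0 <= fit.F_bound <= 1.0


class TestRecoveryGrid:
    def test_median_bound_fraction_error(self, defoc):
        """Median |F̂ − F| ≤ 0.02 over a grid of bound fractions at 10⁵
        model-generated jumps (several seeds each)."""
        errors = []
        for F in (0.2, 0.5, 0.8):
            for seed in range(3):
                jd = sample_model_jumps(100_000, F_bound=F, D_free=2.5, seed=seed, defoc=defoc)
                fit = fit_two_state(jd, sigma=0.035, defoc=defoc, n_restarts=4, seed=seed)
                errors.append(abs(fit.F_bound - F))
        assert np.median(errors) <= 0.02
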
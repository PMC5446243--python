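"""Two-state (bound/free) displacement-distribution model and its fit.

A population of nuclear factors is modeled as a steady-state mixture of a
chromatin-bound state (apparent diffusion coefficient D_bound, dominated by
slow chromatin motion and localization error) and a freely diffusing state
(D_free). With per-axis localization error σ the radial jump length r over a
lag kΔτ follows, per state, a Rayleigh-type density with effective scale
2(D·kΔτ + σ²). The free component is additionally depleted by axial loss
from the detection slice, captured by the defocalization weight
Z_corr(kΔτ, D_free) (:mod:`smtk.defocalization`):

    P(r, kΔτ) ∝ F_b · Ray(r; D_bound) + Z_corr(k) (1 − F_b) · Ray(r; D_free)

Each lag's mixture is renormalized so its CDF reaches 1, which makes the
free fraction *observed* at lag k smaller than the true one — exactly the
bias the weight encodes. The three parameters (D_bound, D_free, F_bound)
are fitted jointly to the empirical CDFs of lags 1..7 by multi-start
nonlinear least squares; state switching within a lag is neglected, which is
safe when 1 − exp(−k_off·Δτ) is tiny (sub-10⁻⁴ for minute-scale residence
times at millisecond lags, see :func:`state_switch_probability`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from smtk.defocalization import DefocalizationParams, z_corr
from smtk.trajectories import JumpData

__all__ = [
    "TwoStateFit",
    "model_pdf",
    "model_cdf",
    "fit_two_state",
    "state_switch_probability",
    "D_BOUND_RANGE",
    "D_FREE_MIN",
]

#: Bound-state diffusion coefficient search range, μm²/s.
D_BOUND_RANGE = (0.0005, 0.08)
#: Lower bound of the free-state coefficient, μm²/s.
D_FREE_MIN = 0.15
_D_FREE_MAX = 30.0  # generous upper bracket for the optimizer


@dataclass
class TwoStateFit:
    """Fitted two-state model parameters and fit diagnostics."""

    D_bound: float  # μm²/s
    D_free: float  # μm²/s
    F_bound: float  # fraction in the bound state
    sigma: float  # μm, fixed input
    frame_interval: float  # s
    ssq: float = float("nan")  # residual sum of squares at the optimum
    n_restarts_used: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.F_bound <= 1.0):
            raise ValueError("F_bound must lie in [0, 1]")
        if self.D_bound < 0 or self.D_free <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "D_bound": self.D_bound,
                    "D_free": self.D_free,
                    "F_bound": self.F_bound,
                    "sigma": self.sigma,
                    "frame_interval": self.frame_interval,
                    "ssq": self.ssq,
                    "n_restarts_used": self.n_restarts_used,
                },
                fh,
                indent=1,
            )


def _scales(fit: TwoStateFit, dt_index: int) -> tuple[float, float]:
    dt = dt_index * fit.frame_interval
    sb = 2.0 * (fit.D_bound * dt + fit.sigma**2)
    sf = 2.0 * (fit.D_free * dt + fit.sigma**2)
    return sb, sf


def _weights(fit: TwoStateFit, dt_index: int, defoc: DefocalizationParams) -> tuple[float, float]:
    """Per-lag renormalized (bound, free) mixture weights."""
    zc = z_corr(dt_index, fit.D_free, defoc, dt=fit.frame_interval)
    wb = fit.F_bound
    wf = zc * (1.0 - fit.F_bound)
    tot = wb + wf
    return wb / tot, wf / tot


def model_pdf(
    r, dt_index: int, fit: TwoStateFit, defoc: DefocalizationParams
) -> np.ndarray:
    """Two-state radial jump-length density at lag ``dt_index``·Δτ."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    sb, sf = _scales(fit, dt_index)  # s = 2(D·kΔτ + σ²); pdf = (r/s)·e^(−r²/(2s))
    wb, wf = _weights(fit, dt_index, defoc)
    return wb * (r / sb) * np.exp(-(r**2) / (2.0 * sb)) + wf * (r / sf) * np.exp(
        -(r**2) / (2.0 * sf)
    )


def model_cdf(
    r, dt_index: int, fit: TwoStateFit, defoc: DefocalizationParams
) -> np.ndarray:
    """Closed-form CDF of :func:`model_pdf` (mixture of Rayleigh CDFs)."""
    r = np.asarray(r, dtype=float)
    sb, sf = _scales(fit, dt_index)
    wb, wf = _weights(fit, dt_index, defoc)
    return wb * (1.0 - np.exp(-(r**2) / (2.0 * sb))) + wf * (
        1.0 - np.exp(-(r**2) / (2.0 * sf))
    )


def state_switch_probability(k_off: float, dt: float) -> float:
    """Probability a bound molecule unbinds within one lag: 1 − e^(−k_off·Δτ)."""
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(-np.expm1(-k_off * dt))


def fit_two_state(
    jumps: JumpData,
    sigma: float,
    defoc: DefocalizationParams | None = None,
    n_restarts: int = 20,
    seed: int = 0,
    max_eval_points: int = 20_000,
) -> TwoStateFit:
    """Fit (D_bound, D_free, F_bound) to multi-lag empirical jump-length CDFs.

    The objective is the unweighted sum of squared deviations between the
    model CDF and the empirical CDF of every present lag, evaluated at the
    observed displacements (subsampled evenly in rank beyond
    ``max_eval_points`` per lag — the empirical CDF is unchanged at the
    retained quantiles). Multi-start: ``n_restarts`` random initial guesses
    inside the constraint box; the best optimum is kept.
    """
    if defoc is None:
        defoc = DefocalizationParams()
    lags = jumps.lags()
    if len(lags) < 2:
        raise ValueError("need displacements at >= 2 lags")
    if jumps.n_total < 100:
        raise ValueError("need >= 100 displacements in total")
    dt = jumps.frame_interval

    eval_r: dict[int, np.ndarray] = {}
    eval_F: dict[int, np.ndarray] = {}
    for k in lags:
        r = np.sort(jumps.displacements[k])
        n = len(r)
        F = (np.arange(1, n + 1)) / n
        if n > max_eval_points:
            idx = np.linspace(0, n - 1, max_eval_points).round().astype(int)
            r, F = r[idx], F[idx]
        eval_r[k], eval_F[k] = r, F

    # z_corr depends only on (lag, D_free); cache per D_free across residual
    # calls since the optimizer revisits nearby values frame by frame.
    zc_cache: dict[tuple[int, float], float] = {}

    def zc(k: int, D_free: float) -> float:
        key = (k, round(float(D_free), 12))
        if key not in zc_cache:
            zc_cache[key] = z_corr(k, D_free, defoc, dt=dt)
        return zc_cache[key]

    def residuals(p):
        D_b, D_f, F_b = p
        out = []
        for k in lags:
            sb = 2.0 * (D_b * k * dt + sigma**2)
            sf = 2.0 * (D_f * k * dt + sigma**2)
            w = zc(k, D_f)
            wb = F_b
            wf = w * (1.0 - F_b)
            tot = wb + wf
            r = eval_r[k]
            cdf = (
                wb * (1.0 - np.exp(-(r**2) / (2.0 * sb)))
                + wf * (1.0 - np.exp(-(r**2) / (2.0 * sf)))
            ) / tot
            out.append(cdf - eval_F[k])
        return np.concatenate(out)

    lo = np.array([D_BOUND_RANGE[0], D_FREE_MIN, 0.0])
    hi = np.array([D_BOUND_RANGE[1], _D_FREE_MAX, 1.0])
    rng = np.random.default_rng(seed)
    best = None
    used = 0
    for _ in range(n_restarts):
        x0 = lo + rng.random(3) * (hi - lo)
        # sample D_free log-uniformly; linear sampling rarely lands near small D
        x0[1] = np.exp(rng.uniform(np.log(D_FREE_MIN), np.log(_D_FREE_MAX)))
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        used += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("two-state fit failed in all restarts")
    D_b, D_f, F_b = best.x
    return TwoStateFit(
        D_bound=float(D_b),
        D_free=float(D_f),
        F_bound=float(F_b),
        sigma=sigma,
        frame_interval=dt,
        ssq=float(2 * best.cost),
        n_restarts_used=used,
    )
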
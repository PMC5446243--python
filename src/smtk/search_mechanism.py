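"""Target-search algebra for nuclear factors.

Steady-state two-state occupancy relates the specifically bound fraction
F_s and the specific off-rate k_off (the inverse residence time) to the
pseudo first-order on-rate k_on* and hence to the mean search time — the
time between dissociating from one cognate site and binding the next:

    F_s = k_on* / (k_on* + k_off)        τ_search = 1/k_on* = (1−F_s)/(F_s·k_off)

The specific fraction is the total bound fraction minus the non-specific
fraction measured on a binding-deficient mutant. During the search the
molecule alternates free 3D diffusion and transient non-specific chromatin
association (1D sliding, hopping); the search time splits between the two
in proportion to the corresponding steady-state fractions.

:func:`motion_blur_loss` quantifies the residual bias of stroboscopic
imaging: the probability that a free molecule moves farther than a given
distance during the brief laser pulse (and thus blurs beyond the
point-spread-function fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SearchParams",
    "specific_fraction",
    "search_time",
    "decompose_search",
    "motion_blur_loss",
    "derive_search_params",
]


@dataclass
class SearchParams:
    """Full set of search-mechanism quantities for one cell line/condition."""

    F_total: float  # total bound fraction
    F_ns: float  # non-specifically bound fraction
    F_s: float  # specifically bound = F_total - F_ns
    F_free: float  # 1 - F_total
    tau_res: float  # specific residence time, s
    k_off: float  # 1 / tau_res, s^-1
    k_on_star: float  # pseudo on-rate, s^-1
    tau_search: float  # 1 / k_on_star, s
    tau_search_free3d: float  # s spent in free 3D diffusion per search
    tau_search_ns: float  # s spent non-specifically bound per search


def specific_fraction(F_total: float, F_ns: float) -> float:
    """Specifically bound fraction: total minus non-specific (mutant control)."""
    if not (0.0 <= F_ns <= 1.0 and 0.0 <= F_total <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if F_ns > F_total:
        raise ValueError(
            f"non-specific fraction {F_ns} exceeds total bound fraction {F_total}"
        )
    return F_total - F_ns


def search_time(F_s: float, tau_res: float) -> tuple[float, float]:
    """(k_on*, τ_search) from the specific fraction and residence time.

    τ_search = (1 − F_s)/F_s · τ_res; both returned in the units of τ_res.
    """
    if not (0.0 < F_s < 1.0):
        raise ValueError("F_s must lie strictly between 0 and 1")
    if tau_res <= 0:
        raise ValueError("tau_res must be positive")
    k_off = 1.0 / tau_res
    k_on_star = F_s * k_off / (1.0 - F_s)
    return k_on_star, 1.0 / k_on_star


def decompose_search(
    tau_search: float, F_free: float, F_ns: float
) -> tuple[float, float]:
    """Split the search time into free-3D-diffusion and non-specific parts.

    The split is proportional to the steady-state fractions:
    τ_3D = τ·F_free/(F_free + F_ns), τ_ns = τ·F_ns/(F_free + F_ns); the two
    parts sum to τ_search exactly.
    """
    if F_free < 0 or F_ns < 0 or F_free + F_ns <= 0:
        raise ValueError("need F_free + F_ns > 0 with non-negative fractions")
    tot = F_free + F_ns
    tau_free3d = tau_search * (F_free / tot)  # ratio first: exact when F_ns = 0
    return tau_free3d, tau_search - tau_free3d


def motion_blur_loss(D: float, t_exposure: float, threshold: float) -> float:
    """Probability that a 2D Brownian displacement over ``t_exposure``
    exceeds ``threshold``: exp(−threshold²/(4·D·t)). Dimensionless."""
    if D <= 0 or t_exposure <= 0:
        raise ValueError("D and t_exposure must be positive")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return float(np.exp(-(threshold**2) / (4.0 * D * t_exposure)))


def derive_search_params(F_total: float, F_ns: float, tau_res: float) -> SearchParams:
    """Full search-mechanism table row from (F_total, F_ns, τ_res)."""
    F_s = specific_fraction(F_total, F_ns)
    k_on_star, tau_search = search_time(F_s, tau_res)
    F_free = 1.0 - F_total
    tau_3d, tau_ns = decompose_search(tau_search, F_free, F_ns)
    return SearchParams(
        F_total=F_total,
        F_ns=F_ns,
        F_s=F_s,
        F_free=F_free,
        tau_res=tau_res,
        k_off=1.0 / tau_res,
        k_on_star=k_on_star,
        tau_search=tau_search,
        tau_search_free3d=tau_3d,
        tau_search_ns=tau_ns,
    )
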
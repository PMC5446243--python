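# Methods

This note documents the models implemented in `smtk`, their assumptions,
the defaults and why, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Two-state displacement model (`smtk.jump_model`)

A population of nuclear factors is treated as a steady-state mixture of a
chromatin-bound state and a freely diffusing state. Over a lag kΔτ, the
radial displacement of each state is Rayleigh-distributed with effective
scale 2(D·kΔτ + σ²), where the per-axis localization error σ (default
35 nm under stroboscopic illumination) inflates the apparent motion. The
free component at lag k is further weighted by the defocalization survival
Z_corr(kΔτ, D_free) (below), and the mixture is renormalized per lag so the
model CDF reaches 1 — matching empirical CDFs, which necessarily do. The
renormalized free weight at lag k is Z_k(1−F_B)/(F_B + Z_k(1−F_B)), so
later lags carry smaller observed free fractions, which is exactly the bias
the weight encodes.

Assumptions and their justification:

- **No state switching within a lag.** The switching probability over the
  longest lag used (7Δτ ≈ 31.5 ms) is 1 − e^(−k_off·Δτ); for residence
  times of minutes this is below 10⁻³ and negligible
  (`state_switch_probability`).
- **One bound and one free state.** A second diffusive state is not
  modeled; for CTCF/cohesin-class factors a single free state fits the
  displacement distributions.
- **Fit on CDFs, not histograms.** Binning (10 nm) introduces artifacts;
  the fit minimizes summed squared deviations between model and empirical
  CDFs jointly over lags 1..7, evaluated at the observed displacements
  (rank-subsampled beyond 20,000 points per lag, which leaves the
  empirical CDF unchanged at the retained quantiles).
- **Constraints.** D_bound ∈ [0.0005, 0.08] μm²/s, D_free > 0.15 μm²/s,
  F_bound ∈ [0, 1]. Multi-start least squares (default 20 seeded random
  initializations, D_free drawn log-uniformly) guards against local minima;
  in practice the optimum is reproducible across restarts.
- **First seven jumps only.** Only the first 8 localizations of each
  trajectory contribute. Long trajectories are dominated by bound
  molecules, and at long lags the axial-loss correction is an
  approximation whose small errors are amplified; truncation trades a
  small, quantified underestimate of F_bound (below) for robustness.

## Defocalization correction (`smtk.defocalization`)

For molecules uniform in z inside a slab of thickness Δz with absorbing
boundaries, the fraction remaining after Δτ is the classic erfc-series
survival integral, z-averaged over the slab (`p_left`). Real tracking is
gentler than absorbing: molecules re-enter, and the tracker tolerates a
1-frame detection gap. Both effects are absorbed into an enlarged effective
window Δz_corr(D) = Δz + a√D + b.

The calibration (`calibrate_dz_corr`) simulates 50,000 axial random walks
per diffusion coefficient (D = 1..12 μm²/s, steps N(0, √(2DΔτ)),
Δτ = 4.4477 ms, 15 lags) and fits (a, b) by multi-start least squares of
the analytic formula to the simulated survival. A molecule counts as
surviving at lag k if it is inside the slice at frame k and was never
outside for more than `max_gap` (default 1) consecutive frames before
that — the tracker's own gap rule. With the defaults this yields
a ≈ 0.16 s^(−1/2), b ≈ 0.19 μm (stable within a few percent across seeds),
consistent with the reference constants a = 0.15716, b = 0.20811 used as
package defaults.

Numerical choices: the z-average uses a fixed 64-node Gauss–Legendre rule
(the integrand is smooth; the rule is converged far below the series
tolerance); the alternating series stops when the next term falls below
10⁻¹² everywhere; results are insensitive to tightening that tolerance to
10⁻¹⁴ (< 10⁻⁹ change).

Two deliberate subtleties:

- With `max_gap=0` the simulated survival still exceeds the continuous
  absorbing-boundary formula, because positions are only checked at frame
  times and boundary excursions between frames are missed (the classic
  ~0.58·step-sd overshoot per side). The fitted window is therefore
  slightly larger than Δz even without gap tolerance; the gap rule enlarges
  it further.
- Survival with gap tolerance dominates survival without it at every lag —
  the counterintuitive frame-rate dependence of apparent axial loss.

## The trajectory simulator (`smtk.simulate`)

`simulate_tracks` emulates a fast stroboscopic photo-activation tracking
experiment: molecules start uniformly in a spherical nucleus (default
diameter 8 μm), are bound or free for life (switching is negligible on the
bleach-limited trajectory timescale), take Gaussian steps of sd √(2DΔτ)
per axis with radial reflection at the nuclear envelope, photobleach with a
constant rate while inside the illuminated slab (default 4 μm, the HiLo
sheet — molecules bleach outside the detection slice too), and are
localized with per-axis Gaussian error whenever |z| ≤ Δz/2. Detections are
assembled into trajectories with the same 1-frame gap rule the analysis
uses; a molecule re-entering after a longer absence starts a new
trajectory, reproducing the over-counting of free molecules real tracking
suffers. `tune_bleach_rate` bisects the bleach rate to hit a target mean
observed track length (default 3 frames, counting single-detection
trajectories, the experimentally anchored value for CTCF-class factors).

What the generator does not emulate: dye photoblinking kinetics (gaps are
produced only by axial excursions), anisotropic or intensity-dependent
localization error, motion-blur failures of the localizer (quantified
separately by `motion_blur_loss`), and state switching within a trajectory.
Passing recovery tests therefore demonstrates correctness of the estimator
pipeline under the stated physics, not robustness to every experimental
nuisance.

### Bound-fraction bias study

The recovery study (`smtk.replay.bound_fraction_bias_stage`,
`analysis/02`) simulates 500,000 molecules at the study conditions — 50%
bound and **static** (the bound state carries no diffusion in this study;
localization error alone moves its detections), D_free = 2.5 μm²/s,
Δz = 0.7 μm, 4 μm illuminated depth, 8 μm nucleus, σ = 35 nm,
Δτ ≈ 4.45 ms, bleach rate tuned to a mean track length of ~3 — and fits
the seven-jump CDFs. The fitted bound fraction falls ~4 percentage points
(3.4–4.5 across seeds) below the truth: free molecules re-entering the
slice are counted as extra trajectories, inflating the free jump pool.
The general simulator default gives the bound state a small diffusion
coefficient (0.0025 μm²/s, chromatin motion); enabling it adds roughly one
further percentage point to the underestimate.

## Residence-time analysis (`smtk.residence_time`)

Dwell durations (track span × frame interval) from motion-blur tracking
are summarized as a survival function and fitted, after discarding dwells
shorter than a threshold N_min (default 2.5 s, the empirical convergence
point of τ̂ vs threshold; `threshold_convergence` recomputes that curve),
with A e^(−k_ns t) + B e^(−k_s t) on survival values at log-spaced times,
unweighted, with A + B = 1 after re-referencing time to the threshold.
The slower rate is the specific component; fits where the two rates agree
within 1% or one amplitude falls below 0.05 are reported as single
exponentials (the vanishing component is tail noise). The apparent slow
rate is then corrected with an H2B-style control measured the same way:
photobleaching, axial and lateral drift are independent Poisson losses, so
rates add and τ = 1/(k_s − k_bias). The estimate is a genomic average; the
fit assumes one specific off-rate.

The dwell generator draws durations from Exp(k_true + k_bias) (plus an
optional fast contaminant) discretized to whole frames, with an
Exp(k_bias) control. End-to-end recovery of a 60 s residence time under a
300 s bias is accurate to a few percent at 5,000 tracks; the estimate is
invariant to the exposure time when thresholds are fixed in seconds.

## FRAP (`smtk.frap`)

Traces are corrected frame-by-frame for whole-nucleus photobleaching
(~15% per movie is typical) and normalized to the 20-frame pre-bleach
baseline. The reaction-dominant model 1 − A e^(−k_a t) − B e^(−k_b t) is
fitted from the first post-bleach frame (the ~1 s bleach pulse itself is
excluded; bound and free fractions are not identifiable from these
curves), with rates parametrized logarithmically and multi-start
initialization; the residence time is the inverse slower rate. 95%
intervals come from a parametric bootstrap (200 refits of the fitted curve
plus Gaussian noise at the residual scale) — they quantify fit
uncertainty around the estimate, not coverage of an unknown truth.
Applicability is checked with the two model-selection ratios
(k_on*·w²/D_free < 0.01 and k_off/k_on* ≲ 1, thresholds configurable), and
`radial_profile` verifies that recovery is spatially uniform across the
0.6 μm analysis disk — flat for binding-limited recovery, center-depressed
when diffusion matters.

## Target-search algebra (`smtk.search_mechanism`)

Steady-state two-state occupancy: F_s = k_on*/(k_on* + k_off) inverts to
τ_search = 1/k_on* = (1 − F_s)/F_s · τ_res. The specific fraction is the
total bound fraction minus the non-specific fraction measured on a
binding-deficient mutant; the search time splits between free 3D diffusion
and non-specific association in proportion to those fractions (the split
conserves τ_search exactly). All times are carried in seconds internally.
Two caveats are inherited from the data: the U2OS specific fraction is
0.412 by the total-minus-mutant arithmetic (0.589 − 0.177) but 0.398 in
the published summary table — both are surfaced, neither resolved — and
cohesin's multi-step topological loading is treated as a single
rate-limiting first-order step, restricted to G1. `motion_blur_loss`
evaluates exp(−r₀²/(4Dt)), the chance a free molecule travels beyond r₀
during the laser pulse.

## Spatial statistics (`smtk.spatial_stats`)

`pair_cross_correlation` bins inter-channel distances (10 nm default) and
normalizes by the CSR expectation; each pair is weighted by the inverse
fraction of its annulus inside the ROI (isotropic edge correction, exact
geometry via polygon intersection, computed only for points near the
boundary). The estimate averages the A→B and B→A directions, making it
symmetric in the channels by construction; per-cell curves are averaged
with across-cell standard errors. C(r) = 1 under independence.

The binomial composition test histograms the channel-1 fraction k/N of
clusters with ≥ 10 detections (20 bins on [0,1], add-one smoothed — KL is
undefined on empty bins) against a reference built by resampling
k ~ Binomial(N, p1) per observed cluster, and reports the Kullback–Leibler
divergence in bits. Genuinely mixed clusters give fractions of a bit;
single-color (blinking-artifact) clusters give several bits. Cluster
assignment is an input; the bundled DBSCAN-based assigner is plumbing for
synthetic data, not a model-based cluster-identification method.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-for-bit
reproducible. Default study sizes — 50,000 molecules × 12 diffusion
coefficients for the window calibration, 500,000 molecules for the
bias study, 5,000 dwells, 10⁵ jumps for recovery grids — run in seconds to
about a minute each on one CPU; the test suite uses the same sizes or
modest reductions chosen so the whole suite stays fast while the
statistical assertions remain well-powered.
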
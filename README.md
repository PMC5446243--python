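# smtk — single-molecule tracking kinetics for nuclear factors

`smtk` is a Python toolkit for the kinetic analysis of live-cell
single-molecule imaging of chromatin-binding proteins such as CTCF and
cohesin. It covers the full chain from localization tables to biophysical
parameters:

- **Two-state displacement modeling.** Radial jump lengths r pooled over
  lags kΔτ (k = 1..7, Δτ ≈ 4.45 ms) are fitted with a bound/free mixture of
  Rayleigh-type densities with per-axis localization error σ,

  P(r, kΔτ) ∝ F_B · r/(2(D_B kΔτ + σ²)) e^(−r²/(4(D_B kΔτ + σ²)))
  + Z_corr(kΔτ) (1 − F_B) · r/(2(D_F kΔτ + σ²)) e^(−r²/(4(D_F kΔτ + σ²)))

  where Z_corr is the probability that a free molecule is still inside the
  axial detection slice after kΔτ, evaluated with an enlarged effective
  slice Δz_corr(D) = Δz + a√D + b calibrated by Monte-Carlo simulation of
  the tracker's gap rule (`smtk.defocalization`). The fit returns
  (D_bound, D_free, F_bound).

- **Residence times.** Dwell-time survival curves from long-exposure
  ("motion-blur") tracking are fitted with P(t) = A e^(−k_ns t) + B e^(−k_s t);
  the slow rate is corrected for photobleaching and drift with an
  H2B-control rate, τ = 1/(k_s − k_bias) (`smtk.residence_time`).

- **Reaction-dominant FRAP.** FRAP(t) = 1 − A e^(−k_a t) − B e^(−k_b t),
  valid when k_on*·w²/D_free ≪ 1 and k_off/k_on* ≲ 1 (`smtk.frap`).

- **Target-search decomposition.** F_s = F_total − F_ns;
  τ_search = (1 − F_s)/(F_s) · τ_res, split between free 3D diffusion and
  non-specific chromatin association in proportion to the population
  fractions (`smtk.search_mechanism`).

- **Spatial statistics** for two-color super-resolution point patterns:
  edge-corrected pair cross-correlation C(r) and the binomial
  cluster-composition test with a Kullback–Leibler summary
  (`smtk.spatial_stats`).

- **A synthetic-data generator** (`smtk.simulate`) producing two-state
  Brownian trajectories in a spherical nucleus with an axial detection
  slice, HiLo illumination, photobleaching and localization error — plus
  dwell-time, FRAP-trace and point-pattern generators — so every analysis
  is testable end to end.

## Worked example

Simulate a stroboscopic tracking experiment with a 50% bound population and
recover the parameters:

```python
import smtk

cfg = smtk.SimConfig(F_bound=0.5, D_free=2.5, D_bound=0.0,
                     n_traj=500_000, bleach_rate=76.4, seed=1)
tracks = smtk.simulate_tracks(cfg)
jumps = smtk.extract_jumps(tracks)            # first 7 jumps per trajectory
fit = smtk.fit_two_state(jumps, sigma=0.035)
print(f"F_bound = {fit.F_bound:.3f}, D_free = {fit.D_free:.2f} um^2/s")
```

```
F_bound = 0.462, D_free = 2.40 um^2/s
```

The fitted bound fraction falls ~4 percentage points below the true 50%:
restricting each trajectory to its first seven jumps (which limits the
over-weighting of long bound-molecule tracks) slightly over-counts free
molecules that re-enter the detection slice as new trajectories. The same
number derived from the analysis driver:

```bash
python analysis/02_bound_fraction_bias.py
# mean track length 2.95; F_bound_hat = 0.457 (truth 0.500);
# underestimate 4.34 percentage points
```

Search-mechanism algebra from measured fractions and residence times:

```python
from smtk.search_mechanism import derive_search_params
sp = derive_search_params(F_total=0.535, F_ns=0.137, tau_res=21.8 * 60)
print(f"tau_search = {sp.tau_search/60:.1f} min "
      f"({sp.tau_search_free3d/60:.2f} min 3D diffusion, "
      f"{sp.tau_search_ns/60:.2f} min non-specific)")
```

```
tau_search = 33.0 min (25.47 min 3D diffusion, 7.50 min non-specific)
```

## The analysis chain

Numbered drivers under `analysis/` run each stage on simulated data and
write JSON tables to `results/`:

1. `01_calibrate_defocalization.py` — Monte-Carlo calibration of Δz_corr
2. `02_bound_fraction_bias.py` — seven-jump bound-fraction bias study
3. `03_residence_time_recovery.py` — dwell-time pipeline recovery
4. `04_frap_fits.py` — reaction-dominant FRAP fits and regime checks
5. `05_search_table.py` — target-search parameter table
6. `06_spatial_statistics.py` — C(r) and cluster-composition statistics

The same stages are available from the command line via `smtk`
(subcommands `simulate`, `jumps`, `fit-jumps`, `calibrate-dz`, `residence`,
`frap`, `search`, `xcorr`, `replay`).

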
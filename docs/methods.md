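# Methods

This note documents the models behind `fluxdry`, the conventions that are
not forced by the science, and what the synthetic experiments do and do not
demonstrate.

## The synthetic world

The generator exists so that every downstream stage has an exact oracle. It
is *not* a land-surface model; it is the simplest construction that exposes
the phenomena the analysis chain is meant to detect.

**True GPP surface.** Instantaneous GPP is
`GPP = A·L/(A + L)` with light term `L = α·Rg` and effective capacity
`A = A*(SWC)·m(VPD)`. The capacity curve is a product of two logistic ramps
placed symmetrically about the optimum,

    A*(s) = A_peak · σ((s − s_lo)/w) · σ((2·s_opt − s_lo − s)/w) / σ((s_opt − s_lo)/w)²,

so capacity declines below `s_lo` (drought) and above the mirror point
(waterlogging-like), peaking exactly at `s_opt` — which makes the analytic
SWC sensitivity vanish there, a property the tests use. The VPD multiplier
is `m(D) = exp(−k_D·max(0, D − D₀))` with onset `D₀ = 1 kPa`, mirroring the
plateau-decay form used in the light-response fits. Defaults:
`s_opt = 26 %`, `s_lo = 15 %`, `w = 12 %`, `A_peak = 30 µmol m⁻² s⁻¹`,
`k_D = 0.15 kPa⁻¹`, `α = 0.05 µmol per W`.

The width and decay-rate defaults were fixed in one calibration pass with a
specific aim: the growing-season SWC deciles of a default site must straddle
the optimum (driest two decile columns below it, wettest column above it),
and the one-standard-deviation perturbations of the sensitivity analysis
must stay close to the observed driver support, keeping true z-scale
sensitivities in the ±0.6 range typical of observational grids. Steeper
surfaces are representable (`swc_width`, `vpd_decay` are parameters) but
push the perturbation statistic into extrapolation territory — see
"Limitations".

**Consistent fluxes.** Conductance follows a Medlyn form
`Gc = g₀ + f_s·1.6·(1 + g₁/√D)·GPP/c_a` (mol m⁻² s⁻¹, `c_a` fixed at
400 µmol mol⁻¹, `f_s` a soil factor closing below `s_lo`); LE is produced by
the *forward* Penman–Monteith equation from `Gc` and the log-profile `r_a`;
respiration is `R_eco = R_b·Q10^((T−15)/10)`; and `NEE = R_eco − GPP` before
noise, so carbon closes exactly at zero noise and the conductance inversion
has an exact round trip. Friction velocity is generated so that the
canopy-height relation recovers the site's true canopy height exactly under
the near-neutral filter.

**Weather.** Daily radiation is a seasonal sinusoid times a Beta-distributed
cloudiness factor; air temperature is linear in daily radiation plus noise;
daily surface SWC is a seasonal sinusoid plus a mean-reverting AR(1) anomaly
(`φ = 0.85`) recharged by precipitation; deeper layers are lagged running
means of the surface layer. Relative humidity falls with warming air and
drying soil, which makes daily VPD and SWC negatively correlated (full-year
per-site Pearson r ≈ −0.5 to −0.6, inside the −0.7…−0.3 band typical of
water-limited sites). Half-hourly downscaling uses fixed diurnal shapes
normalized so each driver's 07:00–19:00 mean equals its daily value; this
makes the "daily forward model" (used by the oracle) consistent with the
generator by construction.

**Noise model.** Fluxes carry multiplicative Gaussian noise
(`noise_sd_rel`, default 2 %), a small fraction of poor-quality QC flags
(2 % at flag ≥ 2) and missing values (0.5 %). Real eddy-covariance towers
are substantially noisier (random flux error on the order of 10–20 % per
half-hour, more structured gaps). The clean default defines the reference
experiment in which the sensitivity machinery can be validated to
0.15 z-units per percentile cell; robustness of individual stages to
realistic noise is exercised separately (e.g. the regression calibration at
σ = 0.3 z, the light-response recovery at 10 % noise). Results on the clean
default therefore certify the *machinery*, not the attainable precision on
real towers.

**Null constructions.** For decomposition nulls, `decouple_swc` replaces the
soil-moisture series with a weather-independent, non-seasonal AR(1) track.
The seasonal component must go too: a seasonal SWC re-imports the annual
radiation/VPD cycles into SWC-conditioned contrasts even when the flux
response is flat in SWC — an instructive confounding in its own right, but
fatal to a null.

## Ingest conventions

- Daytime is `[07:00, 19:00)` local standard time; the half-open interval
  avoids double-counting the endpoint.
- Only measured or good-quality gap-filled records (QC flag 0 or 1) enter
  daily means; each variable uses its own QC twin; GPP variants inherit the
  NEE flag. Days with under 50 % valid daytime slots are flagged, not
  dropped (threshold configurable).
- Growing-season selection: daily Ta > 15 °C, VPD > 0.5 kPa,
  Rg > 250 W m⁻²; a site is *eligible* with ≥ 300 such days. Alternative
  modes: the 3 consecutive calendar months (wrapping year-end, ties to the
  earliest start) with maximum mean GPP; and anomalies from the multi-year
  seasonal cycle smoothed with a 30-day moving average.
- z-scores use the n−1 standard deviation over the selected day set;
  percentiles are linear-interpolation (type-7) order statistics; decile
  bins are left-closed/right-open except the last, so a value equal to an
  edge falls in the upper bin.
- Per-site decile edges (not pooled) define the 10×10 grid: each site
  contributes its own climate-relative cells, and cross-site statistics
  aggregate percentile-homologous cells.
- Croplands and wetlands are excluded by a PFT blacklist (management and
  water-table dynamics decouple their fluxes from SWC/VPD).

## Biophysics conventions

- The Penman–Monteith inversion solves the standard big-leaf forward
  equation `λE = [Δ(Rn−G) + ρc_p D/r_a] / [Δ + γ(1 + r_c/r_a)]` for
  `r_c = 1/Gc` in closed form; it is accepted by forward/inverse round trip
  (< 1e-8 relative). Degenerate cases — nonpositive LE, or LE at/above the
  Penman limit so the implied conductance is infinite or negative — return
  missing values and are counted, not raised.
- Rainy days (> 0.1 mm) and the following day are excluded from the
  conductance inversion; the threshold is configurable.
- Air pressure defaults to 101.325 kPa; air density and molar density come
  from the ideal gas law at (P, Ta); conductance converts between m s⁻¹ and
  mol m⁻² s⁻¹ via molar density (40.87 mol m⁻³ at 25 °C, 1 atm).
- The light-response fit works in the NEE sign convention (uptake negative);
  windows grow greedily from 2 to at most 14 days until ≥ 30 measured
  (flag-0) half-hours spanning a ≥ 5-fold radiation range are available.
  When a window never exceeds the 1 kPa onset the decay rate is
  unidentifiable and pinned to 0 with a flag. Daily `A_max` is `β₀` — the
  VPD-uncorrected plateau shared by all days of the window; the ambient
  alternative `β(D̄_day)` is exposed as `amax_ambient`.
- Kinetics: Kc25 = 404.9 µmol mol⁻¹, Ko25 = 278.4 mmol mol⁻¹,
  Γ*25 = 42.75 µmol mol⁻¹, activation energies 79 430 / 36 380 / 37 830 /
  65 330 J mol⁻¹ (Kc, Ko, Γ*, Vcmax) — the in-vivo Bernacchi set, pinned in
  one dataclass. `c_i` is computed midday (11:00–14:00, Rg ≥ 500 W m⁻²) in
  mole-fraction units; values outside (Γ*, c_a) are flagged invalid.

## Sensitivity stages

- The regression stores raw OLS coefficients; only the reporting layer flips
  the SWC slope to the drying orientation (so a negative reported slope
  always means "dryness costs GPP", for both drivers). The interaction term
  is the product of the standardized main effects and is not itself
  re-standardized.
- Networks: one hidden layer, 10 rectified-linear units, linear output,
  trained by full-batch L-BFGS (≤ 1000 iterations) on a 60/20/20
  train/validation/test split; 4 seed-derived restarts are ranked by
  validation MSE; a site is excluded when its median held-out r over the
  5 repeats falls below 0.5. Repeat j of site s uses seed
  `base + 1000·s + j`, making every grid bit-reproducible.
  Two deliberate conventions: (i) *rectified* rather than saturating hidden
  units — the perturbation statistic evaluates the fitted function one
  standard deviation beyond each day's position, and saturating units
  systematically damp that response in edge deciles (measured: up to ~60 %
  damping in the driest-decile row on a noise-free response), whereas
  piecewise-linear units extrapolate linearly, which matches the near-linear
  ramps of the truth surface; (ii) restart selection on the validation set
  rather than epoch-wise early stopping — with a quasi-Newton full-batch
  optimizer the epoch axis is not the useful regularization knob, the
  restart axis is.
- The SWC perturbation is −1 sd by default so the printed sign conventions
  hold ("negative = drying reduces the response"); a `direction` argument
  restores the literal +1 sd form.
- Per-bin aggregation is median-of-days within repeat, median across
  repeats, median across sites; cross-site cells carry
  SE = population-sd/√n (n ≥ 2) and a two-sided one-sample t-test (n ≥ 3;
  zero-variance cells with nonzero mean are reported as p = 0).
- The oracle applies the *same finite perturbations* to the true daily
  forward model (daytime-mean GPP over the deterministic diurnal shapes) and
  standardizes by the response sd — it is the estimand of the network
  statistic, not a linearization. Pointwise analytic partials are available
  separately and are finite-difference-verified to 1e-6.

## Decomposition

Within each conditioning decile, the highest and lowest *populated* deciles
of the contrast driver (≥ 3 days each, configurable) are compared; the site
value averages the qualifying conditioning deciles. ΔGPP(SWC|VPD) is
oriented low-minus-high so that limitation is negative for both drivers.
GPP_I = GPP/Rg is re-standardized before contrasting. The
lowest/highest-populated fallback and the 3-day occupancy floor are this
package's choices; stricter variants can be configured.

## Numerical choices

- Missing values are native NaN in memory, `-9999` on disk; CSVs are written
  with shortest-round-trip float formatting and read with round-trip float
  parsing, so writer → reader is exactly lossless.
- Sub-seeds derive arithmetically from the run seed (kept below 2³¹);
  distinct sites, repeats and stages use disjoint streams.
- Curve fits use bounded trust-region least squares; fits that hit a bound
  or fail to converge are flagged and their windows skipped.
- Near-zero denominators in relative uncertainty (mean |sensitivity| below
  1e-6) are typed as "undefined-high" flags rather than infinities.

## Limitations

- Perturbation sensitivity of any fitted model is attenuated where the
  perturbed point leaves the training support (distribution edges, and
  regions emptied by driver covariation). The default surface is configured
  so this bias stays within 0.15 z-units per well-populated cell; for
  steeper surfaces or stronger SWC–VPD coupling the edge rows should be
  read with that bias in mind.
- The generator's noise is unstructured (iid multiplicative); real towers
  have autocorrelated errors, u*-filtering gaps, advection and energy-balance
  non-closure that this sandbox does not emulate. Passing tests certify the
  implementation, not field-scale accuracy.
- The biochemical inversion is Rubisco-limited only (no Jmax/TPU
  limitation, no sun/shade canopy partitioning).
- Timestamps are local standard time with no timezone or leap handling.
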
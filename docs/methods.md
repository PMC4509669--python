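# Methods

This document describes the statistical methods implemented in `sealdive`
and the modelling choices inside the synthetic-data generator.

## 1. Location processing

**SDA filter** (`tracks.sda_filter`). Argos locations are screened by a
speed-distance-angle filter: iterative passes remove first the worst
speed-limit violator, then the sharpest short-leg spike (tight turning angle
over short distances), until no violations remain. The first location of a
track is never removed. A brute-force re-implementation of the same rules is
kept in the test suite as an oracle.

**Movement model** (`tracks.fit_track`). Each animal's filtered track is
modelled as a continuous-time correlated random walk (integrated
Ornstein–Uhlenbeck velocity) in a local tangent plane, fitted by maximum
likelihood through a Kalman filter with per-location-class measurement
variances. Haul-out periods, detected from the saltwater-switch dry record,
freeze the movement process so position uncertainty does not grow while the
animal is ashore. Dive positions are obtained by Kalman smoothing at the
dive start times.

## 2. Dive metrics

**Bottom time** (`dives.bottom_time`). Dive profiles are transmitted as four
inflection points; the profile is treated as a broken stick and bottom time
is the total time spent below 80 % of the dive's maximum depth, computed by
exact linear interpolation of the threshold crossings. For a symmetric
V-shaped dive this yields 0.2 × duration in closed form, which the tests pin.

**Effort residuals** (`dives.effort_residuals`). Per animal, bottom time is
regressed on dive depth and duration and the standardized residuals (mean 0,
SD 1) are the relative foraging-effort index. Standardization is exact per
animal and is asserted to 1e-6.

**Dive classification** (`dives.classify_dive`). With bathymetry at the dive
position: dives reaching ≥ 95 % of the water depth are *benthic*; shallower
dives over water deeper than 50 m are *pelagic*; dives over water ≤ 50 m that
are not benthic are *coastal*; dives with no bathymetry data are
*unclassified*.

**Time spent in area** (`dives.compute_tsa`). The fitted track is stepped at
a fixed interval, each step's duration allocated exactly to the grid cells
it crosses; haul-out time is excluded. Total allocated time equals the
at-sea track span to 0.1 %, and the top quartile of cell occupancy defines
high-usage areas.

## 3. Hydrography

**Equation of state.** Density follows the EOS-80 (UNESCO 1983) polynomial
and potential temperature follows Fofonoff's adiabatic-lapse integration,
both verified against the published check values.

**Mixed layer depth** (`hydro.mixed_layer_depth`). Per upcast, the MLD is
the depth where potential density first exceeds its value at the 6 m
reference depth by 0.03 kg m⁻³, located by linear interpolation between
measurement levels. Casts whose deepest level never crosses the threshold
are flagged bottom-limited and excluded from recovery scoring.

**T/S assignment** (`hydro.interpolate_ts`). Temperature and salinity at a
dive's position and depth are Gaussian-weighted means over all cast levels,
with standard deviations of 3 days in time, 25 km in the horizontal and 5 m
in the vertical, and a small weight floor. A scalar double-loop oracle in
the tests reproduces the vectorized implementation to 1e-9.

**Water masses** (`hydro.water_mass_label`). Warm saline water (T > 3 °C and
S > 34.9) is labelled Atlantic Water, cold fresher water (T < 1 °C and
S ≤ 34.7) Arctic Water, anything else mixed.

## 4. Environmental linkage

**Divergence change point** (`envlink.change_point`). The daily difference
between pelagic dive depth and the mixed layer depth is scanned for a single
mean shift; the split minimizing the residual sum of squares is accepted if
the gain exceeds a modified-BIC penalty (3 log n). The 3-day weighted
smoothing of the divergence series is presentation-only and never applied
before change-point analysis. An exhaustive split-search oracle backs the
implementation, and 200-replicate calibration runs establish localization
within ±2 days at the design signal-to-noise.

**Wind covariates** (`envlink.wind_covariates`). Wind records contribute to
sector N when their direction of origin is within ±45° of true north (NE
analogously). For lag k, the covariate on day d is the mean speed of
in-sector records over the half-open window [d−k, d), zero if none; windows
with fewer than half the expected records are flagged sparse.

**Wind-lag selection** (`models.fit_wind_gam`). For every sector and lag
1–7, candidate additive models (date smooth by year; plus linear or smooth
wind terms) are compared by BIC against the date-only baseline; the best
(lag, structure) pair is reported with BIC weights. The response used in the
pipeline is the daily mean depth of *pelagic* dives only: the wind effect
acts on the pelagic prey layer, and including benthic dives (whose depth is
set by the bottom) only adds composition noise that blurs the lag
discrimination.

## 5. Seasonal and diel models

**Additive mixed model engine** (`models.fit_amm`). Penalized cubic
B-splines with a random animal intercept and AR(1) residuals; smoothing
parameters by REML, with an ML evaluation used to assemble BIC
(n = number of observations) for comparisons across fixed-effect
structures. A Poisson additive model (PIRLS with GCV smoothing) covers
daily dive counts; a multinomial logit covers dive-type composition against
month, with fitted probabilities summing to one.

**Seasonal depth curve.** The pooled daily mean maximum depth (all animals,
episode days excluded) is fitted with a date smooth; the pointwise 95 % band
is compared against the generator's expected seasonal curve.

**Diel contrast** (`pipeline.diel_contrast_by_month`). For each animal-date
with both day and night pelagic dives, the night-minus-day difference of
mean depths is one paired contrast; pairing cancels animal offsets,
day-scale autocorrelation and that day's habitat composition. Per month, a
diel effect is declared when BIC prefers a free-mean over a zero-mean
Gaussian model of the contrasts:
`dbic = n log(mean(d²)/var(d)) − 2 log(n) > 0`.

## 6. Synthetic-data generator

`simulate.SimConfig` drives a ten-animal, ~250-day deployment by default.
Design choices that matter for interpretation:

- **Habitat occupancy.** Animals switch among coastal, bank and outer-shelf
  modes with season-dependent weights; the analytic expectation of the
  occupancy (used by truth curves) is computed by a fixed-seed Monte Carlo
  over the mode process and cached.
- **Dive depths.** Coastal and benthic depths follow truncated normals
  bounded by the bathymetry; pelagic depths track the mixed layer through a
  softmin saturation (`pelagic_depth_mean`), so the pelagic mean follows the
  deepening mixed layer until a saturation depth. All dive depths are
  truncated below at 6 m — the transmitted-record convention that shallower
  excursions are not dives — and records must last at least 8 s.
- **Mixed layer.** The true MLD deepens smoothly from summer to autumn and
  then steps up at the configured winter-mixing date; two-layer casts are
  sampled along the tracks with configurable level spacing and sensor noise.
- **Wind and intrusions.** A shared wind stream carries episodic northerly
  events; each event triggers a warm/saline intrusion and a deep-diving
  behavioural episode exactly `intrusion_lag_days` later. Wind parameters
  draw from a stream separate from the per-animal dive streams, so changing
  the wind does not perturb the dive draws.
- **Diel effect.** A night-time depth offset is applied only inside the
  configured months, with a tapered (Tukey-style) envelope at the window
  edges so month-level detection has a sharp inside/outside truth.
- **Determinism.** Every animal has its own `SeedSequence` child; repeated
  runs with the same config are byte-identical, and the ground truth records
  every injected effect (dive kinds, episode days, MLD, expected seasonal
  curve, change date, lag, diel months) for recovery scoring.
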
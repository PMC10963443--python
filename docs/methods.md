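# Methods

This note documents the models, conventions and numerical choices behind
`microclim`, and what the synthetic generator does and does not emulate.

## Recording model and QC

A logger series is a naive local-civil-time sequence at six fixed hours
(02, 06, 10, 14, 18, 22); the study region observes no DST, so no timezone
arithmetic is performed anywhere. The analysis window is a 365-day year
(default 2022-03-01..2023-02-28). Strict schedule mode rejects off-schedule
rows; lenient mode snaps rows within ±30 min of a slot (logger clocks
drift) and drops the rest. Completeness is the fraction of the window's
6 × 365 = 2190 slots present; the default retention threshold is 1.0
("complete time series"), configurable because real campaigns need
tolerance. Daily summaries require all six recordings by default (`min_obs
= 6`; 4 in lenient analyses); days below the threshold are omitted, never
interpolated.

Daily extremes are taken over the six recorded values only. Relative to
continuous sensing this biases DRT low (the true daily max rarely falls
exactly on a recording hour); the bias is shared with any analysis of the
same six-per-day data and is therefore the faithful convention here.

## Bioclimatic indices

- MAT = mean of daily means over the window. With a complete schedule this
  equals the mean of all raw recordings (each day contributes six equal
  weights); the package computes the daily-means version so that partially
  complete days, where admitted, do not distort weighting.
- MMT = unweighted mean of daily means within a calendar month.
- BIO7 continentality = max(MMT) − min(MMT); warmest/coldest month ties go
  to the earliest month in the window (logged). Strict mode requires 12
  months.
- Quarters are fixed Southern-Hemisphere blocks: warmest = Dec–Feb
  (December of the window's first calendar year pooled with Jan/Feb of its
  second — 90 days in a non-leap window), coldest = Jun–Aug. Quarterly MDT
  and DRT are means of the daily values over those dates.

## Moisture

Saturation vapour pressure uses the Murray exponential form with over-water
constants (a = 17.2693882, b = 237.3 °C, e0 = 6.1078 hPa) as a single
continuous branch at all temperatures — matching the convention of the
humidity utilities commonly used with this kind of data — with an over-ice
branch (21.8745584, 265.5) available behind a flag. VPD is computed per
recording and *then* averaged per day: e_sat is convex in T, so the order
matters, and the per-recording order is the faithful reading of "VPD from
the recorded temperature and humidity". The internal unit is hPa; kPa
thresholds (VPD₅₀ of 1.3 / 2.3 kPa) are converted explicitly at the
interface. The fire-ignition indicator counts days with t_max > 25 °C and
rh_min < 25 %, both strict inequalities, with rh_min taken over the six
recordings (the data contain no other humidity source).

## Gradient models

Lapse rates are classical OLS fits of site MAT on elevation, reported per m
and per 100 m with adjusted R² and a two-sided t-based p for the slope; no
small-sample correction beyond adjusted R². Gap sites are excluded from
lapse fits (they measure the opening, not the interior climate).

Continentality standardisation uses one pooled OLS fit of BIO7 on elevation
across all stand sites; each site's standardised value is
`observed + slope · (reference − elevation)` with reference 1000 m. This is
algebraically the fit residual shifted by the prediction at the reference,
so standardised values are exactly uncorrelated with elevation —
property-tested, and the basis of one acceptance check. Per-sector
standardisation is available as an option.

Aspect elevation-equivalence converts the north−south prediction gap into
metres: Δz(z) = (pred_N(z) − pred_S(z)) / |overall slope|, positive when
north is warmer. When the two aspect fits differ in slope, Δz declines
linearly with elevation; the overall pooled lapse is the divisor by
default (the mean of the two stratum slopes via config).

The VPD–elevation trend is a univariate penalized regression spline:
a clamped cubic B-spline basis of dimension k = 5 with uniform interior
knots over the observed range, penalised by the exact integral of the
squared second derivative (assembled by 2-point Gauss quadrature per knot
span, which is exact for the piecewise-quadratic integrand). Straight lines
span the penalty null space, so noiseless linear data is reproduced to
machine precision at any smoothing level. The smoothing parameter is chosen
by GCV, `n·RSS / (n − edf)²`, over a log-spaced grid on the internally
rescaled covariate. The pointwise standard error is the Bayesian posterior
SE, `σ²(BᵀB + λP)⁻¹` with `σ² = RSS/(n − edf)` — the convention of
mgcv-style smoothers — and the 95 % band is fitted ± 1.96·SE, pointwise,
not simultaneous. Prediction outside the fitted covariate range raises an
error rather than extrapolating. The fit of record excludes the shrubland
successional-stage sites; those are then classified above/within/below the
band.

## Group statistics

Normality screening (Shapiro–Wilk) routes to parametric vs rank-based
comparisons; the routing is recorded, not silently automatic. The omnibus
across vegetation types is tie-corrected Kruskal–Wallis. The all-pairs post
hoc is the Nemenyi test on pooled midranks,

    q_ij = |R̄_i − R̄_j| / sqrt( N(N+1)/12 · (1/n_i + 1/n_j) ),

referred to the studentized-range distribution with k groups and infinite
df (p = P(q_{k,∞} ≥ q_ij·√2)); a chi-square variant sits behind a flag.
Compact letters come from the insert-and-absorb algorithm and satisfy the
contract *two groups share a letter iff their pairwise p ≥ α* for every
input matrix (property-tested on random matrices); α defaults to 0.001 for
the vegetation table. A caveat worth knowing: rank statistics saturate, so
with k = 4 groups of n = 20 an adjacent pair's Nemenyi p cannot fall below
≈ 0.03 no matter how separated the groups are on the raw scale.

The vegetation summary table pools daily values across a type's sites,
treating days as replicates. This is pseudo-replication in the strict
sense (days within a site are autocorrelated, sites share weather); the
per-site-mean unit is available as a robustness option (`unit="sites"`),
and the default mirrors the pooled-daily convention of field summaries of
this kind. Stand–gap tests are two-sided paired t-tests day-matched per
recording hour; raw p-values are the headline (with Holm-adjusted values
reported alongside), since six hours per month are tested together.

## Synthetic generator

The generator is a statistical emulator, not an energy-balance model. The
deterministic skeleton for a site at day-of-year d and hour h is

    T = base(sector) + lapse·(z − 1000)/100 + aspect(z)
        + A_season(sector, z)·cos(2π(d − 15)/365)
        + A_diurnal(veg, setting)·f(sector)·cos(2π(h − 14)/24)

with defaults: lapse −0.47 K/100 m; sector baselines 7.0/7.2/7.4/7.6 °C at
1000 m (west→east warming at equal elevation); seasonal amplitudes
6.0/7.4/7.5/7.6 K (sector 1 markedly less continental) declining by
0.0013 K per m of elevation so continentality falls at ≈ −0.0022 K/m as
observed along such transects; an aspect offset of 0.54 K (N − S) at
1000 m decaying by 0.0004 K/m, which reproduces the characteristic
equivalent-elevation shifts of ~150/115/65 m at 500/1000/1500 m; diurnal
amplitudes per vegetation type (AusChil 5.6, NotDomb 4.85, NotAnta 6.4,
NotPumi 4.45 K — i.e. sampled DRT = twice the amplitude), scaled by sector
factors 0.90–1.10 so DRT grows west→east, plus 2.5 K extra amplitude in
gaps. The diurnal cycle peaks at 14:00, the warmest recorded slot. The
cosine phase (maximum at day-of-year 15, mid-January) encodes the
Southern-Hemisphere season.

On top of the skeleton: one *shared* AR(1) day-level synoptic anomaly
series per network (sd 3 K, ρ 0.6, demeaned over the window so the year's
climate is not shifted by the draw) — shared because co-located loggers
experience the same weather, which is what makes day-matched paired tests
and stand–gap contrasts behave as in real campaigns — plus iid recording
noise (sd 0.3 K). RH is generated conditionally on the temperature
deviation from the site's deterministic seasonal mean
(`rh = rh_base(sector) + veg_offset + slope·ΔT + noise`, slope −3 %/K,
sector bases 61/58/55/52 %, shrubland offset −8 % and forest-type offsets
−7/−9 % encoding canopy humidity retention), clamped to [2, 100] %, so VPD
inherits the T–RH anticorrelation. Finally both channels are quantized to
the sensor resolutions (0.0625 K, 0.6 %RH). Setting the noise fields and
`synoptic_sd` to zero and `quantize=None` makes every record equal the
deterministic skeleton exactly, and the `SyntheticTruth` expectations
(MAT, BIO7, DRT per site) are exact in that regime.

The default layout mirrors the campaign design: 37 stands (6 AusChil at
600–890 m, 7 NotDomb at 500–1000 m, 9 NotAnta at 900–1300 m, 15 NotPumi at
1100–1600 m) on 8 transects over 4 sectors × 2 aspects, plus 3 gap loggers
paired to stands — 40 sites. Aspect/elevation placements were balanced so
that the pooled deterministic MAT–elevation regression of the layout
recovers the configured lapse (−0.471 vs −0.47 K/100 m); an unbalanced
layout would confound aspect and sector with elevation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: radiation and albedo physics, snow, wind and
cold-air pooling; spatially structured (rather than network-uniform)
weather; bimodal within-season VPD patterns; burst sensor failures are
available (`mode="burst"`) but default missingness is zero. Two known
biases of the default calibration, both tails of the same RH knob: annual
maxima of daily-mean VPD run ~10–15 % below the levels typical of the
emulated campaign, while fire-threshold day counts for the warmest, driest
vegetation type run correspondingly high. The cosine + AR(1) tail is too
thin to match the VPD maxima and too fat to match the joint hot-dry
exceedance at once; matching both would need a weather model with
heat-wave persistence beyond AR(1).

## Numerical conventions

- Ties: warmest/coldest month and annual-max VPD date → earliest wins.
- Paired t with all-zero differences returns the defined degenerate result
  (t = 0, p = 1); constant non-zero differences raise an error.
- Kruskal–Wallis on an all-tied pooled sample returns H = 0, p = 1.
- Degenerate regression designs (all elevations equal, n < 3, n ≤ k for
  the spline) raise typed errors rather than returning NaN.
- The pipeline is deterministic end to end for a fixed seed/config; output
  tables are checksummed into `manifest.json` and the reporter refuses
  tampered tables.

## Problem sizes

The default analyses run on the 40-site, 365-day network (87,600 records).
Parameter-recovery checks use 200 replicate fits at the network's 40
elevations; permutation cross-checks of the Nemenyi p use 10,000 draws at
k = 4, n = 20; the letters contract is exercised on 1,000 random matrices.
All of it completes in well under a minute on one CPU.
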
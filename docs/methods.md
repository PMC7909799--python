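# Methods

This note records the models, conventions and numerical choices behind
`defolyr`, and what the synthetic test-bed does and does not establish.

## Data model and conventions

A tree's record is three aligned width vectors (earlywood, latewood, total,
in mm) on strictly consecutive calendar growth years. Earlywood + latewood
must equal the total within 0.01 mm. Locally absent ("missing") rings are
stored as width 0 with a flag: they enter detrending as linearly
interpolated values, but the relative growth change (RGC) is undefined at a
missing ring and wherever the previous ring is zero, and undefined values
never count toward synchrony denominators. Multiple cores of one tree are
averaged per year with a plain arithmetic mean (the seasonal fractions are
averaged separately, the total recomputed as their sum); cores whose spans
do not chain-overlap are refused rather than concatenated.

Tucson/RWL files are accepted in both circulating dialects — stop marker
`999` with 0.01 mm units and `-9999` with 0.001 mm — with the unit inferred
from the marker.

## Standardisation

* **Baillie–Pilcher index**: per cent of the centred 5-year running mean,
  edges truncated. Used for the leave-one-out screen (reject at *r* < 0.4
  against the mean of the remaining series, iterated to a fixed point; a
  non-positive threshold is vacuous by definition).
* **Smoothing-spline detrend**: division by a second-difference penalised
  (Whittaker–Henderson) smoother whose penalty is set from the conventional
  50% frequency-response cutoff, λ = 1/(16·sin⁴(π/λ₀)) at cutoff wavelength
  λ₀ (default 0.67 × series length). This is the discrete equivalent of the
  cubic smoothing splines standard in dendrochronology: it reproduces
  constants and straight lines exactly and passes high-frequency variation
  essentially untouched. Indices are undefined where the fitted curve is
  ≤ 0.
* **Double detrend**: a modified negative exponential a·e^(−bt) + k
  (a, b > 0, k ≥ 0; fallbacks: non-positive-slope line, then the mean)
  followed by the spline. Used for the climate modelling chronology.

Chronology confidence uses the Wigley statistics with pairwise-complete
correlations over ≥ 10 shared years: EPS = n·r̄/(n·r̄ + 1 − r̄),
SNR = n·r̄/(1 − r̄); negative r̄ reports both as 0, r̄ = 1 reports SNR = ∞.
The reliable span is the union of the longest contiguous run of 20-year
windows (10-year overlap, anchored at the first year, one right-aligned
remainder window) with EPS ≥ 0.85.

## Detectors

**Pointer-year method.** Thresholds follow the field vocabulary
(`change.l`, `sync.l`, `change.e`, `sync.e`). Two readings of "RGC below the
threshold change" are possible; the default **drop** semantics tests
RGC ≤ 100 − change (a decline of at least `change` %), because the published
optimal values of 10–15 would otherwise demand an 85–90% seasonal-wood
collapse, inconsistent with the weak per-event growth effects these
outbreaks produce. The literal **ratio** semantics (RGC < change) is
selectable. Synchrony denominators count only trees with a defined RGC in
the tested year; a year with fewer than 5 evaluable trees is skipped.
Adjacent flagged years are merged keeping the earliest (one episode
produces overlapping signatures); the merge distance `min_event_gap`
defaults to 2 years. Regional events merge site events by single linkage
with a 2-year tolerance.

**OUTBREAK.** "Indices ≤ std × standard deviation" is read as indices at or
below mean − std·sd, the convention of the host-tree suppression literature;
a constant series (sd = 0) produces no flags. The abruptness ratio is
computed on the detrended index series, consistent with criterion (a). The
stand threshold is ≥ 10% of covered trees.

**MWM.** Raw (absolute) total widths, per the method's definition. Strict
minima only — a within-window tie disqualifies both years (configurable);
edge years without a full window are never flagged. The stand proportion
uses trees whose series cover the full window. The known false-negative
mode — one episode's minima split over two adjacent years, each below
`perc` — is reproducible, and an experimental `adjacent_sum` option (sum of
two adjacent years' proportions) is provided, off by default.

**MICA.** Series are truncated to the latest common start (the number of
removed early years is reported), z-scored per tree, and decomposed with
FastICA (tolerance 1e-3, up to 2000 iterations, three deterministic
restarts from seeds derived from the given one). Components are rescaled to
unit variance and sign-oriented to correlate positively with the mean
standardised series so that "below `lim`" is well defined. The default
component count is the smallest number of principal components explaining
≥ 80% of variance, capped at 5. A preliminary run (any component < `lim`
for ≥ `lng` consecutive years) is confirmed when the spline-detrended site
chronology dips below its `q`-quantile (computed over the analysed span)
within `rng` years of the run; confirmed overlapping runs merge and report
their first year.

## Parameter optimization

A detection hits a documented outbreak window when an event year falls
inside it or up to `match_lead` = 2 years before its first year. PYM, MWM
and MICA grids are scored lexicographically: windows hit, then fewer false
positives, then the most stringent thresholds (ties broken by grid order);
OUTBREAK maximises the mean flagged-tree proportion inside the windows
subject to hitting all of them. If nothing hits every window the best-effort
set is returned with a warning.

## Concordance

The unit of the 2×2 table is the calendar year of the analysed span. Each
pointer-year event consumes the earliest unconsumed reference-method event
within 0–4 years after it (A), otherwise counts as unconfirmed (B);
leftover reference events are false positives at their own year (C); all
remaining years are D. Sensitivity A/(A+B) therefore equals the confirmed
fraction of pointer-year events and is independent of the span — which is
why the published sensitivity cells are exactly recomputable from the
printed event lists and confirmation counts, while accuracy and specificity
depend on the (unstated) span convention and are not treated as exact.
Fisher's exact test is two-sided with p = 1 at a zero margin;
Benjamini–Yekutieli adjustment uses the harmonic-sum factor and is applied
across whatever family the caller assembles (the site × method layout by
default).

## Climate and defoliation

Candidate predictors are the 42 monthly variables from January of the
previous year to September of the growth year (mean temperature and
precipitation sum; lowercase month = previous year, uppercase = growth
year). Screening is a bootstrapped response function: per resample the
chronology is regressed on the principal components of the standardised
monthly matrix (components kept to ≥ 90% cumulative variance, at most a
third of the sample size) and the coefficients are back-transformed; a
variable is significant when its 1000-draw 95% percentile interval excludes
zero. Models are ordinary least squares with backward stepwise elimination
by AIC; the defoliation indicator O_t (1 at lags +1 and +2 after each
event, per the two-year suppression seen in the epoch analysis;
configurable) is never eligible for elimination. The added value of O_t is
assessed by refitting both models on 100 linked bootstrap resamples of the
years and comparing the paired R²adj series with Friedman's rank test. The
two-sample Friedman statistic is computed directly (with tie correction,
df = k − 1) because the common implementations require k ≥ 3; it agrees
with them for k ≥ 3.

A caveat established during development: as a *null-calibrated test* the
linked-bootstrap Friedman comparison is anti-conservative. When the true
dummy effect is zero, the sign of each resample's ΔR²adj tracks whether the
resampled dummy t² exceeds ≈ 2(n−p)/n, and the resampled t clusters around
the full sample's chance value — so block wins are systematically
imbalanced in one direction or the other and the test rejects for a large
share of null datasets (measured ≈ 76% at the 5% level). The procedure is
therefore evidence of an effect only jointly with the effect-size estimate,
not a stand-alone significance machine; the package reports it as the
published analysis defines it.

Superposed epoch analysis averages the chronology's departure from its mean
at lags −3…+5 around the event years and compares each lag against 1000
random same-size event draws (two-sided percentile test, α = 0.05).

## The synthetic test-bed

`simulate_site` generates, per tree, width = age trend × climate modifier ×
exp(stand factor + tree factor + noise), split 70/30 into earlywood/
latewood with a small per-year jitter, with defaults chosen once to match
the study conditions the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| trees × years | 20 × 100 | typical screened stand and reliable span |
| age trend a, b, k | 1.5, 0.05, 0.55 mm | mature pine: fast juvenile decline to ≈ 0.6 mm |
| tree factor | AR(1), φ = target + 0.07, sd 0.105 | realized detrended lag-1 autocorrelation ≈ 0.75 (target 0.8, band 0.7–0.9); the +0.07 offsets the slight whitening of spline detrending |
| stand factor | AR(1), φ = 0.99, sd 0.22 | decadal-scale common signal giving r̄ ≈ 0.35 and EPS ≥ 0.85 at 20 trees; its year-to-year change is negligible, so it cannot fake the synchronous one-year drops the pointer-year method keys on |
| white noise | sd 0.01 (log) | measurement-scale noise |
| earlywood share | 0.70 ± 0.02 per year | seasonal partition jitter; it perturbs the earlywood/latewood channels without touching the total width |
| climate effects | May/June precip +, July temp − (±0.003–0.004 per z) | the response structure the climate models assume |
| defoliation | responders 70%; latewood −40% (t+1), earlywood −30% (t+2), whole ring −25% (t+1..t+2) | seasonal signature plus the lagged whole-ring trough (the whole-ring term is omitted when only the seasonal signature is under study) |

Monthly climate is a seasonal sine (annual mean 1.8 °C, July 19.6 °C,
continental amplitude) with white noise, and lognormal monthly
precipitation.

What the passing tests show — and do not. On this generator the
pointer-year method recovers injected events exactly and lag-free in ≈ 96%
of stands, OUTBREAK and MWM fire 1–4 years late, and ICA events never
precede the event. Real stands add non-stationary age structure, uneven
sample depth, crossdating error and climate–defoliation interaction, none
of which are modelled; the tests validate the algorithms' logic, not their
field error rates. Two synthetic behaviours deserve note. First, the MWM
cannot be made silent on event-free data at its published synchrony
threshold: for any continuous stationary series a tree has a strict
window minimum in a given year with probability ≈ 1/(2·width+1), so with
20 trees the expected number of chance ≥ 35% synchrony years is of order
one per century even for independent trees — consistent with the method's
documented false-positive propensity. Second, the synthetic ICA detector
is much less sensitive than its real-data counterpart: the z-scored raw
matrix is dominated by the shared age trend, which compresses event dips
in the components; its null behaviour and lag direction are still
informative.

## Degenerate inputs and tie-breaks

Zero-variance trees fail ICA standardisation with a named error; constant
detrended series produce no OUTBREAK flags; empty event lists are valid
detection results; a zero margin yields Fisher p = 1 and undefined
(NaN) sensitivity or specificity; grid-search ties resolve by declared
stringency and then grid order; all stochastic components (generator,
FastICA, bootstraps, epoch analysis) are reproducible bit-for-bit from the
seeds they are given.

## Problem sizes

The test suite and the acceptance script use 50-seed detector suites
(20 trees × 100 years), 100-seed coefficient-recovery runs and 20-seed
bootstrap/epoch runs; together they complete in a few minutes on one CPU.
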
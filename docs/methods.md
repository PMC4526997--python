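# Methods

This note records the scientific conventions, parameter defaults, and
numerical choices behind `mobisense`, and what the synthetic cohort does
and does not establish.

## Data model and sufficiency filter

Timestamps are UTC epoch seconds; local time comes from a fixed
per-participant timezone offset in hours (no DST). "Available for more
than 50% of the time" is operationalized per stream: location coverage
is the fraction of 5-minute bins of the study period containing at least
one GPS fix (5 minutes being the nominal sampling period); usage
coverage is the fraction of local calendar days containing at least one
screen event. Eligibility is strict (> 0.5) and computed independently
for the two streams, since location and usage analyses admit different
subsets of a cohort. Clock-time binning is one of several defensible
readings of "time" (waking hours would be another); any consistent
definition suffices for synthetic data.

## Preprocessing

* **Speed labeling.** Backward-difference speed per sample
  (haversine distance / elapsed time, Earth radius 6371 km); the first
  sample inherits the second's speed. *Stationary* iff speed < 1 km/h
  (strict). Samples following a sampling gap longer than `max_gap_s`
  (default 900 s, three nominal periods) are labeled *unknown*: a single
  displacement across an outage is not a movement estimate. Unknown
  samples are excluded from clustering, occupancy, and transition time,
  and gap legs contribute zero to total distance.
* **Clustering.** K-means (scikit-learn, k-means++, 10 restarts, fixed
  seed) over stationary (lat, lon) in degrees, K incremented from 1
  until the farthest sample of every cluster lies within 500 m
  (haversine) of its center, centers taken as coordinate means; K is
  capped at `min(n_points, k_max=50)` and exceeding the cap without
  satisfying the radius rule raises rather than returning a model that
  violates the contract. Occupancy counts stationary samples — a proxy
  for time that is exact under uniform sampling; time-weighted occupancy
  would be the alternative under heavily irregular sampling.
* **Home cluster.** Among the three most-visited clusters, the one with
  the most stationary samples between 00:00 and 06:00 local time; ties
  break by overall count then lowest index. With no night samples at
  all, the most-visited cluster is used and flagged. The heuristic
  assumes no night-shift schedules.

## Features

Natural logarithms throughout; this is fixed by the occupancy-entropy
worked examples (an 80/20 split gives −(0.8 ln 0.8 + 0.2 ln 0.2) ≈
0.500, a 50/50 split ≈ 0.693). Location variance uses population
variance in degrees², matching the direct use of coordinates in the
definition; the choice of units shifts the log by a constant and cannot
affect correlations. Normalized entropy is defined as 0 for a single
cluster (all points in one place).

**Circadian movement.** The Lomb–Scargle periodogram (scipy) of the
mean-centered latitude and longitude series on the irregular time grid.
The conceptual frequency grid runs from 1/span to 1/(2 × median
sampling interval) with spacing 1/(5 × span) (oversampling 5); the
24-hour band keeps bins with period in [23.5 h, 24.5 h] inclusive,
expanded to the two nearest bins if the grid is too coarse to place two
bins inside the band (traces shorter than ~10 days). `E` is the *mean*
band power — the printed form of the band-average denominator is
sign-inconsistent under the stated bin ordering, and the mean is the
only reading that keeps `E` positive; a summed-power variant would
rescale CM by a constant and leave all correlations unchanged. Only the
band ordinates are evaluated (each Lomb–Scargle ordinate depends only
on its own frequency), which keeps Monte-Carlo cohorts cheap; a
full-grid function (`circadian_band`) is exposed for diagnostics.
Constant signals are assigned exactly zero band power, so a constant
trace yields NA rather than log of numerical dust. Traces shorter than
24 h yield NA.

**Usage features.** Screen sessions pair each `on` with the next `off`
(consecutive `on`s collapse to the first; a trailing unmatched `on` is
dropped with a warning); sessions shorter than 30 s (strict) are
discarded as notification-driven. Frequency and duration divide by the
inclusive local-calendar-day span of the participant's events.

## Association statistics

Pearson r with the two-sided t-transform p-value (n − 2 df),
pairwise-complete over NA; the group comparison at the PHQ-9 ≥ 5 cutoff
uses the Welch (unequal-variance) t-test by default — the robust default
when group variances are unknown — with the pooled-variance variant
available via `equal_var=True`. No multiple-comparison correction is
applied: these are exploratory statistics and correction is the
caller's prerogative.

## Severity models

Features are standardized to zero mean/unit variance inside each
training fold; coefficients are reported on both scales. The elastic-net
penalty is `λ₁‖w‖₁ + λ₂‖w‖₂²` with the intercept unpenalized (standard
practice). The squared L2 term is the conventional elastic-net form; an
unsquared L2 norm admits no closed ridge limit and is not what standard
solvers implement. Fits map onto scikit-learn's `ElasticNet` and
`LogisticRegression` parameterizations exactly (`α`, `l1_ratio`, `C`
derived from λ₁, λ₂); the unpenalized paths use `lstsq` and
high-precision lbfgs and are verified in the tests against
normal-equation and IRLS oracles. λ grids are logarithmic, 10 points
over [1e−4, 1e2] per penalty, tuned by 5-fold CV on training data only.
Matching the study's usage, regularization is auto-enabled only when a
feature set has more than two features.

**Evaluation protocol.** B bootstrap resamples of participants (drawn
with replacement; single-class resamples are redrawn and counted), each
evaluated by leave-one-entry-out cross-validation; held-out predictions
are pooled within a resample to give its accuracy/sensitivity/
specificity and NRMSD (RMSD divided by the observed score range of the
cohort), then averaged across resamples (SDs are population SDs, zero
at B = 1). B = 1 uses the identity resample and therefore equals plain
leave-one-participant-out CV. Duplicated participants can appear on
both sides of a fold — an optimism inherent to bootstrapping a LOPO
protocol; the report carries the realized leak rate
(`duplicate_leak_rate`), and `unit_level=True` holds out all copies of
a participant together instead. Unpenalized regression folds use the
exact hat-matrix leave-one-out identity `e_i/(1 − h_ii)` (OLS
predictions are invariant to per-fold standardization, so this is
algebraically identical to refitting; the tests verify equality with a
physical refit loop). A leave-one-out training fold that contains a
single class predicts that class (degenerate but well-defined; rare
except in tiny or extremely unbalanced resamples).

## Synthetic cohort

The generator emulates the statistical structure the features measure,
not demographically realistic mobility (no road networks, no
origin–destination matrices):

* **Anchors.** `n_anchors` significant places on a planar patch around
  a configurable origin, home at the center, others rejection-sampled
  on a disk of radius `mobility_scale_km` with pairwise separation
  > 1.2 km (2.4 × the 500 m clustering radius), so each visited anchor
  maps to exactly one recoverable cluster.
* **Days.** With probability `regularity` a day is canonical (depart
  09:00, visit the non-home anchors in fixed order with equal stays,
  return after an away window set by `home_stay_frac`); otherwise
  departure time and anchor order are shuffled. Nights are always at
  home (the away window is capped at 16 h), so the home heuristic's
  assumption holds by construction. Transitions are constant-speed
  (25 km/h) interpolated runs, well above the 1 km/h threshold.
* **Observation.** Gaussian GPS jitter (`gps_noise_m`), uniform sample
  thinning to `coverage`, Poisson screen sessions per day with
  exponential durations (which naturally include sub-30 s blips).
* **Severity link.** u ~ U(0,1) per participant; behavioral parameters
  are `baseline + slope·u` (clipped to their valid ranges; anchor count
  rounded); PHQ-9 = round(clip(27·u^γ + N(0, 2))). γ = log₂(27/4.5) ≈
  2.585 places the rounding boundary of the score-5 cutoff at the
  median latent, so default cohorts split roughly half/half at the
  cutoff — echoing the 14/14 design — while keeping scores monotone in
  u; γ = 1 recovers a plain linear map. The default slopes plant the
  six associations the analysis should recover (lower normalized
  entropy, location variance and circadian movement; higher home stay,
  usage frequency and usage duration at higher severity), with the
  usage-feature association planted positive. Defaults (28
  participants, 14 days, 300 s sampling; baseline 4 anchors, home-stay
  0.55 + 0.35u, regularity 0.9 − 0.6u, mobility scale 6 − 4u km, GPS
  noise 15 m, 15 + 30u sessions/day of mean 70 + 110u s, coverage
  0.85) were chosen as behaviorally plausible urban values spanning
  withdrawn-to-active ranges.

What passing tests show: the pipeline recovers planted cluster counts,
association signs and separability under clean, strong links with
near-uniform sampling and isotropic noise. What they do not show:
performance under real GPS artifacts (urban-canyon multipath, indoor
dropout correlated with place, device heterogeneity), schedule
structure beyond a one-daily-loop model, shared phones, night-shift
work, or real effect sizes — real-cohort correlations and accuracies
will be substantially weaker than the synthetic ones.

## Problem sizes and runtime choices

Monte-Carlo checks use 50 replicates of n = 100 cohorts for sign
recovery, 50 generator seeds per regularity level for the circadian
comparison, and B = 50 bootstraps for protocol sanity; the acceptance
script evaluates the normalized-entropy models at the protocol's
B = 1000 on the default n = 28 cohort. These sizes give stable
Monte-Carlo estimates at interactive runtimes on one CPU.

## Known limitations

* Occupancy is sample-count-, not dwell-time-, weighted.
* Clustering operates in raw degree space; longitude compression
  (~cos latitude) is ignored within the city-scale patches the radius
  rule implies, and only the radius check uses exact haversine
  distances.
* The coverage filter's "time" is clock time, not waking time.
* The bootstrap-within-LOPO protocol is optimistic by construction
  (duplicate leakage); the reported leak rate quantifies, but does not
  remove, that optimism.
* PHQ-9 is treated as a plain integer outcome; no item-level structure
  or measurement error model.
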
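# Methods

This note records the models, the processing conventions, and the design
choices made where the published processing description left the design
open. It documents what the code does and why; every number quoted here
is computed by the test suite or by `scripts/acceptance.py`.

## Fix-level cleaning

The cleaning chain runs in a fixed order — drop incomplete records →
compute forward kinematics → remove outliers → de-duplicate timestamps →
flag non-wear. Conventions that the thresholds alone do not pin down:

* **Forward attachment.** Distance, interval and speed between a fix and
  the *next* fix are attached to the earlier fix; the last fix of a
  trace carries no kinematics and contributes no time.
* **Outlier removal is single-pass.** A fix is removed iff its forward
  speed exceeds 50 m/s or its forward distance exceeds 30 m (strict
  inequalities). Kinematics are recomputed once over the survivors, not
  iterated to a fixed point: a bridged interval across removed fixes may
  legitimately exceed 30 m and then represents a spatial gap, not a new
  outlier.
* **Duplicate timestamps** keep the earliest-in-file fix. A zero-length
  interval has undefined (not infinite) speed, so the outlier rule never
  pre-empts the duplicate rule.
* **Distances** are haversine on a sphere of radius 6 371 km. At the
  30 m threshold scale the ellipsoidal correction (< 0.5 %) is
  immaterial. Stop detection uses a local equirectangular plane for its
  centroid-radius test; the discrepancy against the sphere at 150 m is
  sub-centimeter.
* **Days and midnight.** Timestamps are zone-naive local civil time and
  a day is the local calendar date. Each fix contributes its forward
  interval to the day of its own timestamp; an interval spanning
  midnight is split at midnight so daily totals conserve time exactly.

## Intensity and location

Heart-rate thresholds are fixed per participant for the whole study
period (age at enrolment, mean of daily resting heart rates). The
20–39 % band's upper edge is implemented as `< 40 %` so the three bands
partition the heart-rate line; heart rates are classified unrounded.
Implausible device values (outside 20–250 bpm) become missing at ingest
and are then dropped with the other incomplete records.

Indoor/outdoor labelling is planar point-in-polygon on raw lon/lat
(adequate at building scale), boundary-inclusive toward indoor, with the
five-consecutive-fix rule converting short outdoor runs to indoor, never
the reverse. Runs cannot span a non-wear gap: "consecutive" is read as
consecutive in worn time.

## Stops, trips, outdoor walking

Stops come from a greedy left-to-right scan within each participant-day
(also broken at non-wear gaps): a candidate grows while the next fix is
slower than 0.5 m/s and lies within 150 m of the running centroid, and
is a stop when the members' worn forward intervals total at least two
minutes. The duration is the summed member intervals — the stretch of
time the qualifying speeds actually describe — not last-minus-first
timestamps, which would undercount by one interval.

Trip candidates are maximal runs of in-transit fixes; the ≥3 min /
≥100 m / ≥1 km/h screen is applied once, and mode is then assigned from
the 90th percentile of per-fix speeds (type-7 linear interpolation
between order statistics). The speed bands are half-open so no trip can
carry two modes; a screened trip whose 90th-percentile speed still falls
below 1 km/h keeps mode `none`. Day-level inclusion (≥ 9 h wear, then
≥ 4 surviving days per participant) runs before segmentation, and "nine
hours of data" is read as wear time, not elapsed span.

## Weather merge

Stations are matched to residences by great-circle distance once per
participant (no per-day switching), ties broken by lowest station id.
The merge preserves participant-day rows exactly: missing station
weather flags the row `incomplete` rather than dropping it, and a
missing mean temperature is *not* imputed from (tmin+tmax)/2 —
explicit missingness is preferred because the published station records
treat the three temperatures as separate measurements. Snow is
snow-on-ground (a level in cm), not daily snowfall. Daylight hours use
the NOAA low-accuracy solar series with the standard 90.833° zenith;
against published sunrise/sunset tables for the study region's latitude
the error is ~2 min, and polar day/night clamp to 24/0 h.

## Multilevel models

Nine Gaussian random-intercept models (REML, via `statsmodels` MixedLM)
with days nested in participants. Day-level weather enters as
within/between pairs: the daily term is the deviation from the person
mean, the overall term is the person mean centered on the *unweighted*
grand mean of person means (weighting by days would let wear compliance
leak into the between-person axis). Age and health are grand-mean
centered; sex (female = 1), freeze-thaw, tropical night, weekend and the
1-based study-day index enter uncentered. Complete cases per model;
centering is computed on the analysis sample.

Inference is Wald/normal (estimate ± 1.96·SE); the output metadata
records this since small-sample t/Satterthwaite corrections would differ
slightly at 40 groups. ICC comes from an intercept-only model as
τ₀₀/(τ₀₀+σ²). R² follows the variance-partition (Nakagawa) form with
the fixed-effect variance taken as the sample variance (ddof = 1) of the
fixed linear predictor. Degenerate situations are reported, not raised:
a zero-variance outcome yields a flagged all-zero fit, near-zero τ₀₀
sets `singular=True`, and a predictor with no variation in the analysis
sample (e.g. no tropical night fell inside any participant's window) is
excluded from estimation and reported as NaN. A design that is rank
deficient beyond constant columns (too few participants for the
person-level terms) raises, since no coefficient is interpretable.

The statsmodels fit is cross-checked in the test suite against an
independent REML implementation (`lme4` via Rscript) on one synthetic
dataset; fixed effects agree to 1e-4 relative and variance components to
1e-3.

**Power.** The power simulator draws a unit-variance outcome with the
requested intraclass correlation, plants a slope on a standard-normal
within- or between-person predictor, fits the mixed model and counts
Wald p < 0.05. Its realized type-I error at 40×10 is ≈ 0.05 (0.048–0.064
across seeds at 500 replicates).

## Synthetic cohort

The device-level generator emulates the study conditions: 40
participants aged 60–85 (≈ 5:3 female:male, self-rated health centered
near 4), 10 consecutive days each with start dates spread over a full
year, ~12.7 h of daily wear, and fixes every 5 s at rest and every
1–2 s while moving fast (emulating the device's adaptive recording — and
necessary for realism, since a 40 km/h vehicle sampled at 5 s would
produce 55 m inter-fix legs that the 30 m cleaning screen would remove).
Each participant-day is a schedule of behaviour blocks (home dwell,
indoor LPA/MVPA, gardening, walks, brisk walks, bike rides, vehicle
errands to a distant plaza) on a street-grid village, with heart rate at
a state-typical fraction of the person's HRR (10 % dwell / 30 % walk /
55 % vigorous) plus 5 bpm Gaussian noise.

Choices that matter for what the tests demonstrate:

* **GPS error is AR(1)** (stationary SD 1.2 m, φ = 0.95 per fix), not
  i.i.d. — independent per-fix noise would make a stationary wearer
  appear to move at nearly the 0.5 m/s stop threshold, which real
  autocorrelated GPS error does not do.
* **The worn day span is drawn independently of the activity draws**
  (Normal, mean 757 min ≈ 12.7 h of wear after gaps), with idle home
  time absorbing the slack, and occasional short days (device started
  late) are generated below the nine-hour rule by construction. If the
  day length were the sum of the activity blocks, the nine-hour
  inclusion rule would select on the planted outcomes and bias the
  recovered weather slopes — a selection artifact worth remembering when
  interpreting wear-time-based exclusions on real data.
* **Snowpack has its own dynamics** (accumulation from cold-day
  precipitation, melt from warm maxima) rather than being a function of
  temperature; a deterministic snow–temperature link would make the
  within-person snow and temperature terms collinear and split the
  planted temperature slope between them.
* **Planted effects** sit at the minutes scale: the within-person
  temperature slope (+2.33 min/°C) on gardening time, the freeze-thaw
  shift (−11.57 min) on walks, the female indoor-LPA shift
  (+62.86 min). Person-level baselines (walk ≈ 45 ± 10 min, garden
  ≈ 30 ± 6 min) give the outcomes a realistic between-person variance
  share.

What the generator does *not* emulate: real street networks, GNSS
multipath and urban-canyon error structure, behavioural feedback between
weather and indoor activity choice, device-specific heart-rate bias, or
seasonal wardrobe/terrain effects on gait speed. Passing tests therefore
show that the pipeline recovers structure *of this kind* faithfully, not
that any specific real-world cohort would behave this way.

**Measurement attenuation.** Heart-rate noise misclassifies ~5–9 % of
minutes near band edges, so device-level recovered coefficients are
shrunk a few percent toward zero relative to their planted values
(single-cohort estimates of the 2.33 min/°C slope scatter roughly over
2.1–2.4). The end-to-end test asserts recovery within a tolerance
that reflects this honest measurement loss. Nominal-coverage claims
(93–99 of 100 replicate CIs covering truth) are checked at the
panel level, where outcomes are drawn directly from the fitted model
family at the published variance scales (σ² = 2167.65, τ₀₀ = 1059.45
for outdoor LPA; σ² = 882.87, τ₀₀ = 310.38 for outdoor walking):
running 100 full device-level cohorts would measure the same estimator
property at ~100× the cost.

## Problem sizes

The default test and acceptance runs use: one full device-level cohort
(40 × 10 days, ≈ 3.8 M fixes) for conservation, accounting and
end-to-end recovery; 100 panel cohorts (40 × 10) for CI coverage; 500
replicates for the type-I error of the power simulator; 1,000-fix random
instances for the brute-force oracle comparisons. Smaller cohorts (2–4
participants, shortened days) exercise file round-trips and orchestration.

## Known limitations

* Wald/normal CIs are slightly liberal at 40 groups; a t-based
  correction would widen them marginally.
* The stop detector is the text's three-threshold contract implemented
  as a greedy scan; other clusterings satisfying the same thresholds
  (e.g. with hysteresis) could split borderline dwells differently.
* Outdoor walking minutes depend on the interaction of trip detection
  with the five-fix location rule; short walks near buildings are
  systematically undercounted, as they would be on real data.
* The guideline-attainment share is computed as participant mean daily
  MVPA × 7 > 150 min; on the synthetic cohort (deliberately active)
  this is 100 %.
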
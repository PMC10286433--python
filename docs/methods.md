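# Methods

`crowdstress` implements an individual-level analysis chain for studying
how street-level overcrowding relates to momentary physiological stress,
as measured by a wrist-worn sensor during guided city walks. This note
documents the models, the defaults and the reasoning behind the open
design choices.

## Change score from skin conductance and skin temperature

Sympathetic arousal produces a skin-conductance response (SCR): a phasic
rise of the galvanic skin response (GSR, µS) over the tonic level,
typically accompanied by a small drop in skin temperature (ST, °C). The
per-second **change score** CS quantifies this with four rules evaluated
on a trailing window (default 8 s) ending at each second:

| Rule | Quantity | Partial (0.5) | Complete (1) |
|------|----------|--------------|--------------|
| R1 | trough-to-peak GSR amplitude (µS) | ≥ 0.05 | ≥ 0.10 |
| R2 | least-squares ST slope (°C/s) | ≤ −0.002 | ≤ −0.005 |
| R3 | trough-to-peak rise time (s) | in (5, window] | in [1, 5] |
| R4 | amplitude / rise time (µS/s) | ≥ 0.01 | ≥ 0.02 |

Each rule scores ternary (0 / 0.5 / 1) and CS = Σ wₙ·sₙ with default
weights wₙ = 20, so CS ∈ [0, 80] and is a multiple of 10 under defaults.
The ternary scheme and the 0–80 range over four rules are the method's
fixed constants; the individual thresholds are this package's defaults,
chosen at standard SCR magnitudes (conventional SCR detection thresholds are of
order 0.01–0.05 µS; rise times of 1–5 s are typical). Equal weights are
the unique symmetric choice consistent with a maximum of 80 over four
rules. Every threshold lives in `ScoringParams` and is serialized with
results for provenance.

Implementation choices:

- **Trailing (causal) window**, not centred: scores are computable in
  streaming order and the score at second *t* uses no future samples.
- **Trough definition**: the trough is the running minimum before the
  window's maximum; ties take the latest index (shortest rise time).
- **Preprocessing** blanks physiologically implausible samples (GSR
  outside 0.01–100 µS, ST outside 20–40 °C — bounds decided here),
  linearly interpolates gaps up to 2 s, splits streams at longer gaps,
  and smooths with a 1 s centred moving average. Rational-ratio
  resampling (`scipy.signal.resample_poly`) aligns off-rate streams.
- Scoring covers sitting and walking alike; any baseline filtering
  happens downstream on the fused records.

## Proxemics zones from detections

Per-frame object detections (COCO vocabulary) are mapped to four
overcrowding categories: human crowds (*person*), motor vehicles (*bus,
car, truck, motorcycle*), bikes (*bicycle*) and sitting facilities
(*chair, bench, dining table*); all other labels are ignored.

Each person is assigned one distance zone using the perspective proxy
d = |Yᵢ − h|, the pixel gap between the bounding-box bottom edge Yᵢ
(y_top + height, origin top-left, y downward) and the image bottom
h = image height:

1. **personal space** if the instance-mask fraction exceeds 10% of the
   image (checked first — a person this large has entered the wearer's
   personal space regardless of d);
2. otherwise **close** if d ≤ 5 px, **medium** if 5 < d ≤ 100 px,
   **far** if d > 100 px.

Stated as open intervals — "(5, 100)" and "over 100" — the bands would
leave d = 5 and d = 100 unassigned; this package closes them upward
(d ≤ 5 close, d ≤ 100 medium), making the zones an exact partition. Thresholds are in
native-frame pixels (they were calibrated on sample frames of one
camera); `ZoneThresholds.reference_height` enables proportional rescaling
for other resolutions. The bottom edge (not the centroid) is used as Yᵢ,
and the mask area (not the box area) defines the personal-space
fraction. Detections below `min_confidence` (default 0.5, a decision of
this package) are dropped before counting.

## Fusion

All streams join on the change-score timeline: each scored second takes
the zone counts of the nearest frame within ±1 s (frames are nominally
1 Hz, so nearest-within-tolerance is a join, not a resampling) and a
linearly interpolated GPS position (lat/lon interpolation; at walk-scale
distances the deviation from great-circle interpolation is far below GPS
noise). Seconds without a frame or a bracketing fix are dropped and
counted by cause, so `records_out + dropped_no_frame + dropped_no_gps =
records_in` always holds. Site labels come from point-in-polygon lookup
(boundary points count as inside; overlaps resolve to the first-listed
polygon with a warning). Clock offsets beyond a 600 s sanity bound abort
with a diagnostic rather than silently fusing disjoint sessions.

## Mixed model

The global association model is a Gaussian linear mixed model (identity
link) per site:

CS ~ persons_personal + persons_close + persons_medium + persons_far
     + motor_vehicles + bikes + sitting_facilities
     + (1 | timeslot) + (1 | participant) + (1 | gender)

The continuous, roughly symmetric change score with residual variances
in the hundreds supports the Gaussian reading of "GLMM" here. Fitting is
REML via `statsmodels.MixedLM` with variance components over one
umbrella group (timeslot and gender partition participants, so the
groupings are crossed only above the participant level and the umbrella
formulation represents them exactly). CIs are Wald at 95%; significance
bands *** / ** / * at 0.1% / 1% / 5%. Gender enters as a random
intercept to mirror the study design even though two levels is
degenerate; the fitter warns, and a config can move it to a fixed
effect.

When a variance component is estimated at the zero boundary the REML
Hessian is singular and no standard errors exist; the fitter then drops
the coarsest degenerate grouping and refits, reporting its τ00 as 0.00.
ICC = Στ00 / (Στ00 + σ²), undefined (reported as a dash/NaN) when the
total random variance is ~0. R² follows Nakagawa: marginal =
var(Xβ)/total, conditional adds Στ00; conditional is undefined when the
random part collapsed.

## Geographically weighted regression

The local model is a fixed-Gaussian-kernel GWR: at each record location
a weighted least-squares fit with weights w = exp(−d²/(2b²)) over planar
metres. Coordinates come from a local equirectangular projection centred
on the data centroid — at sub-kilometre walk extents the distortion
versus a conformal projection is negligible. The bandwidth b is either
fixed or chosen by AICc minimisation (bounded golden-section search over
a log-spaced bracket spanning ~1%–400% of the data extent). Outputs per
record: local coefficients, fitted value, leverage (the diagonal of the
hat matrix) and standardized residual r/(σ̂√(1−leverage)). Locally
singular designs (a predictor without weighted variance in the
neighbourhood) yield NaN coefficients at that point instead of a crash.
As b → ∞ all weights → 1 and every local coefficient converges to the
global OLS coefficient; this limit is asserted in the tests at b = 10⁶ m.
An adaptive (nearest-neighbour) kernel is not implemented; the fixed
kernel is the default reading absent a stated kernel policy. No
multiple-testing correction is applied (per-coefficient bands only).

GWR is O(n²); the pipeline thins fused records deterministically (every
k-th record) to at most 1500 points before fitting, a size at which the
bandwidth search completes in seconds on one core. Per-predictor
(one-at-a-time) fits are the default for map output; joint fits are
supported through the same API.

## Synthetic scenarios

The original field data are confidential, so a generator emulates the
study protocol: participants walk four ~180 m sites in order (green
garden, transit centre, commercial street, river bank), 5 min sitting at
the centroid plus 15 min walking an interior loop per site, two daytime
timeslots, alternating two-level gender labels. Default scenario
parameters are the study conditions: 20 participants, 4 Hz physiology,
1 Hz frames, 80 min sessions.

- **Counts**: independent Poisson per category/zone per frame with
  site-specific intensities (commercial busiest, green/blue quietest;
  sub-person-per-frame personal-zone rates). Optional AR(1) on the log
  intensity (default off) — no crowd-dynamics model is published, so
  independence is the default assumption.
- **Ground-truth change score**: CS\* = μ + Σβⱼ·countⱼ + b_person +
  b_timeslot + b_gender + ε, with defaults β_personal = 3.85 (the
  magnitude the recovery tests target), other effects 0, SD(b_person) =
  5.3, SD(b_timeslot) = SD(b_gender) = 0, SD(ε) = 16. These mirror the
  variance structure a study of this design reports (participant-level
  clustering, degenerate timeslot/gender components, residual variance
  ≈ 260); they are scenario defaults, not claims about the real data.
  CS\* is deliberately unclipped to keep the generating model exactly
  linear.
- **Physiology**: SCRs with linear rise (2–4 s) to 0.12–0.35 µS and
  exponential decay (τ 3–6 s), plus event-locked ST dips (0.05–0.15 °C),
  on a tonic level of 1.5–4 µS with slow drift and 0.005 noise SD.
  Events trigger at seconds with personal-space intrusions with
  probability min(0.8, 0.06·β_personal·count) — zero coupling when the
  true effect is zero — plus a spontaneous background rate of 1/120 s.
- **Detections**: fabricated geometry per drawn count, kept strictly
  inside the classifier's threshold bands (personal mask fractions
  0.12–0.35, non-personal ≤ 0.08; d sampled with margin inside each
  band), so generator zone labels round-trip through the classifier for
  100% of detections.
- **GPS**: 1 Hz piecewise-linear waypoint interpolation with 2 m
  Gaussian jitter (no published GPS noise model).
- Everything derives from one `SeedSequence`; per participant the track,
  scene and model-level streams are split so that ground truth is
  identical whether or not streams are fabricated (`truth_only` mode).

What the generator does **not** emulate: detector misses and false
positives, occlusion, camera shake, GPS multipath near buildings,
circadian/thermoregulatory ST trends, motion artefacts in GSR, and any
dependence between crowding and walking speed. Passing recovery tests
therefore show that the estimators recover effects *under the assumed
data-generating process*, not that the field pipeline is unbiased under
real-world measurement error.

## Parameter recovery and problem sizes

The recovery experiment (analysis/06_recovery.py and the acceptance
suite) runs 20 seeded replicates of the default scenario in ground-truth
mode, fits the mixed model on one site's ~24,000 records, and checks
that 95% CI coverage of the personal-space effect lies in [85%, 100%]
and the mean estimate sits inside the Monte-Carlo band of 3.85. Fitting
uses the ground-truth CS\* (the linear-model response) because that is
the quantity whose generating process the estimator assumes; the
physiology→scoring path is validated separately by an effect-injection
test (scored CS is significantly higher on seconds with personal-space
intrusions, one-sided Welch test at α = 0.01 over ≥ 5000 frames). The
rule-based scorer is a bounded nonlinear transform, so no claim is made
that regression on *scored* CS recovers β_personal numerically.

Test problem sizes were chosen so the whole suite runs on one core in a
few minutes: GWR fixtures use 400–600 points over a ~500 m strip, the
end-to-end determinism check runs the full 20-participant default
configuration twice, and desk-scale fixtures elsewhere use 10²–10⁴
records.

## Known limitations

- Scoring thresholds are package defaults, not published constants; CS
  values are comparable only under a fixed `ScoringParams`.
- The umbrella-group MixedLM formulation is exact for partition-type
  groupings (timeslot/gender above participants) but would need true
  crossed-effects machinery for general crossed designs.
- GWR standard errors are not reported (only standardized residuals);
  local inference under kernel smoothing requires effective-parameter
  corrections beyond scope here.
- The pixel-distance proxy ignores camera pitch and lens distortion;
  zones are ordinal proxies for ground distance, not metric distances.
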
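# Methods

## The activity model

A singly housed pig's gross activity is summarized by three ordinal states:
1 lying, 2 standing, 3 walking. The cascade mirrors how the states nest
physically: posture (body footprint seen from above) separates lying from
standing, and only a standing pig can be walking, so motion analysis runs
only on standing frames. The numeric codes are treated as an activity
scale: hourly means of the codes are the "activity level" that is
aggregated, normalized and validated. This is a modelling choice — a mean
of ordinal codes has no unique interpretation — but it needs only a single
threshold-free downstream pipeline and matches how such budgets are
commonly plotted.

Assumptions inherited from the facility being modelled: exactly one pig
per pen; fixed overhead camera; constant lighting while the lights are on
and pitch black otherwise (so a mean-intensity gate can segment recording
sessions); no dynamic shadows; humans (keepers) are occasional, visually
distinctive visitors.

## Sparse optical flow

Feature selection and tracking are implemented from first principles.

* **Scoring.** λ_min of the windowed structure tensor, gradients by central
  differences, box sums over a 5 px block (`feature_block`). Corners need
  2-D structure; edges and flat floor score ~0.
* **Selection.** Local maxima with score ≥ `quality_level` (0.01) × the
  ROI's best, kept best-first at pairwise distance ≥ `min_distance` (7 px),
  at most `max_features` (50). On a pig-box ROI this yields ~10–15
  features.
* **Tracking.** Classical iterative Lucas–Kanade, coarse-to-fine over a
  binomial-blur/decimate pyramid (`pyramid_levels` 3, `window` 21,
  `max_iters` 10, `epsilon` 0.01 px), bilinear subpixel sampling,
  gradients from the previous frame only. A point is LOST when its tensor
  is near-singular at the finest level (λ_min < 1e−4·window²), when it
  wanders out of the frame, or when its final mean absolute window error
  exceeds 20 gray levels. Points whose window does not fit inside a coarse
  pyramid level skip refinement at that level rather than ingesting
  clamped border samples; the finest level always refines.

None of these values is critical: they follow the conventional defaults of
widely used sparse-flow implementations and are exposed in `FlowParams`.
The tracker is validated against an exhaustive block-matching oracle
(`pentrack.flow_oracle`), which shares no code or failure mode with it:
over 50 textured pairs with integer shifts in [−4, 4]², mean absolute
error per axis is ~0.03 px (bound asserted: ≤ 0.5 px).

Features are re-detected every frame inside the current pig box rather
than tracked long-term — the quantity of interest is per-frame motion, and
re-detection sidesteps drift and occlusion bookkeeping. Flow runs on
full-frame pyramids with features restricted to the box (feature scoring
crops to the box, so cost tracks the pig, not the pen). Cropping the
frames themselves to the box plus a fixed margin was rejected: at 1 fps a
walking pig moves ~30 px between frames and would leave any small crop.

## Movement accumulation and thresholding

Per frame pair, the mean displacement magnitude over TRACKED vectors; per
one-second window aligned to integer timestamps, the sum of pair
displacements divided by the window length, in px/s. Each pair is credited
to the window of its **earlier** frame: motion measured between two
captures happened during the interval they span. This makes the 25 fps and
1 fps paths agree exactly in expectation — at 1 fps the window holds the
single inter-frame displacement itself — and avoids an off-by-one-second
lag at walking onsets/offsets.

`walk_threshold_px_per_s` defaults to 5. In the synthetic world walking is
30 px/s and standing jitter is < 1 px/s, so the threshold sits an order of
magnitude from both; on real footage it is the main site-specific
calibration knob (it should scale with camera height/resolution).

Degenerate inputs: a standing frame with no movement estimate (first frame
after a dark gap, featureless box, all points LOST) falls back to state 2
with a `low_confidence` flag — unknown motion is not evidence of
stillness. A lit frame with no selected pig yields an UNKNOWN record
rather than carrying the last state forward; aggregation drops UNKNOWNs.

## Reference detector and its confidence scale

The reference detector background-subtracts against the known floor gray,
binarizes at +40 gray, fills holes, labels 8-connected components and
discards specks (< 100 px²). Components with mean gray ≥ 200 are keepers;
the largest remaining component is the pig, lying iff its area ≥
`area_split_px` (1100 px², between the standing ≈ 691 px² and lying
≈ 1319 px² footprints). Pig confidence is min(1, area / (2·area_split)),
i.e. ≈ 0.60 lying and ≈ 0.31 standing; the `detect` interface default
threshold is 0.5, but the pipeline default is 0.25 so standing pigs
survive the reference detector's scale. A trained object-detection model
would be wired in behind the same `Detector` protocol with its own
confidence calibration (an `nms` hook exists for detectors whose raw boxes
overlap).

## Synthetic scenes: what they emulate, what they don't

The generator emulates the target facility at 1 px/cm: a 240×266 px pen,
uniform gray-60 floor, a 12 h light cycle (dark frames are emitted, not
skipped, so gating is testable), a speckle-textured elliptical pig (mean
gray 150; lying 60×28 px axes, standing 44×20 px), a gray-220 keeper
rectangle at a fixed spot by the gate, and a gray-90 ball distractor that
deliberately sits below the detector's binarization threshold. Behaviour
is a per-second Markov chain over the three states in which walking is
reachable only from standing and the standing→walking rate scales with an
hourly propensity profile; mid-range propensity gives roughly 45 % lying /
45 % standing / 10 % walking with minute-scale lying bouts and walking
bouts of a few seconds. A walking pig moves at 30 px/s, turning once per
second (σ = 0.3 rad); a resting pig holds position and heading, so
consecutive resting captures differ by sensor noise (σ = 3 gray) alone.
Everything is a pure function of (config, seed); per-frame noise is seeded
by (seed, frame index), so lazily re-iterating a scene is byte-identical.

What the synthetic benchmark **does** show: the cascade's logic, the flow
arithmetic, the window accounting, the frame-rate equivalence and the
aggregation identities are correct, because they recover a known truth
almost perfectly (≥ 99 % per-frame accuracy at both rates on the study
scene). What it does **not** show: performance under real imaging —
deformable bodies, partial occlusion by pen furniture or hay, detector
misclassifications of walls and balls (the ball here is invisible to the
reference detector by design), lighting drift. Real-data accuracy is a
property of the detector model and site calibration, not of this code
path, and published figures for comparable real systems (~90 % frame
accuracy) should be the expectation there.

## Aggregation

Hourly activity is the mean state code per (pig, hour-of-day), pooled
across days; each hour is then divided by the pig's own all-time mean
(computed over all its usable records regardless of day or health status).
A ratio rather than a difference keeps the quantity scale-free across pigs
with different baselines; by construction the record-weighted mean of the
ratios is exactly 1, which the tests assert to 1e−9. Keeper-present
records can be excluded (default), kept, or kept-but-flagged for
stratified analysis, since keeper visits provoke non-spontaneous activity.

## Validation statistics

Accuracy is pooled over instances and therefore identical to micro recall
(single-label multiclass); precision is support-weighted one-vs-rest,
which is why it can exceed recall; "correlation" is Pearson's r on the
paired numeric codes (the codes are ordinal, and a swap of 1↔3 yields
−1 as expected), with multiclass Matthews correlation available as
`matthews_corr` for a chance-corrected alternative. Proportion tables
report count/total to 3 decimals; a stated total that disagrees with the
summed counts is surfaced as a warning and used as-is, never silently
corrected. The binomial proportion test is exact (two-sided tail
summation) up to 10⁶ trials, then a normal approximation with continuity
correction; the two paths agree within 10 % relative p near the switch.
The frame-rate comparison anchors the null at the high-rate run's
proportions and pairs per-minute mean state codes in a classical paired
t-test, with zero-variance differences flagged as degenerate rather than
producing an undefined statistic.

## Problem sizes

The end-to-end study scene used by the tests and the acceptance script is
300 s at 25 fps (7500 frames, 240×266 px), chosen to hold dozens of state
transitions and several walking bouts while keeping a full run in minutes
on one CPU; the flow oracle suite uses 50 pairs of 64×64 textures; the
diurnal aggregation checks use five simulated days of 1 Hz states
(216 000 records). Scaling any of these up changes sampling noise, not the
identities being checked.

## Known limitations

* The behaviour chain has no inactive-but-standing substates (feeding,
  rooting); the ethogram is deliberately three states.
* One pig per pen is assumed throughout (`select_pig` keeps the single
  best pig detection); multi-animal assignment is out of scope.
* The mean-of-ordinal-codes activity level weights walking twice as far
  from lying as standing; alternative weightings would need their own
  normalization.
* Flow assumes brightness constancy; the generator honours it exactly,
  real footage only approximately.
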
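# pentrack

Video-based posture and activity tracking for singly housed experimental
pigs.

Animal-welfare monitoring in experimental facilities still relies on
periodic in-person scoring: subjective, labour-intensive, and blind outside
working hours. For pigs recovering from procedures in single-pig pens, a
fixed overhead camera plus lightweight image analysis can instead produce a
continuous, objective activity record. `pentrack` implements that analysis
as a tested Python library for researchers and facility engineers: it
classifies each frame into one of three coded activity states — **1 lying,
2 standing, 3 walking** — and turns the stream of codes into hourly,
baseline-relative activity budgets with the accompanying validation
statistics.

## Method

The classifier is a two-stage cascade:

1. **Posture.** A detector (any implementation of the `Detector` interface;
   a background-subtraction reference detector for synthetic scenes is
   included) labels the pig *lying* or *standing* and flags human keepers.
   Lying maps directly to state 1 — no motion analysis is run for a lying
   pig.
2. **Movement.** For a standing pig, sparse optical flow restricted to the
   pig's bounding box decides standing (2) vs walking (3). Shi–Tomasi
   corners — maxima of the smaller eigenvalue λ_min of the windowed
   structure tensor *G* = Σ_W [Ix² IxIy; IxIy Iy²] — are re-detected in
   the box each frame and tracked with iterative pyramidal Lucas–Kanade:
   per pyramid level, *d* ← *d* + *G*⁻¹ *b* with
   *b* = Σ_W ∇I·(I_prev − I_next(x+d)), doubling the estimate on each
   descent. Per-frame mean feature displacements are summed over
   one-second windows into an accumulated distance per second, and a
   px/s threshold (default 5 px/s) separates walking from standing —
   frame-rate-independent by construction, so the same threshold serves
   25 fps and 1 fps operation.

Around the cascade: light-gated frame I/O (the pens are dark 12 h/day),
frame-rate downsampling, keeper-presence filtering, hourly mean states
normalized by each pig's own all-time mean (removing inter-individual
baseline differences), and validation statistics (3×3 confusion matrices,
pooled accuracy / support-weighted precision / Pearson correlation on the
paired codes, exact binomial proportion tests, paired t-tests).

Because no footage ships with the package, a first-class synthetic scene
generator renders overhead pen video with per-frame ground truth (state,
bounding box, keeper presence, lighting), driven by a Markov behaviour
chain with an hourly walking-propensity profile. Every stage is tested
end-to-end against that ground truth.

## Worked example

`examples/03_track_activity.py` simulates 60 s of pen footage at 25 fps,
runs the full cascade, and scores it against the generator's truth:

```
frames tracked: 1500
predicted activity budget: {1: '0.117', 2: '0.633', 3: '0.250'}
per-frame state accuracy vs truth: 1.0000
confusion matrix (rows=truth 1..3, cols=predicted):
[[175   0   0]
 [  0 950   0]
 [  0   0 375]]
```

The budget line says this pig spent 11.7 % of the minute lying, 63.3 %
standing and 25.0 % walking; on this short clean scene every frame matches
the ground truth. `examples/02_optical_flow.py` shows the tracker
recovering a known (3, −2) px shift to sub-millipixel agreement with an
exhaustive block-matching search, and `examples/04_hourly_budget.py`
recovers configured morning (7–9 h) and afternoon (13–15 h) activity peaks
from five simulated days:

```
hour  mean_state  relative
   7       2.201     1.363  ###########################
   8       2.220     1.375  ###########################
  ...
two most active hours: [8, 7]
```

The same workflow is available from the shell:

```sh
pentrack simulate --config scene.yaml --out scene/ --seed 17
pentrack track --in scene/ --out activity.csv
pentrack validate --truth scene/ --pred activity.csv --out metrics.json
pentrack aggregate --activity activity.csv --pig-id P1 --out hourly.csv
pentrack compare-fps --a activity.csv --b activity_1fps.csv --out cmp.json
```

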
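# Methods

## The screening problem

Strabismus is a misalignment of the visual axes.  Under the alternate
cover test (ACT) the occluded eye, freed from fusion, drifts toward its
anatomical resting position — outward in exotropia, inward in esotropia,
upward in hypertropia — and refixates when uncovered.  A remote infrared
eye tracker imaging both pupils through an IR-transparent occluder turns
this into a measurable signal: the interocular horizontal difference
`d(t) = RPCX(t) − LPCX(t)` in the tracker's normalized screen units,
sampled at 60 Hz for roughly 10 s per ACT cycle ("sample").  The package
classifies samples as normal vs strabismic and aggregates to a
per-participant verdict.

## Generative model of a recording

**Occlusion schedule.**  Alternating left/right cover intervals tile
`[0, duration]`; dwell lengths are uniform on (3, 6) s, the range a manual
examiner produces.  Draws are capped so every interval, including the
final one that absorbs the remainder, stays inside the dwell range
whenever the duration permits.  Which eye is covered first is a convention
(left).

**Deviation kinematics.**  Each eye carries a first-order lag envelope
toward amplitude `a` while covered (time constant τ_on, default 0.08 s —
dissociation is fast, saccade-like) and toward 0 while uncovered
(τ_off, default 0.4 s — fusional vergence re-alignment is slow).  Two
consequences matter:

- On plateaus the envelopes sum to `a` exactly, so `d(t)` sits at
  baseline + a (exotropia) or baseline − a (esotropia) through most of the
  recording.
- At each occluder swap the fast rise of the newly covered eye outruns the
  slow decay of the newly uncovered one, producing a transient *overshoot*
  of roughly 0.5·a above the plateau — the distinct peaks that make
  strabismic traces visually recognizable.  After median centering these
  peaks are what separates the classes; with a single shared time constant
  the two envelopes would sum to a constant and centering would erase the
  class signal entirely.  The two-constant model is therefore both the
  physiologically sensible and the mathematically necessary choice.

The eye covered at frame 0 starts fully deviated: the occluder is placed
before logging begins, so no artificial opposite-sign onset transient
contaminates the first frames.  Hypertropia applies the same kinematics to
the Y coordinates; it exists only to exercise the rare-class exclusion.

**Sensor model.**  I.i.d. Gaussian noise (sd 0.01 normalized units,
default) on every coordinate of every frame; each frame is independently
invalidated with probability 0.02, upon which both validity flags drop to
0 and the coordinates hold the last valid value, as trackers behave during
blinks.  A recording's tracking-confidence score is its fraction of
bilaterally valid frames.

**Cohort defaults.**  25 normal / 18 exotropic / 7 esotropic participants,
3–7 samples each; per-participant amplitude uniform on [0.05, 0.15]
normalized units (the 10–45 prism-diopter clinical range mapped onto the
tracker scale, and ≥ 3× the noise sd at the low end); per-participant
baseline separation N(0.385, 0.05) and left-pupil position N(0.62, 0.02).
The baseline jitter is deliberate: it is the between-subject confound that
centering removes, and the reason raw features underperform preprocessed
ones.

**What the simulator does not model** — and hence what passing tests do
not establish about clinical data: pupil-diameter changes, torsion,
vergence micro-movements, head motion, calibration drift, pediatric
non-compliance (fixation loss unrelated to occlusion), asymmetric or
incomitant deviations, and intermittent strabismus whose angle varies
between cycles.  Synthetic separability is by construction cleaner than
clinical separability; benchmark accuracies here validate the machinery,
not the clinical effect size.

## Preprocessing pipeline

Stages run in a fixed, tag-enforced order:

1. **Difference signal**: `d(t) = RPCX − LPCX`, validity mask
   `LPV ∧ RPV`; Y-coordinates are discarded (horizontal deviations
   dominate the exo/eso screening task).
2. **Invalid-frame repair**: linear interpolation between nearest valid
   neighbours (edge frames take the nearest valid value); a drop policy is
   available.  An all-invalid sample is unrecoverable and discarded.
3. **Centering**: subtract the series *median*.  The median, not the mean,
   so that long deviation episodes do not drag the baseline estimate.
4. **Outlier removal, threshold 0.025**: by default a frame-jump
   (velocity) rule — drop any point whose difference from the previous
   point exceeds the threshold — deleting tracking artifacts while
   preserving physiological drifts, which build up over several frames
   (at τ_on = 0.08 s and a = 0.15, the largest per-frame physiological
   step is ≈ 0.023).  A deviation-from-mean variant is available by
   config, but note that taken literally it deletes the diagnostic
   excursions themselves on any strongly deviated recording.
5. **Temporal compression 10:1**: non-overlapping 10-frame means
   (60 Hz → 6 Hz).  A trailing partial window of ≥ 5 points is averaged
   into a final point; shorter tails are discarded.
6. **Featurization**: linear resampling to exactly 60 points
   (10 s × 60 Hz / 10), the fixed classifier input dimension.

The "raw" benchmark condition is stages 1–2 plus resampling only: no
centering, artifact removal or compression.

Open choices made here and pinned by tests: normalization is per-sample;
outlier removal runs after centering; the trailing-window rule is ≥ half a
window keeps.

## Dataset and split

Samples with tracking confidence < 0.25 are removed; subtypes with fewer
than 5 samples are excluded outright (hypertropia in the reference
composition: 339 → 335).  The train/test split assigns whole participants,
stratified by binary label, shuffled by seed and accumulated greedily
toward a 12% test sample fraction, with at least one participant per class
on each side.  A no-leakage invariant (no participant on both sides) is
asserted on every split.

## Classifiers and evaluation

Seven scikit-learn classifiers, each grid-searched by stratified 5-fold CV
accuracy on the training side and refit on all of it.  The random-forest
grid contains the reference optimum (200 trees, depth 20,
min_samples_split 5, Gini); the other six grids are small, documented
inventions sized for minutes of CPU.  SVM, k-NN, MLP and logistic
regression are standardized in-pipeline.  The single-sample acquisition
condition thins the training side to one seeded sample per participant;
the test side is identical across all cells and never touches tuning
(property-tested by corrupting test features and asserting unchanged CV
selection).

Metrics are the five diagnostic proportions with binomial 95% CIs.  Wald
is the default (symmetric about the estimate, matching how such intervals
are usually printed); Clopper–Pearson is available and preferred at
boundary proportions where Wald collapses to zero width.  Patient-level
verdicts take the modal predicted label per participant, ties broken
toward strabismus — in screening, a false alarm costs a confirmatory
examination while a miss costs a diagnosis.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng`; cohort
  generation, splitting, fold shuffling and estimator seeds derive from
  explicit integer seeds, and end-to-end runs derive per-stage sub-seeds
  from one master seed via `SeedSequence` spawn keys (all < 2³¹).
- Gaze logs are written with 5-decimal coordinates; round-tripping is
  exact at that precision.
- Schedule interval membership is end-exclusive; envelope recursions use
  the exact discrete decay factor `exp(−Δt/τ)` with τ = 0 treated as an
  instantaneous step.
- Undefined metrics (zero denominator) are NaN and flagged, never 0.

## Problem sizes

The test suite and the acceptance script use the 50-participant default
cohort (≈ 260 samples of 600 frames) for benchmark-level checks, a
17-participant cohort for harness unit tests, 10 seeded cohort replicates
for the preprocessed-vs-raw comparison, 200 zero-noise draws for the
sign-separation property, and 1000 random series for the brute-force
oracle equivalences.  These sizes were chosen so a full run completes in a
few minutes on a single CPU while keeping binomial tolerances meaningful.

## Known limitations

- The deviation amplitude's mapping from prism diopters to normalized
  tracker units is a modeling convention; absolute calibration is
  unknowable without screen/viewing geometry.
- The simulator emits symmetric, constant-angle deviations; classifiers
  trained on it will not transfer to clinical recordings.
- Patient-level and sample-level accuracy coincide often at high
  separability; they are reported side by side and never conflated.
- With small test cohorts (6–7 participants) patient-level proportions
  are coarse; their CIs are correspondingly wide.
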
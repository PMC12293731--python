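# Methods

## Problem and data model

`aaaquant` quantifies abdominal aortic aneurysms (AAA) from the 1D *area
signal* of a CTA scan: the per-axial-slice count of segmented aortic-lumen
pixels, ordered from the thoracic aorta (slice 0) down to the iliac
bifurcation. Such signals come from a prompted mask-propagation tracker
that follows the vessel through pathological segments; a complementary
failure signature comes from a segmentation model trained only on normal
anatomy, which stops producing masks over the aneurysm so the counts
collapse to zero there. The package assumes inputs at the mask/signal
level; it does not run any image segmentation itself, and DICOM handling
is out of scope.

All slice indexing is 0-based, aneurysm intervals are inclusive
`[start, end]`, and masks are binarized by "any nonzero pixel counts".
Grayscale inputs are normalized to 8-bit by linear contrast stretching of
the observed intensity range onto [10, 245] (round-half-up; a constant
image maps to the low anchor — the observed min/max convention is a
package decision, as fixed input anchors would make the map depend on
acquisition scaling).

## Screening (segmentation-failure classifier)

`screen_signal` keeps a rolling mean of the counts over the last
`window = 4` *non-anomalous* slices as the normal baseline. A slice is
flagged when its count drops below `low_frac = 50%` or exceeds
`high_frac = 140%` of that baseline; an anomaly is declared when flags
persist over `persistence = 4` consecutive slices. The first flagged slice
is the anomaly start; the anomaly ends at the last flagged slice before
`persistence` consecutive in-range slices (or the end of the signal). When
several runs occur the longest (earliest on ties) is reported.

Excluding flagged slices from the rolling mean is a deliberate choice: a
dropout region averaged into its own baseline would drag the baseline to
zero and un-flag itself. Equivalently, the baseline freezes at its
pre-anomaly value until recovery is confirmed. Against a zero baseline
(e.g. scanning past an unrecovered dropout), any positive count is treated
as deviating. The first `window` slices seed the baseline and are never
flagged.

## Expert rule-based boundary detector

`detect_expert` finds, on a continuous (tracker-style) signal, a sustained
*rise* marking the aneurysm onset and a sustained *drop* marking its end.
A candidate start `i` requires all of slices `i .. i+window-1` to exceed
`start_frac = 120%` of the mean of the `window = 4` slices preceding `i`;
a candidate end `j` requires all of `j .. j+window-1` to fall below
`end_frac = 80%` of the mean of the `window` slices preceding `j`. The
baseline mean is *anchored* at the candidate slice: all `window` slices
are compared against that one mean. A per-slice rolling mean is unusable
here — it absorbs the rise within two or three slices, so no slice run
could stay consistently above it.

Among valid pairs with `j > i` the detector keeps the pair maximizing the
span `j - i` (the largest abnormality window; earliest start on ties) and
returns `[i, j-1]`, i.e. the interval up to the slice before the sustained
drop. With valid start set S and end set E this maximum is attained at
`(min S, max{j in E : j > min S})`, which the implementation uses; a
property test checks equivalence with exhaustive pair enumeration. Note
that end candidates shortly *after* the true end can also validate
(their anchored baselines mix bulge and post-bulge slices), so the
detected end can sit a few slices caudal of the last enlarged slice; on
plateau-shaped bulges the error stays within ramp + window slices.

`grid_search_expert` tunes `(window, start_frac, end_frac)` exhaustively
against annotated signals, scoring each rule by mean interval Dice
(absent detections score 0). Defaults: window ∈ {3,4,5,6}, start_frac ∈
{1.10 .. 1.40}, end_frac ∈ {0.60 .. 0.90}; ties prefer the smaller window,
then thresholds nearest the canonical 1.20/0.80 operating point.

## Bidirectional-LSTM labeler

The trainable detector classifies each position of a fixed-length
representation of the scan as aneurysmal or normal:

* input: the area signal linearly resampled to `out_len = 200` positions
  spanning slice 0 .. n-1, scaled by the per-sequence maximum (an all-zero
  signal is passed through unscaled). Per-sequence max scaling keeps the
  labeler scale-invariant, consistent with the relative thresholds of the
  rule-based detectors; the resampling map is affine,
  `slice = pos * (n-1) / (out_len-1)`, and is inverted via the run's
  half-open edges when decoding predictions.
* architecture: 2 stacked bidirectional LSTM layers (default 600 hidden
  units per direction; forward/backward states concatenated between
  layers), then a fully connected ReLU head shared across positions
  (2H -> 256 -> 64 -> 1 by default) and a sigmoid. The shared
  per-position head aligns outputs one-to-one with the 200 positions; a
  flatten-to-200 head was the alternative and was rejected because it
  breaks the position/output correspondence and inflates parameters.
* loss: binary cross-entropy plus a soft-Jaccard term,
  `loss = BCE + w * (1 - (sum(p t)+s)/(sum(p + t - p t)+s))` with
  `w = 1` and smoothing `s = 1`. The smoothing constant is the standard
  overlap-loss regularizer: negligible against real batch sums, and it
  makes an empty-target batch with a confident all-negative prediction
  score Jaccard ~1 (zero loss) instead of being undefined.
* optimization: Adam (lr 0.0003, batch 10), patient-level
  train/validation split (`val_fraction = 0.2`), early stopping on
  validation loss (`patience` epochs) with best-validation weights
  restored. The network, backpropagation through time and Adam are
  implemented directly in NumPy (float32); all randomness — init, split,
  shuffling — derives from the config seed via named substreams, so
  training is bit-reproducible on a given BLAS.
* prediction: probabilities thresholded at 0.5 (threshold configurable);
  the longest contiguous positive run (earliest on ties) is decoded to an
  original-slice interval; no run above threshold means no detection.

`crossvalidate` performs k-fold (default 5) cross-validation with strict
patient-level separation: a seeded permutation is split into k folds, each
fold's model trains on the other k-1 (with its own internal validation
split) and is scored on the held-out patients; per-fold and pooled tables
report R²/MAE/MSE of start and end slices, mean interval Dice, and
truth-vs-predicted surrogate-volume R².

Gradient correctness is verified in the test suite by finite-difference
checks of the full network (LSTM gates, both directions, both layers, and
the head) and of the loss.

## Volumetrics

For an interval `[s, e]`, the surrogate volume is `Vol = sum_{i=s..e} P_i`
(unit-less pixel·slices; proportional to lumen volume, with no mm³
calibration — slice thickness and pixel spacing metadata are out of
scope). The *interpolated baseline* joins the measured counts at `s` and
`e` with a straight line — the hypothetical normal aorta — whose volume is
exactly `(P_s + P_e)/2 * (e - s + 1)`. Enlargement is reported as
`100 * (observed - baseline) / observed`; with typical bulge-to-baseline
ratios this lands in the tens of percent, whereas a baseline denominator
would roughly double it. The denominator choice is a package convention,
recorded here because the percentage-difference convention is genuinely
open. Baseline endpoints use the measured (noisy) counts, not smoothed
values. Cohort statistics (mean/median/SD of enlargement) use the n-1
standard deviation; a single-report cohort reports SD 0 with an explicit
`sd_undefined` flag.

## Evaluation metrics

Interval Dice = `2TP / (2TP + FP + FN)` on the slice index sets of
predicted vs annotated intervals (boundary overlap along the axial axis);
a 2D `mask_dice` exists for mask-vs-mask checks but does not enter the
boundary reports. R² = 1 - RSS/TSS (undefined for constant truth), MAE,
MSE, and clipped BCE (eps 1e-7) follow their standard definitions.
Classification metrics from a 2x2 table report `None` for
zero-denominator cases rather than a silent 0. `boundary_report` emits the
standard comparison layout — R² start/end, MAE start/end, MSE start/end,
mean Dice, volume R² — plus an `n_absent` column: absent predictions score
Dice 0 but are excluded from the boundary/volume regressions.

## Synthetic cohort generator

No public dataset carries this pipeline's inputs, so the generator *is*
the study population for all quantitative protocols. A patient is:

* scan length n ~ U{120..200} slices; thoracic-end area `base` ~
  U(300, 600) pixels; linear taper of `taper_fraction = 0.15` of the base
  from slice 0 to n-1 (a gentle caudal narrowing, far too slow to trip
  any 4-slice relative threshold);
* with probability `aneurysm_prob` a fusiform bulge: support length ~
  U{20..60} slices placed uniformly with a 10-slice bulge-free margin at
  both ends, peak area ratio ~ U(1.5, 3.5) over the local baseline.
  Envelope shapes: `plateau` (5-slice raised-cosine ramps into a flat
  top — the default, giving a well-defined interior for closed-form
  checks), `gaussian`, and `asymmetric` (3-slice rise, 8-slice fall). The
  envelope's virtual anchors of 1 sit one slice outside the support, so
  every in-support slice of a noise-free patient strictly exceeds the
  tapered baseline and every out-of-support slice equals it.
* multiplicative log-normal noise with unit mean and coefficient of
  variation `noise_cv = 0.03` (a few percent of slice-to-slice area
  jitter); counts rounded to nonnegative integers;
* `dropout_mode` then zeroes the counts over the bulge support, emulating
  the normal-anatomy segmentation model's failure signature;
* optionally a post-bifurcation count drop (off by default, since the
  tracked signal ends at the bifurcation).

Per-patient streams are derived counter-style from `(cohort seed, patient
index)`, so patient i is identical regardless of cohort size.
`rasterize_patient` renders each slice as a centered filled disc holding
*exactly* the slice's count (pixels ranked by distance from center, ties
lexicographic), making mask-stack extraction an exact round trip.

What the generator does **not** emulate: anatomical curvature and
tortuosity (signals are monotone-taper + bulge), thrombus and wall (lumen
only), branch vessels, tracker drift or partial dropout, inter-slice
correlated noise, and annotation ambiguity at bulge shoulders. Passing
the synthetic protocols therefore demonstrates algorithmic correctness
and internal consistency, not clinical-grade performance on patient CTA.

## Study protocols and problem sizes

The quantitative protocols (test suite and `scripts/acceptance.py`) use:

* expert-detector recovery: 50 noise-free plateau patients, peak ratio
  U(2.0, 3.5) — the regime where bulges rise past the 120% threshold
  within the ramp; expect mean interval Dice >= 0.90, boundary MAE within
  ramp + window (9 slices), truth-vs-detected volume R² >= 0.90.
* screening: 20 dropout-mode + 20 normal patients at 3% noise; expect
  accuracy >= 0.95.
* LSTM cross-validation: 200 easy-regime patients (3% noise, peak >= 2),
  5-fold, with a reduced training profile — 64 hidden units, head (32,),
  40-epoch cap, patience 10 — sized for a single CPU; the pooled Dice bar
  is 0.6. The full-size configuration (600 units, 1000 epochs) is the
  package default for real use.
* enlargement statistics: 60 default-spec patients, truth intervals.

## Numerical notes and limitations

* Float32 training numerics; metrics and losses accumulate in float64.
* `r2` raises on constant truth rather than returning 0; `bce` clips
  predictions at 1e-7; enlargement is undefined (error) at zero observed
  volume, and a zero-count baseline endpoint yields 100% by construction.
* Tie-breaks are fixed and documented: longest/earliest anomaly run,
  earliest detector start, earliest longest probability run, smallest
  window in grid-search ties.
* Single-aneurysm assumption throughout: the detectors report one
  interval; multi-aneurysm scans are out of scope.
* The expert detector's end boundary inherits a small caudal bias from
  baseline contamination (see above); this is a property of the anchored
  sliding-window rule, not of the implementation.
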
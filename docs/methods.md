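# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of the `lthrm` pipeline. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute themselves.

## Conventions

All indices are 0-based, intervals half-open `[a, b)` except where a
tolerance window is stated with inclusive endpoints. Annotated swallow
starts refer to the raw 50 Hz timeline; after left-aligned smoothing
(value at j summarizes samples j..j+w−1) they map onto the preprocessed
timeline unchanged, since the alignment shift (< 30 samples) is an order
of magnitude below the evaluation tolerance d.

## Preprocessing

Per sensor row: left-aligned moving average (w = 30 samples = 0.6 s),
clip to [−200, 300] mmHg, affine rescale onto [0, 255] kept in floating
point (no 8-bit quantization — quantization would discard up to 1 mmHg of
resolution for no benefit). Both the clipped mmHg matrix and the 0–255
matrix are retained: the threshold detector's 80 mmHg binarization is only
physiologically meaningful on the mmHg scale (80 on the 0–255 scale would
correspond to ≈ −43 mmHg and binarize almost everything), while the
classifier consumes the normalized scale. Resizing (windows → classifier
input; change images → 50 × 50) is separable, corner-aligned bilinear
interpolation: it preserves constant images exactly and never leaves the
input range beyond floating-point epsilon.

## Threshold detector

Chain: strict binarization (> 80 mmHg) → vertical moving sum over 20
consecutive sensors, zero-padded below row 36 → column sum over all
sensors → moving average w = 100 → peak finding. Free parameters not fixed
by the method description:

| parameter | default | rationale |
|---|---|---|
| peak threshold | 60 | ≈ 3 fully active sensors sustained across the smoothing window; `ThresholdDetector.fit` can calibrate it on annotated data by F1 sweep |
| min peak distance | 250 samples (5 s) | physiological refractory gap between swallows |
| threshold domain | mmHg | see above; the 0–255 domain remains available via config |

Peak finding uses `scipy.signal.find_peaks` with the height nudged by one
ulp to enforce the strict inequality; on conflicts within the minimum
distance the higher peak survives. Reported confidence is peak height
normalized by the maximum attainable activity 36 × 20. The detector fires
mid-contraction, not at the onset, so it is evaluated in event mode.

## Classifier detector

**Training set.** One positive window `[start, start + 500)` per annotated
swallow; windows overrunning the recording end are skipped with a warning.
Negative windows are tiled non-overlapping inside inter-swallow gaps
shrunk by a 250-sample guard margin on both sides, so contraction tails
cannot leak into negatives; the segment after the last annotation is used
(guarded on its left), the segment before the first annotation is not,
because a recording may begin mid-swallow. Classes are balanced by seeded
subsampling of the majority class.

**Backbone.** The `tiny` backbone is a committee of five identical MLPs
(one hidden layer of 64 units) over 36 × 50 bilinearly downsampled windows,
each trained from scratch with SGD (learning rate 3 × 10⁻³, batch size
128, 20 epochs, Nesterov momentum 0.9), differing only in initialization
and shuffling; predicted probabilities are averaged. Inputs are scaled to
[0, 1] and standardized per pixel with a variance floor at the mean pixel
standard deviation. Both choices were made for the shape of the confidence
response as a window slides across a swallow: plain z-scoring lets
near-constant background pixels (divided by their tiny noise sd) dominate
and makes the response oscillate, which fragments one swallow into several
detection runs; a single unstandardized MLP under-fits the weaker
archetypes within the 20-epoch budget. The committee's averaged response
is unimodal and peaks at window/onset alignment. All 36 sensor rows are
kept at full resolution because the upper-sphincter relaxation — the one
cue shared by every swallow archetype — lives in only three rows.

**Inference.** A window slides with configurable stride (default 1; the
synthetic benchmarks use 5, trading a 5× speedup against localization
error well below the tolerance window). Per window the predicted class
o and its probability c are recorded; for stride > 1 both traces are
linearly interpolated back to per-sample resolution before forming
s = o ⊙ c. The trace is smoothed (moving average w = 20), thresholded at
0.2, and each maximal run of ones becomes one detection whose start is the
first argmax of raw s within the run's sample span (first index on ties;
run boundaries live on the smoothed trace's left-aligned timeline, indices
are reported on the preprocessed timeline). No minimum run length is
imposed. Requesting one of the large pretrained CNN backbones raises an
error naming the supported set.

## Two-stage clustering

Features per swallow window: valid-mode convolution with the change kernel
[−1, 0, …, 0, 1] (length 10; output width 491), element-wise square —
squaring *before* resizing, preserving the sharpness of the change
response — then 50 × 50 resize, Gaussian smoothing with σ = 1 px, flatten
(2500), PCA to 30 components fitted on the recording's own swallows
(a shared-fit mode would be needed for cross-patient pattern atlases and
is out of scope). Fewer than 31 swallows reduce the component count with a
warning; fewer than 2 are an error.

Clustering is agglomerative with Ward linkage on Euclidean distances;
the cluster "center" is the centroid of member features. The stage-1
cluster count is swept over k ∈ [4, 10]; two selection rules ship:

* `intra` (default, the method's literal rule): lowest mean distance of
  samples to their own-cluster centroid, smallest k on ties (equality
  within 1e−12 relative). The score is non-increasing in k, so on data
  with any within-cluster spread the rule saturates at the top of the
  range — a documented bias, kept because it is the stated selection rule.
* `knee`: largest relative score drop from k−1 to k. This recovers the
  true group count whenever it lies strictly inside the sweep range, and
  is what the archetype-recovery experiments use.

Stage-1 clusters holding ≥ 15 % of all swallows are the main categories;
members of all other clusters are pooled and re-clustered with
k = min(10, pool size) (a fixed stage-2 count rather than a second sweep).
With fewer samples than the smallest candidate k the sweep is skipped and
k is clamped to the sample count. Representatives per final cluster are
the n = 5 closest and most distant members by Euclidean distance to the
centroid, ties broken by sample index; n is capped at the cluster size.

## Evaluation protocol

A prediction matches an annotation when it falls in `[y − d/2, y + d/2]`
(start mode) or `[y + 200 − d/2, y + 200 + d/2]` (event mode, for the
threshold detector), endpoints inclusive, d defaulting to 400 samples with
100 and 800 as standard alternatives. Matching is greedy one-to-one by
increasing distance to the window center with deterministic tie-breaking
(prediction index, then annotation index); one-to-one matching prevents a
single prediction from absorbing several annotations, and greedy equals
the optimal assignment whenever tolerance windows are disjoint (tested
against a Hungarian-algorithm oracle). Precision is defined as 0 with no
predictions so aggregation never fails. No systematic offset correction is
applied to detections before matching. Cross-validation partitions
patients (never recordings of one patient across folds) with a seeded
shuffle; per-fold metrics pool TP/FP/FN over the fold's recordings, and
folds aggregate as mean ± sd.

## Synthetic generator

The generator emulates exactly the structure the pipeline exploits:
region baselines (UES rows 0–2 at 70 mmHg, body rows 3–32 at 5 mmHg, LES
rows 33–35 at 25 mmHg), per swallow a UES relaxation dip at the annotated
start (depth 65 mmHg, σ = 10 samples), an LES relaxation spanning the
swallow, and a Gaussian-in-time body contraction per sensor row with a
row-linear delay. Archetypes: normal (150 mmHg, 12.5 samples/row
propagation ≈ 2.4 cm/s), failed (40 mmHg — below the 80 mmHg contraction
threshold by construction), simultaneous (all rows fire together),
hypercontractile (300 mmHg ≥ 2× normal, broader), plus unannotated
cough-like artifacts (brief 120 mmHg spike across all 36 rows). Defaults:
1 swallow/min (1440/24 h, inside the typical 900–1500 daily range),
0.2 artifacts/min, i.i.d. Gaussian sensor noise with sd 2 mmHg, minimum
start-to-start gap 2000 samples (40 s) so every inter-swallow gap can hold
a guarded negative window. Event counts are deterministic per recording
(rate × duration, rounded); start times are uniform conditioned on the
minimum gap; everything is reproducible from one seed via spawned
per-patient substreams.

What the generator does **not** model: baseline drift, breathing and
posture artifacts, mealtime pressure patterns, sensor dropout, circadian
variation, impedance channels, or the continuum between archetypes.
Passing benchmarks on this generator therefore demonstrate that the
implementation is faithful and the pipeline recovers the structure it
assumes — not clinical-grade performance; the published clinical figures
were obtained on 25 annotated patient recordings that are not publicly
available, and are not reproducible here.

## Problem sizes

The standard benchmark sizes were chosen as the smallest cohorts at which
the protocol is still meaningful: detection uses 20 patients × 10 minutes
(200 swallows) with fivefold patient-grouped CV and inference stride 5;
clustering uses 4 patients × 10 minutes with an equal archetype mixture
plus artifacts (≈ 50 events, five ground-truth classes — a knee in the
k sweep is only observable when the true class count exceeds the sweep's
lower bound of 4); the noiseless threshold-detector check uses 3 patients
× 5 minutes of pure normal peristalsis.

## Known limitations

* The literal `intra` k-selection rule saturates at the top of the sweep
  range on any data with within-cluster spread; use `knee` when the goal
  is recovering a true group count.
* The threshold detector misses failed peristalsis by design (no
  supra-threshold contraction exists) and fires on cough-like artifacts.
* The classifier committee's confidence is a probability average, not a
  calibrated posterior; the 0.2 run threshold is taken as given rather
  than tuned per cohort.
* Stride > 1 linearly interpolates the class trace, so run edges are
  resolved only to within one stride.
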
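# Methods

## Problem setting

A polyp detector emits axis-aligned bounding boxes with confidence scores
over colonoscopy frames. Detectors developed only on polyp-containing
imagery meet out-of-distribution content in deployment — frames with
instruments, water jets, feces, blood, blur, or the camera close to the
mucosa — and fire spurious boxes on it. `negdetect` implements the
apparatus needed to study this quantitatively: negative-image ("not-polyp")
injection into dataset partitions, a box-wise evaluation protocol, and a
simulator that stands in for a trained network so the full pipeline is
reproducible at desk scale.

## Evaluation protocol

TP/FP/FN are defined per predicted and per truth box: a predicted box over
a truth box is a TP, over no truth box an FP, and a truth box with no
predicted box over it an FN. Two points in this definition are genuinely
open and are therefore configurable, with the choice surfaced in every
report header (`criterion` column / provenance entry):

* **The "over" predicate.** Default is any positive-area intersection
  (`any_overlap`); an IoU-thresholded predicate (`iou:<min>`) is available
  for comparability with COCO-style protocols. Boxes are 0-based and
  half-open internally, so "positive area" is exact integer arithmetic.
* **Counting multiplicity.** Default is `literal_per_box`: the three
  definitions are applied independently to every box, so two predictions
  over one truth count as two TPs. `one_to_one_greedy` instead lets each
  prediction, in descending confidence order, consume at most one unmatched
  truth (ties between candidate truths break toward the highest IoU, then
  the lowest truth index).

Metrics are micro-averaged: counts are pooled over the evaluation set
before recall, precision and F1 are formed. A metric whose denominator is
zero is `None` (an explicit undefined flag), never a silent zero.
Threshold comparison is `>=`: a detection at exactly the threshold
survives.

The PR curve places one point per distinct confidence value, in decreasing
order, and AP is the step estimator `Σ precision_i · (recall_i −
recall_{i−1})` with `recall_0 = 0`. The implementation exploits that under
both counting modes a detection's TP/FP status is decided by the full
unthresholded matching (raising the threshold only truncates the
confidence-sorted list), so the sweep is a single cumulative pass; a test
verifies every curve point against an independent from-scratch evaluation.
The operating threshold is the curve point with maximal F1, ties broken
toward the smaller threshold (the more sensitive operating point).

## Injection

`plan_injection` shuffles the negative pool once with a seeded generator
and consumes it partition by partition, level by level. This makes the two
structural guarantees hold by construction: a negative image belongs to
exactly one partition type, and the negatives at a lower level are a subset
of those at any higher level. Counts follow round-half-away-from-zero on
`p/100 · base_size`; the rounding rule is a declared convention (any
consistent rule would do) and is exercised against the reference partition
sizes 13,873/6,045/8,658 (49/21/30% of a 28,576-image cohort), where 2%
injection adds 277/121/173 images.

## Ground-truth I/O

VOC XML uses 1-based inclusive coordinates; conversion to the internal
0-based half-open convention (`x_min = xmin_voc − 1`, `x_max = xmax_voc`)
is lossless and round-trips exactly. Mask conversion binarizes at pixel
value ≥ 128 (source masks are near-binary; configurable), labels connected
components at 8-connectivity (diagonal-touching mask fragments belong to
one polyp; 4-connectivity available), drops components under 16 px as
speckle (configurable, 0 disables), and emits one tight-extent box per
component sorted by `(y_min, x_min)`. One box per component — rather than
one global box per mask — is the assumed convention for multi-component
masks, and is configurable by post-processing the returned list.

## Simulator

`generate_dataset` produces 640×480 frames; most polyp images carry one
box, with 8% carrying two and 2% three (public collections do contain
multiple-polyp frames); box sides are uniform in 24–96 px; polyp images
split 49/21/30 into training/validation/test; negatives form an unassigned
pool. Boxes are sampled with a 1-px separation margin so rendered masks
keep one component per box. Rendered masks are filled inscribed ellipses
with the four side-midpoint pixels set explicitly, which makes the tight
pixel extent of each component equal the generating box exactly — a strict
round-trip oracle for the mask converter.

`simulate_detections` detects each truth box independently with probability
`p_detect` (edges jittered by up to `jitter_frac` of the box dimensions;
confidence from the TP law) and adds per-image spurious boxes with Poisson
counts at class-specific rates `fp_rate_polyp` / `fp_rate_negative`
(uniformly placed, by default rejecting overlap with truth boxes; a
fixed-count mode exists for exact small fixtures). Per-image randomness is
keyed by `(seed, crc32(image_id))`, so a fixed model emits identical
detections for an image regardless of which evaluation set contains it —
this reproduces exactly the central bookkeeping fact that augmenting a test
partition with negatives cannot move recall.

In the zero-jitter, non-overlapping-FP regime the evaluated micro metrics
have the closed form `recall = p_detect`, `precision = p·b·n_p /
(p·b·n_p + r_p·n_p + r_n·n_n)`. `profile_from_metrics` inverts this form:
given a detector's recall, its precision on a polyp-only test set, and its
precision at a known injection level, it recovers `r_p` and `r_n`. The five
default experiment profiles are calibrated this way from the operating
points of the detector family the package emulates (baseline: recall 0.872,
clean precision 0.890, precision 0.836 at 15% injection; the 15%-injected
variant: 0.880/0.910/0.901; intermediate variants in between), with
decreasing `fp_rate_negative` across variants modelling the effect of
training with progressively more negative imagery.

Confidence laws are Beta distributions: TP ~ Beta(6, 3) (mean 0.67), FP ~
Beta(3, 3) (mean 0.50). The means differ, so threshold selection has a
non-trivial optimum, while the overlap is substantial — as it is for real
detectors, whose selected thresholds are low (the default experiment
selects thresholds around 0.2–0.3) and whose surviving boxes still include
false positives. With well-separated laws the selected threshold would
eliminate nearly all simulated FPs and the dilution phenomenon would be
invisible at the operating point.

## The default experiment

`default_experiment_config(seed)` builds a 2000-polyp-image cohort with a
1200-image negative pool (the cohort it emulates is roughly tenfold larger;
the scaled sizes keep the full run in a few seconds while leaving
Monte-Carlo noise well below the effects of interest), nested injections at
2/5/10/15%, the five calibrated variants, a ten-dataset inter-dataset panel
(250 polyp images each; four datasets carry negatives at 16.14%, 1.25%,
5.08% and 15.7% — fractions typical of public collections — and six are
polyp-only), and two videos (450 polyp frames, 350 not-polyp frames).
`run_experiment` selects each variant's threshold on its own
validation partition (augmented at the variant's training level), evaluates
every augmented test partition, the panel, and the videos, and writes TSV
tables plus provenance. Every displayed metric recomputes from the bundled
raw counts; display rounding is half-away-from-zero at 3 decimals for
metrics and 2 for percentages (values are first snapped at 12 decimals so
binary accumulation noise cannot flip a half-way digit).

For the polyp video no per-frame truth boxes exist; the fraction of frames
with at least one emitted box is reported as a recall proxy (it assumes at
least one box per counted frame is on the polyp) and the output metadata
says so. On the not-polyp video every box is a false positive by
construction, so the total box count is the direct FP burden.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the problem — class
composition, nested partitions, per-image detection stability, asymmetric
FP rates, confidence-score overlap — but not image content: there is no
texture, lighting, instrument or motion model, detection events are
independent across boxes and frames (no temporal correlation within a
video), spurious boxes are uniformly placed, and jitter is uniform per
edge. Passing tests therefore validate the evaluation and injection
arithmetic and the statistical laws (dilution, recovery, parameter
recovery), not the performance of any real detector on real colonoscopies.

## Numerical and degenerate-input choices

* Metrics with zero denominators are `None` and propagate as flags;
  selection over an all-undefined curve raises.
* AP is undefined (an error) on a truth-free evaluation set.
* `relative_change` with a zero reference raises rather than returning a
  sentinel.
* Duplicate image ids, polyp images without annotations, confidences
  outside [0, 1] and degenerate boxes are rejected at parse time with the
  offending row named.
* All randomness flows through explicit integer seeds; reports rerun
  byte-identically for equal configs.

## Known limitations

* The closed-form calibration is exact pre-threshold; at the selected
  threshold, measured precision is higher than the calibrated value by the
  FP-survival factor of the confidence laws. Patterns (dilution along
  levels, recovery across variants) are unaffected.
* Inter-dataset heterogeneity in the default panel is purely Monte-Carlo;
  real cross-dataset variation (resolution, imaging modality, annotation
  style) is out of scope.
* Video analysis consumes per-frame prediction CSVs; no video decoding.
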
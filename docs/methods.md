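# Methods

## Problem setting

Peripheral-blood leukocytes come in five types — neutrophils (NG), basophils
(BG), eosinophils (EG), lymphocytes (L) and monocytes (M) — and detecting
them on stained smear images is a multi-object detection task: each image may
contain several cells, and a detector must localize each cell with a bounding
box, assign a type, and report a confidence. Individual deep detectors
disagree, especially on poor-quality images (over/under-staining, overlapping
cells, impurities, incomplete cells at the field edge). `leukofuse`
implements a detector-agnostic post-processing step that fuses the outputs of
M independent detectors into a single, more reliable detection set, plus the
evaluation machinery needed to quantify the effect.

## The fusion model

For one image, let each detector i contribute detections
D_i = (L_i, C_i, P_i) with corner box L_i = [x1, y1, x2, y2], confidence
C_i ∈ [0, 1] and type P_i. Fusion proceeds in four steps:

1. **Clustering.** Detections are visited in descending confidence (ties
   broken by model id, then coordinates, then class — purely content-based,
   so the result is invariant under permuting models or within-model lists).
   A detection joins the first existing cluster whose *running
   confidence-weighted mean box* has IoU ≥ τ with it and that does not yet
   contain a detection from the same model; otherwise it seeds a new cluster.
   τ defaults to 0.55, the customary weighted-boxes-fusion threshold; it is
   exposed as `FusionConfig.cluster_iou_threshold`. The one-member-per-model
   rule makes cluster size N count *models*, which steps 2–4 rely on.

2. **Support filtering.** A cluster of size N survives iff N ≥ f·M with
   f = `min_support_fraction` = 0.5: a region that fewer than half the
   detectors marked is treated as a false positive and discarded. The
   boundary is inclusive (exactly M/2 survives, matching a strict
   "fewer than M/2 is discarded" rule). Discarded clusters are returned in an
   audit report, never silently dropped.

3. **Majority vote.** The fused label is the most frequent member label; T is
   its count. Ties go to the label with the larger summed confidence, with
   residual ties broken by the canonical class index NG < BG < EG < L < M;
   tie-broken votes carry a flag.

4. **Averaging.** The fused box is the confidence-weighted mean of member
   corner vectors,

       L' = Σᵢ Cᵢ·Lᵢ / Σᵢ Cᵢ ,

   and the fused confidence is C' = Σᵢ Cᵢ / D. Two divisor semantics exist
   in the literature this scheme descends from, and they genuinely differ:

   * `models` (default): D = M. A detector that emits nothing for the region
     acts as an abstention and pulls C' down; C' ≤ 1 always holds when each
     model contributes at most one member.
   * `majority`: D = T. C' is averaged over the majority voters only and can
     exceed 1 when minority-label members contribute to the numerator. Such
     values are reported as-is — clipping would hide the semantics.

   Whether minority-label members enter the box average is likewise
   configurable (`box_average_scope`, default `all_members`).

### Numerical form of the averages

The weighted mean is evaluated in centered form,
`ref + Σ Cᵢ·(xᵢ − ref) / Σ Cᵢ` with `ref` the first member's coordinate
(and analogously for C'). This is algebraically identical to the displayed
equations but has an important floating-point property: when all members
coincide (e.g. M detectors that happen to agree exactly), the differences
vanish *before* any rounding and the fused output reproduces the input
bit-exactly. The naive summation fails this for roughly a third of random
inputs by 1 ulp. Fused coordinates stay within the min/max envelope of the
member coordinates up to that same 1-ulp rounding.

Degenerate inputs are rejected, not repaired: zero-area boxes fail at
construction (they poison IoU denominators and fusion weights), and a cluster
whose confidences are all zero raises rather than producing undefined
weights.

## Evaluation protocol

* **Matching** is the standard greedy protocol: per image, detections in
  descending confidence order each claim the unmatched ground truth of the
  same class (when class-aware) with the highest IoU at or above the working
  threshold; IoU ties go to the lower ground-truth index, confidence ties to
  input order. One-to-one by construction.
* **AP** is 101-point interpolated: TP/FP flags are pooled over images,
  sorted by confidence, and AP is the mean over the recall grid 0.00…1.00 of
  the maximum precision attained at recall ≥ r. The grid is computed as
  k/100 (not `linspace`) so grid points are the correctly rounded doubles of
  the decimal fractions — recall values that are exact small fractions then
  compare against the grid without spurious rounding slack.
* **mAP / mAR** average over the ten IoU thresholds 0.50, 0.55, …, 0.95 and
  then over classes. mAR caps each image at `max_detections` = 100
  highest-confidence detections per class. Classes with zero ground truths in
  the evaluated set have *undefined* AP — they are excluded from the means
  and serialized as an explicit `NA`, never counted as 0. This matters
  because basophils are rare (14 cells in a realistic test split).
* **Confusion matrix** (6×6: five classes + background) uses class-*agnostic*
  matching at IoU 0.5, so cross-class confusions populate off-diagonal cells;
  unmatched ground truths and detections fall into the background column/row.
  Row sums over true classes equal per-class ground-truth counts.
* **Interference-conditional accuracy** is defined as correct-class recall at
  IoU 0.5 over the ground truths carrying a given tag. No operational
  definition is standard for this quantity; this one is declared and fixed.

## Synthetic benchmark generator

The generator works entirely in annotation/detection space — no pixels —
because neither fusion nor evaluation reads image content. It emulates:

* **Scenes**: a 600×600 canvas (the "mini" working resolution for ×1000
  smear fields); cells per image = `base_cells` + Poisson(0.37), matching a
  corpus with ~1.37 cells/image and ~32% multi-cell images; class frequencies
  proportional to NG:BG:EG:L:M = 4135:300:1100:1879:1181; near-square cell
  boxes with side ~ N(100, 15²) px clipped to [40, 200], placed by rejection
  sampling so no pair exceeds IoU 0.30. Cells overlapping another cell above
  IoU 0.05 are tagged `overlapping`.
* **Interference tags**: a closed 10-name vocabulary (`color_cast`,
  `low_illumination`, `giant_platelets`, `wrong_focus`, `impurity`,
  `overlapping`, `degenerated`, `high_ph`, `low_ph`, `incomplete`).
  Image-level tags apply to all cells of the image; `incomplete` and
  `degenerated` are drawn per cell. Per-tag prevalences are free parameters
  (no published per-factor counts exist to anchor them) and default to
  3–6% per image-level factor — enough to represent every factor in a few
  hundred images.
* **Detectors**: each `DetectorProfile` has a miss probability, a Poisson
  false-positive rate per image, Gaussian corner jitter scaled by box size,
  a row-stochastic 5×5 label-confusion matrix, and a confidence model
  `C = clamp(base − slope·(1 − IoU(jittered, true)) + ε, floor, 1)` linking
  reported confidence to realized localization quality — the minimal
  assumption under which confidence *weighting* is meaningful. Tags act as
  noise multipliers (overlapping cells are missed more often, impurity-laden
  images attract more false positives, pH extremes inflate confusion).

Coordinates are snapped to a dyadic 1/1024-px grid. This is far below any
meaningful localization precision and makes corner ↔ x/y/width/height
conversion exact in IEEE arithmetic, so written COCO benchmarks round-trip
bit-identically (for arbitrary doubles a representable width reproducing x2
does not always exist — round-to-even can skip it).

Everything is a pure function of (configuration, seed): scene generation,
each detector, and the 4:1 train/test split draw from independent child
streams of one seed, so adding a detector never perturbs the ground truths.

### What the generator does *not* model

Detector errors here are independent across models given the scene; real
detectors share training data and failure modes (e.g. all confusing an
atypical lymphocyte with a monocyte), which correlates their errors and
shrinks the ensemble's benefit. There is no pixel-level appearance, no
systematic per-detector bias (over-tight or over-wide boxes), and confidences
are calibrated by construction, whereas real detector scores are not
comparable across architectures. Passing tests on this benchmark therefore
demonstrate the *mechanics and the direction* of the ensemble effect
(recall gain from abstention-tolerant clustering, FP suppression from the
support rule, √M-style localization variance reduction), not the magnitudes
achievable on clinical data.

## Default problem sizes

Statistical tests run at sizes where the asserted effects are decisive:
300 scenes (≈410 cells) for the six-detector ensemble-benefit checks,
10,000 single-cell scenes for simulator calibration (exact central 99%
binomial intervals, Bonferroni-corrected across the five confusion
diagonals), 200 random instances for fusion-vs-reference equivalence and 50
for evaluation-vs-reference equivalence. All oracles in the test suite are
independent straight-line reimplementations, kept deliberately naive.

## Known limitations

* Greedy confidence-ordered clustering is order-dependent by design (that is
  what makes it deterministic); a detection may fit a later cluster better
  than the one it joined.
* The `majority` divisor reproduces one reading of the scheme's defining
  equation verbatim; which semantics produced any given published number is
  generally not recoverable, which is why both are first-class options.
* mAR's per-class, per-image top-100 cap is one of several conventions for
  average recall; it is fixed and documented rather than configurable.
* VOC XML round trips are exact only up to the documented 1-based → 0-based
  shift (subtract 1 from xmin/ymin on read, add it back on write).
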
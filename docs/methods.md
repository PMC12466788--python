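# Methods

This note documents the models and procedures implemented in `nucmorph`,
the defaults chosen where several conventions exist, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Inputs and coordinate conventions

Segmentations arrive either as Hover-Net-style JSON (one object per
instance with `contour`, `centroid` and an integer `type` code) or as
labeled instance masks. Coordinates are 0-based pixels, x rightward,
y downward; contours are stored open and closed implicitly. The default
type-code table follows the common PanNuke-trained convention
(1 = neoplastic → cancer, 2 = inflammatory → immune, 3 = connective →
fibroblast, 4 = dead, 5 = epithelial, everything else → unknown) and is
fully overridable, since deployed checkpoints differ in their code tables.
Tiles are non-overlapping 512×512 blocks at nominal 20× magnification;
partial edge tiles are dropped rather than padded. Stain normalization is
*not* performed — inputs are assumed pre-normalized upstream.

Mask reading traces each label's 0.5 iso-contour (sub-pixel boundary
following), so polygon area tracks the label's pixel count to within a few
percent; instance labels, not connectivity, define nuclei.

## Nuclear morphometry

For each contour polygon: area and perimeter are exact polygon quantities
(shapely); circularity is `4πA/P²` (1 for a circle, ≤ 1 for every simple
polygon by the isoperimetric inequality); eccentricity is
`sqrt(1 − (minor/major)²)`.

Axis lengths are the side lengths of the **minimum-area rotated bounding
rectangle**, computed by rotating calipers over the convex-hull edge
directions. This is exact and stable under rotation/scaling; GEOS's
oriented envelope is approximate in some versions, which is why it is not
used. Minimal-area ties (possible for symmetric hulls) break by the
scale-invariant aspect ratio, keeping results deterministic under rigid
motion. An alternative convention — the axes of the ellipse with the same
normalized second central moments as the polygon (the `regionprops`
convention) — is available via `axis_lengths(..., method="moment_ellipse")`;
the two differ systematically (e.g. by a factor 2/√3 for rectangles), and
neither is canonical across toolkits, so the choice is exposed rather than
hidden. Contours are measured as given, with no smoothing, so results are
deterministic functions of the input.

## Slide and patient features

Tiles with zero target-type nuclei (cancer by default; the target is a
parameter, so immune-cell features use the identical machinery) are
removed. Remaining tiles are ranked by the *proportion* of target nuclei,
with raw target count and then tile id as deterministic tie-breaks. The
top `ceil(fraction × n)` tiles are kept (default fraction 0.25, floor of
one tile). Nuclei are **pooled across the selected tiles** — not
tile-averaged — before taking the mean and sample SD (divisor n−1; a
single-nucleus pool yields SD 0 with a warning) of each of the six
characteristics, giving 12 features. Patient-level features are the
unweighted mean over the patient's slides. `cutoff_sweep` scans fractions
5%…50% (step 5%) plus all viable tiles and reports per-feature Spearman
concordance against a reference table, marking the fraction with the
highest mean ρ.

## Subtype classification

Label rules: HER2+ when HER2 is positive regardless of hormone receptors;
HR+ when HER2-negative and ER or PR positive; TNBC when all three are
negative; the four-class scheme uses HER2/ER only, with TPBC = both
positive. Records with an unknown required marker are excluded with a log
entry.

Each subtype's one-vs-all classifier is an L1-penalized logistic
regression under 5×5 nested cross-validation:

* outer folds: stratified, shuffled, seeded; the split is re-drawn (with a
  warning) until every test fold holds ≥ 2 samples of each class.
  Stratification guarantees both classes per fold for rare subtypes.
* scaling: min–max to [0, 1], fit on the training portion only; values
  outside the stored bounds are clamped at application time.
* inner folds: 5-fold grid search over C ∈ 10⁻³…10³ (13 log-spaced
  points), selecting the C with the highest mean inner-fold AUC; ties go
  to the smaller C (stronger penalty).
* the winning C is refit on the full outer-training data; the five
  resulting (bounds, coefficients, intercept, C) records are frozen into a
  JSON bundle. Out-of-fold scores concatenated in original sample order
  give unbiased evaluation; external data are scored by averaging the five
  frozen models. The argmax across subtype scores is the final call, with
  exact ties flagged and resolved by the declared subtype order.

AUC is computed as the Mann–Whitney pairwise win fraction with half credit
for ties. Feature importance is the mean of the five fold coefficients
with a 95% Student-t interval (4 degrees of freedom). Feature–subtype
association uses the two-sided rank-sum test with the rank-biserial effect
size `r = 2U/(n₁n₂) − 1`.

## Survival stratification

Features pass a collinearity filter: zero-variance columns drop first;
then, while any pair exceeds the |Pearson r| threshold, the member of the
worst pair with the larger mean |r| to the remaining features is dropped
(name-order tie-break). The threshold is chosen from {0.7, 0.8, 0.9, 0.95}
by maximizing the cross-validated C-index, since no single cutoff suits
every feature set. The Cox model (lifelines, Efron tie handling) includes
the retained features plus patient age as a confounder; monotone
likelihood or non-convergence triggers a ridge-penalized refit (penalty
0.1) with a warning.

Risk scores come from 5-fold cross-validation (fit on 80%, score the held
20%), re-drawing folds until every test fold contains at least one event.
The concatenated raw scores are quantile-normalized within the
[p10, p90] interval — 0 at or below p10, 1 at or above p90, affine in
between, with percentiles computed by linear interpolation on the full
concatenated vector — and thresholded at 0.5 (exactly 0.5 → Low).
Kaplan–Meier curves, the two-group log-rank test (1 df; significance at
P ≤ 0.1) and Harrell's C-index summarize the stratification. Overall and
progression-free survival share the identical code path, differing only in
the (time, event) columns consumed.

## Segmentation evaluation

Ground-truth and prediction label vocabularies map onto six canonical
classes via an editable YAML table (case-insensitive, default unknown);
the shipped default covers the common breast-pathology annotation
vocabulary (tumor/mitotic figures → cancer; lymphocytes, plasma cells,
macrophages, neutrophils → immune; fibroblasts; ductal → epithelial;
apoptotic bodies → dead) and the segmenter's class names (neoplastic,
inflammatory, connective, epithelial, dead).

Matching accepts candidate pairs with identical canonical class and
IoU > 0.5 (exact polygon clipping), greedily by descending IoU with id
tie-breaks, each nucleus used at most once. For non-overlapping instances
at this cutoff a ground-truth nucleus can exceed 0.5 IoU with at most one
prediction, so the greedy result coincides with the optimal one-to-one
assignment (property-tested against `linear_sum_assignment`). The
confusion matrix uses a type-agnostic alignment at the same cutoff so that
class confusions are visible: aligned pairs count (gt class → predicted
class), missed ground truth (gt class → none), spurious predictions
(none → predicted class). Per-class one-vs-all accuracy, sensitivity,
precision and F1 are reported after aggregating dead/epithelial/unknown
into "Others"; classes with no ground truth (or no predictions, for
precision) are flagged undefined (NaN) rather than zero. Overall accuracy
(diagonal / all instances) is also emitted.

## Synthetic data generator

Tiles contain non-overlapping ellipses (rejection placement on bounding
circles; a nucleus that cannot be placed after 50 tries is dropped with a
warning). Per cell type: Poisson count per tile, Normal area (floored at
30 px²), Beta-distributed eccentricity scaled to [0, 0.95), uniform
orientation. Contours are 64-vertex polygons; the truth table stores the
generative axis lengths, area, eccentricity and Ramanujan perimeter.

Default profiles (cancer nuclei, per 512×512 tile at rate 15):

| profile | area mean (px²) | area SD | eccentricity Beta |
|---|---|---|---|
| HER2+-like | 380 | 110 | (2, 4) |
| HR+-like | 300 | 30 | (2, 4) |
| TNBC-like | 380 | 110 | (6, 2) |

i.e. the aggressive profiles carry strong nuclear pleomorphism (large area
spread), the hormone-responsive profile uniform nuclei, and the TNBC-like
profile elongated nuclei so the two aggressive profiles remain mutually
separable. Immune (rate 8, area 80 ± 15) and fibroblast (rate 4,
150 ± 40, elongated) nuclei provide non-target background. Each patient
perturbs the cancer parameters (area mean ± 25 px² SD, area SD ± 15%
relative, eccentricity shape ± 10%) so within-subtype variation exceeds
pure counting noise. Marker templates per profile guarantee the label
rules recover the intended subtype.

Survival times are exponential proportional hazards on z-scored features
(betas are log hazard ratios per feature SD; baseline rate 1/1000 per
day), with independent uniform censoring whose upper bound is bisected to
hit the requested censoring fraction. All randomness flows through one
seeded `numpy` generator.

What the generator does **not** emulate: H&E texture and stain variation,
segmentation errors of real networks (shape noise beyond rigid jitter),
touching/overlapping nuclei, spatial clustering of cell types, non-ellipse
nuclear shapes, and informative censoring. Passing tests therefore
demonstrate the correctness and determinism of the computational pipeline
and its statistical machinery under known ground truth — not the clinical
accuracy of any particular segmentation model on real slides.

## Problem sizes and numerical choices

The test suite and acceptance script use a default synthetic cohort of 3
subtypes × 100 patients × 6 tiles (≈ 50k nuclei), survival simulations of
n = 300–500 with 100 seeds, and matching fixtures of ≤ 30 nuclei — sizes
chosen so the full pipeline, including nested cross-validation, runs
comfortably on a single CPU while keeping Monte-Carlo error small relative
to the asserted margins. Quantiles use linear interpolation; SDs are
sample SDs; ties everywhere break deterministically (documented per
operation); liblinear is seeded so repeated runs are bit-identical.

## Known limitations

* The axis-length convention materially affects circularity-adjacent
  comparisons across toolkits; cross-toolkit concordance of SD-type
  features (especially circularity) is expected to be weaker than for
  size features.
* Whether nuclei should be pooled across selected tiles or summarized per
  tile and averaged is a genuine modeling choice; pooling is implemented
  (and asserted), with tile-level summaries available by calling
  `compute_npifs` per tile.
* The collinearity threshold search optimizes the same C-index it reports;
  with few events this is optimistically biased. Pass a fixed threshold
  for strictly honest evaluation.
* Per-class "accuracy" in segmentation evaluation is one-vs-all over all
  instances; the overall (micro) accuracy is also reported since the term
  is ambiguous in the literature.
* WSI pyramid decoding, stain normalization and running any segmentation
  network are out of scope; the package consumes segmentations.
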
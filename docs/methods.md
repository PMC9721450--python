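# Methods

This note documents the models, conventions and design choices behind
`periradiomics`: what each stage computes, which knobs matter, what the
synthetic phantom does and does not emulate, and the numerical
conventions that a reimplementation would need to reproduce our
numbers exactly.

## Study design

The package implements a peritumoral-feature study for benign vs
malignant classification of non-spiculated, noncalcified masses
(NSNCM) on mammography. Eleven region models are compared: the tumour
alone; the peritumoral ring at 1, 2, 3, 4 and 5 mm; and the combined
region (tumour ∪ ring) at the same distances. Each model is a
radiomics feature table fed through correlation-threshold feature
selection and an L1-penalised logistic regression, evaluated with
five-fold patient-level cross-validation in a 3:1:1
train/validation/test rotation, at both ROI level (one score per
segmented view) and patient level (views aggregated). Paired model
comparisons use the DeLong test on pooled out-of-fold scores.

Because real screening cohorts of this kind are not publicly
available, the pipeline is driven by a synthetic phantom whose class
signal is fully known, so every stage can be validated against ground
truth: signal placed in the rim must be recovered by (and only by)
models that include the rim.

## Phantom generator

Each phantom patient contributes two views (CC and MLO) of one
elliptical mass inside a bright half-elliptical "breast" on a dark
background; the MLO view adds a pectoral wedge in the upper-left
corner so the body-mask stage has to retain breast *and* pectoral
tissue, as the region rules require. The intensity model per view is

    background N(0, 2) + [body] · (400 + parenchyma + N(0, noise_sd))

where `parenchyma` is a Gaussian-smoothed random field (correlation
scale 8 px, sd 25) standing in for fibroglandular texture, and
`noise_sd = 30` intensity units. The mass adds a class-independent
quadratic-profile contrast bump (peak 120): lesion *visibility* never
separates the classes.

Class signal is injected as **texture variance, not brightness**:
malignant cases receive extra zero-mean white noise of variance
`core_effect · noise_sd²` inside the mass and `rim_effect · noise_sd²`
in an annulus of `rim_width_mm` (default 2 mm) outside it. Two
consequences are used heavily in validation:

* the between-class margin in mean annulus pixel variance equals the
  injected `rim_effect · noise_sd²` exactly in expectation, so direct
  pixel statistics on generated annuli recover it (tested to 10% over
  300 lesions);
* with both effects zero the class distributions are identical and
  every downstream AUC must sit at chance.

Defaults: 256 px frames at 0.2 mm/px, mass radii 3–12 mm (diameters
straddle the clinical 20 mm size split), malignant fraction 0.41 as in
a surgical NSNCM cohort, `core_effect = 0.03`, `rim_effect = 0.06`.
The effect sizes were calibrated once so that cross-validated
radiomics AUCs land in the 0.75–0.90 range typical of published
mammography mass classifiers (tumoral ≈ 0.76, combined-2mm ≈ 0.87 at
ROI level on 100-patient cohorts) instead of saturating at 1.0; the
variance statistics of texture features over thousands of in-mask
pixels make even a few percent of excess variance highly detectable.
Experiments that need strong, localisable signal (the CNN capacity and
CAM studies) explicitly request `core_effect = rim_effect = 1.0`.

What the phantom does **not** emulate: compression deformation,
spiculation or calcification morphology, scanner noise spectra,
overlapping fibroglandular structures, BI-RADS composition variation.
Passing tests therefore demonstrate that the *pipeline* is sound —
regions are geometrically correct, features match their definitions,
cross-validation does not leak, injected signal is recovered where it
should be — not that any particular AUC transfers to clinical data.

## Region construction

The body mask is the set of pixels above the Otsu threshold, with
connected components smaller than 0.5% of the image discarded (stray
bright specks) and holes filled. The pectoral wedge is deliberately
retained.

Dilation uses the Euclidean distance transform in physical units:
`dilate(M, d) = {p : dist(p, M) ≤ d mm}`, exact under anisotropic
spacing and monotone in `d`. Then

    ring(d)     = (dilate(tumor, d) \ tumor) ∩ body
    combined(d) = (dilate(tumor, d) ∩ body) ∪ tumor

Tumour pixels are kept in the combined region even where the body mask
disagrees — the manual lesion mask wins that tie. Rings that come out
empty after the body intersection are flagged and skipped downstream.

Point-to-point distance semantics carry an inherent half-pixel
boundary bias: for a discrete disk of radius 10 px dilated by 3 px the
ring area is ≈ 6% below the continuous annulus π((r+d)² − r²), with a
lattice-dependent wobble; at d = 5 px the discrepancy is ≈ 2%. The
geometry tests therefore check the analytic-annulus area at d = 5 and
the set-algebra identities at every distance.

## Radiomics feature engine

97 features per region in six classes: first-order (18), 2D shape (9),
GLCM (24), GLRLM (16), GLSZM (16), GLDM (14). All texture classes are
computed on gray levels discretized inside the mask; conventions are
fixed as follows (they match common radiomics-toolbox definitions, and
every one of them is enforced by brute-force oracle tests at 1e-9):

* **Discretization** — fixed bin width, default 25 intensity units:
  `level = floor((v − min)/w) + 1`. Matrix rows/columns index only the
  levels actually present in the region.
* **GLCM** — symmetric, normalised per angle (0°/45°/90°/135°, offset
  distance 1 px); features computed per angle and averaged. The
  angle-averaged features are invariant under 90° image rotation.
* **GLRLM** — runs broken by mask boundaries; per-direction matrices,
  features averaged over the four directions.
* **GLSZM** — zones are 8-connected constant-level components; a
  single matrix.
* **GLDM** — dependence of a pixel = 1 + number of 8-neighbours inside
  the mask within level difference α (default 0).
* **First order** — population moments; kurtosis is *not*
  excess-corrected; entropy/uniformity use the discretized histogram;
  robust MAD is computed on the [P10, P90] band; a constant region has
  skewness and kurtosis 0 by convention.
* **Shape** — physical units from pixel spacing; perimeter by
  marching-squares contour length (valid for anisotropic spacing);
  axis lengths 4·√eigenvalue of the coordinate covariance; elongation
  = minor/major; circularity = 2·√(πA)/perimeter; maximum diameter via
  the convex hull of boundary pixels.

The engine is mask-local (pixels outside the mask never influence any
feature) and deterministic. The published feature count for this study
design (825) depends on filter banks and discretization settings that
are not reproducible from the available description; the engine
records its own feature manifest (97 names) instead of forcing a
count. A region too small to contain a co-occurrence pair yields NaN
GLCM features with a warning rather than a hard error.

## Classifier stack

`CorrelationFilter` removes one member of every feature pair with
|Pearson r| > 0.9: offending pairs are resolved greedily in descending
|r| (lexicographic tie-break), dropping the feature with the lower
relevance — absolute point-biserial correlation with the label;
constant features have relevance 0. The procedure is deterministic and
idempotent.

`L1LogisticModel` z-scores features with training-fold statistics and
fits an L1-penalised logistic regression (liblinear), choosing the
inverse penalty `C ∈ {0.01, 0.1, 1, 10}` by AUC on the rotation's
validation fold; ties prefer the stronger penalty. Everything
data-dependent — filter, standardisation, penalty — is computed
strictly inside the training/validation folds of each rotation; the
label-permutation guard verifies there is no leakage path.

Cross-validation is stratified by label at the *patient* level (both
views of a patient always share a fold, preventing view leakage);
rotation r uses fold r as test and fold r+1 as validation. The
reported AUC per model is the mean over the five test sets; confidence
intervals and DeLong comparisons use the pooled out-of-fold scores,
where each case is scored exactly once. Patient-level scores use the
maximum over a patient's views (most-suspicious-view reading; mean and
min are available). Sensitivity/specificity use the Youden-J threshold
chosen on the validation fold; the degenerate all-scores-equal case
reports (sensitivity 0, specificity 1) by a deterministic
larger-threshold tie-break.

`auc` is the Mann–Whitney statistic with midrank ties; `delong_test`
implements the structural-components algorithm (V10/V01 with
midranks), with a two-sided normal p. Degenerate comparisons — fewer
than two cases in a class, or zero variance of the AUC difference
(e.g. a model against itself) — report z = 0, p = 1 with a flag. CIs
are auc ± 1.96·SE truncated to [0, 1].

## Small CNN and CAM

The optional deep stage is a deliberately small convolutional
classifier written directly in numpy: 3×3 conv / leaky-ReLU / 2×2
max-pool blocks (channels 16-32-128, pooling until the maps reach
8×8), global average pooling, batch normalisation of the pooled
features, and a single linear output with sigmoid. Inputs are
region-masked crops: pixels outside the region zeroed, the region's
square bounding box resized to 64 px, standardised to mean 0 / sd 1.

The training loop mirrors a full-scale recipe: binary cross-entropy,
SGD with momentum 0.9 and weight decay 1e-5, random horizontal and
vertical flips, learning rate dropped ×0.1 after a ten-epoch loss
plateau, global gradient-norm clipping at 5. The tiny preset uses
lr 0.02 and batch 4; training is seed-deterministic. Because the head
is linear over globally averaged maps, the class-activation map is
exact: CAM = |Σₖ (wₖ/σₖ)·(mapₖ − mapₖ⁰)| (the batch-norm scale folds
into the weights), bilinearly upsampled to the input and min-max
normalised to [0, 1]. Here mapₖ⁰ is the network's response to a crop
filled with the background constant: region-masked crops have a large
uninformative zeroed background, and leaky activations give it a
nonzero constant response that would otherwise dominate the
normalised map; referencing against the empty input makes the CAM
measure evidence magnitude, so it concentrates where the model
actually reads signal. A full residual network is intentionally out of scope; the
tiny variant exists to exercise the training-loop and CAM contracts at
desk scale.

## Clinical-table statistics

`chi_square` computes the Pearson statistic on r×2 count tables,
applying the Yates continuity correction to 2×2 tables only — the
convention that reproduces the published statistics for the packaged
1298-patient NSNCM cohort table (age 252.6 on 4×2 uncorrected, size
61.701 on 2×2 with Yates — the uncorrected value would be 62.59 —
composition 61.399 on 4×2 uncorrected). The empty malignant cell in
the ≤20-year band is a structural zero; the statistic remains defined
because row/column totals are positive, and zero marginals raise an
explicit error. `two_sample_t` is the pooled-variance two-tailed test,
with the zero-variance equal-means degenerate case reported as
(t = 0, p = 1).

## Problem sizes

The benchmark experiments (`periradiomics.experiments`, also run by
`scripts/acceptance.py`) use 200-patient cohorts × 5 seeds for the
signal-recovery comparison, one 200-patient signal-free cohort for the
chance band, one 100-patient cohort for the permutation guard, and
8/30-patient cohorts for the CNN capacity/CAM study — sizes chosen so
class-mean AUC differences of a few points are resolvable while a full
re-run stays in the minutes range on a single core.

## Known limitations

* Phantom realism is deliberately minimal (see above); absolute AUCs
  on phantoms say nothing about clinical data.
* 2D only; multi-lesion cases and 3D dilation are out of scope.
* The feature manifest is fixed at 97 features; no wavelet/LoG filter
  banks.
* The CNN is a capacity-scale model, not a clinical classifier; its
  accuracy on phantoms is a contract check.
* DeLong comparisons on pooled out-of-fold scores treat the five
  rotations' models as one scoring rule; fold-to-fold model variation
  is visible in `fold_aucs` but not propagated into the CIs.
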
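# Methods

## Problem and model

The package estimates the quality of an automatic short-axis cardiac
segmentation without a reference. The target quantity is the Dice
similarity coefficient DSC = 2|X∩Y|/(|X|+|Y|) of the candidate mask X
against the (absent at inference time) reference Y. Quality is
dichotomised at DSC 0.7 for single slices (2D) and 0.85 for reconstructed
subject-level masks (3D); a value exactly at the cutoff counts as good.
3D masks are stacks of the 2D slices, so a single bad apical slice barely
moves the 3D DSC even though it can shift 3D shape features (long-axis
length in particular) substantially — which is precisely why slice-level
QC matters.

The estimator is supervised: radiomics features of the image region inside
the candidate mask → DSC. When a mask leaks into the wrong tissue or
misses part of a structure, the intensity statistics and texture of the
covered region shift in a way that correlates with the overlap error; the
shape families capture implausible geometry directly.

Two models are trained per (structure, level) group:

* **Regression** — gradient-boosted trees predicting DSC, tuned by 5-fold
  cross-validated grid search on mean absolute error over
  {trees 100, 300} × {depth 2, 3, 4} × {learning rate 0.05, 0.1}, refit on
  all training rows. Sample weights balance the good/bad groups so scarce
  bad segmentations are not drowned out. Predictions are clipped to [0, 1].
* **Classification** — a random forest (class_weight=balanced) over
  {trees 200, 500} × {depth None, 8}, selected by cross-validated negative
  detection rate NDR = TN/(TN+FN) with AUC as tie-break: a QC system's
  first duty is catching bad segmentations, not overall accuracy. The
  decision threshold is 0.5 on the predicted-good probability; AUC is
  reported so the thresholding stays auditable.

The **two-stage filter** combines them: DSC estimates are trusted only for
predicted-good masks, and the reported improvement is MAE(all) −
MAE(kept).

### Confusion-matrix polarity

"Positive" means predicted good, "negative" predicted bad. In
`ConfusionCounts`, fn denotes an actually-bad segmentation that slipped
through (predicted good), so tn + fn is the actually-bad count and NDR is
the detection rate for bad masks. NDR is undefined (an error, not a
silent 0) when no actually-bad instances exist.

## Radiomics features

The extractor is implemented in this package with numpy/scipy/scikit-image,
following the IBSI conventions and the de-facto standard feature set of the
radiomics literature. Families and counts:

| family      | 2D | 3D | notes |
|-------------|----|----|-------|
| shape       |  9 | 14 | mm units via grid spacing; mesh from marching squares/cubes |
| first-order | 18 | 18 | on 0–256-rescaled intensities; Entropy/Uniformity on the discretized histogram |
| GLCM        | 24 | 24 | symmetric, distance 1, averaged over 4 / 13 directions |
| GLRLM       | 16 | 16 | runs broken by the ROI boundary, direction-averaged |
| GLSZM       | 16 | 16 | zones = fully-connected same-level components |
| GLDM        | 14 | 14 | α = 0; dependence size = 1 + dependent neighbours |
| NGTDM       |  5 |  5 | Amadasun–King definitions |

Totals: 102 (2D), 107 (3D). Deprecated/duplicate variants of the
historical feature sets are excluded so the totals are exact.

Pre-processing: the image (slice for 2D, volume for 3D) is linearly
rescaled to [0, 256] and discretized with a fixed bin width of 16 (≈16
gray levels), bins anchored at intensity 0 so gray-level-weighted features
are comparable across masks of the same image. "Normalisation to 0–256"
is read as a linear rescale, not a μ/σ standardisation — the natural
reading for a subsequent fixed-bin-width discretization. For 3D the z axis
is resampled to 1.0 mm (image linearly, mask nearest-neighbour) for voxel
isotropy before extraction. Features come from the original (uncropped,
un-equalised) intensities; the CLAHE/min–max chain in `geometry` serves the
localisation path, not feature extraction. 2D extraction assumes the 1.0 mm
in-plane grid that `resample_inplane` produces.

ROIs with fewer than 2 foreground pixels yield a *failed record* (flagged,
reason logged) rather than an exception, because candidate masks of
quality zero are a normal occurrence in QC datasets; failed rows are
excluded from model fitting.

## Localisation geometry

The whole-heart mask (union of the three structure labels) replaces a
dedicated localisation network. Each slice j contributes its foreground
pixel count W_j and centroid (X_j, Y_j); the subject-level crop centre is
Σ W_j X_j / Σ W_j (and likewise Y), which equals the in-plane centroid of
the whole 3D foreground. The centre is rounded half-away-from-zero to an
integer pixel before windowing (sub-pixel cropping would force
interpolation); windows are half-open, 160×160 px by default, zero-padded
at image borders. Coordinates are (row, col), 0-based throughout.
CLAHE uses clip limit 0.01 and an 8×8 tile grid — standard defaults, since
only the method itself is prescribed by the application.

## Synthetic phantoms

Each subject is a stack of 6–12 slices (z spacing 6–10 mm, in-plane 1.0 mm)
with an LV-cavity disk (radius 18–26 mm), a myocardial annulus (thickness
6–10 mm) and an RV-cavity crescent abutting the annulus, all radii
tapering linearly base→apex (apical radius 45% of basal by default).
Intensities are per-tissue means (background 55, MYO 110, RV blood 185, LV
blood 200, arbitrary units) with Gaussian noise (σ = 14), a smooth
multiplicative low-frequency field (coil-shading analogue) and a mild PSF
blur. Disease presets scale geometry only: HCM thickens MYO ×1.8, DCM
dilates LVC ×1.5 with MYO ×0.6, HHD thickens MYO ×1.4; the default cohort
mix is 40% HC / 20% each disease. The phantom intentionally omits MR
physics (k-space artifacts, bias fields beyond the smooth shading),
papillary muscles and temporal frames; passing tests therefore demonstrate
that the method recovers quality signal when image–mask mismatch is the
dominant effect, not that it is robust to every scanner artifact.

## Perturbation engine

Eight modes degrade one structure of a label volume: dilation and erosion
(up to 8 iterations at severity 1), boundary jitter (smoothed noise added
to the signed distance function, typical displacement up to 14 px),
translation (up to 24 px), dropping apical or basal slices, false blobs in
background, and complete removal. Severity 0 is the identity for every
mode except `empty`; mean DSC is monotone decreasing in severity for every
mode. `calibrate_severity` inverts the severity→DSC map by bisection
(tolerance 0.05, ≤30 iterations) and errors when a target lies outside the
mode's achievable range (dilation, for instance, cannot reach DSC 0).
Where the perturbed structure expands it claims the voxels it covers, as a
real mis-segmentation would; other structures are otherwise untouched.

A variant bank cycles Dice targets through a grid (default 0.2…1.0 in
steps of 0.1; small banks sample the grid end-to-end) with the degradation
mode drawn per variant, so the realized DSC histogram spans both quality
cutoffs for every structure. The default bank size is 32, mirroring a
plausible set of 4 architectures × 8 checkpoints of varying quality. The
targeted-DSC distribution is a design surface of this package — real
segmentation-model error distributions are model- and site-specific.

## Feature selection

Redundancy pruning drops a feature iff |Pearson ρ| > 0.8 against an
already-kept feature, scanning in canonical extraction order (greedy
keep-first; deterministic, row-order invariant). |ρ| rather than signed ρ,
because anti-correlated features are equally redundant. Zero-variance
columns are dropped with the reason recorded. Survivors are ranked by
k-nearest-neighbour mutual information with the continuous DSC (k = 3,
seeded) for regression, or by the one-way ANOVA F statistic against the
good/bad label for classification, keeping at most 12 features — a cap
consistent with the sample sizes the models see per group. `sweep_k`
chooses a feature count by cross-validated score with ties broken toward
fewer features. Selection runs on training subjects only; splits are
grouped by subject so no heart contributes to both sides.

## Evaluation and reporting

Reports contain MAE, R², AUC, confusion counts, NDR, and per-disease MAE
when presets are present. Bland–Altman agreement uses mean = (actual +
predicted)/2 and difference = actual − predicted with limits of agreement
mean ± 1.96 SD; with this sign convention a mask of true DSC 0 predicted
at D lands at (D/2, −D), so all such false-positive points lie on the line
y = −2x. The orientation is configurable, and the y = −2x locus is the
reason for the default. Density tables are shared-bin histograms of
absolute error per stratum; all acceptance checks read numeric tables,
never rendered figures.

## Problem sizes and numerical choices

The end-to-end experiment used by the test suite and `scripts/acceptance.py`
runs 40 phantom subjects × 32 variants of the LV cavity at slice level
(≈11,000 usable rows, about half below the 0.7 cutoff), split 70/30 by
subject — a scaled-down analogue of a multi-hundred-subject study chosen
to keep a full from-scratch reproduction in the minutes range. The
one-sided two-stage check resamples test subjects (10 bootstrap
replicates) of a single trained model pair rather than retraining ten
times; it tests the filter property itself, which is the claim of
interest. Ten full retrainings gave the same sign in pilot form but add
nothing but runtime.

Degenerate inputs are handled by convention, stated where they occur: two
empty masks have DSC = IoU = 1 (agreement on absence; such records carry
an `empty_pair` flag so QC can exclude them — a choice, since DSC is
undefined in the literature when the structure is absent), precision and
recall are 1 when their denominators vanish, a constant volume min–max
normalises to zeros, and a constant ROI has zero variance/contrast and
unit uniformity. GLCM features of a single-gray-level ROI use the
degenerate conventions Correlation = MCC = 1. Ties in grid search resolve
to the first configuration in grid order (seeded CV makes this
deterministic).

## Known limitations

* Feature values follow IBSI definitions but are not bit-compatible with
  any particular third-party extractor (mesh construction and aggregation
  details differ between implementations).
* The phantom's texture is statistically simple; absolute MAE/NDR numbers
  on synthetic data should not be read as clinical performance claims.
* Only end-diastole-like single-frame stacks are modelled.
* RV geometry is a simple crescent; real RV shape variability (the hardest
  structure for 3D QC) is underrepresented.
* The perturbation engine's severity→DSC map is assumed monotone for
  bisection; individual seeds can deviate slightly from the mean trend,
  which the 0.05 calibration tolerance absorbs.
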
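# Methods

This note documents the models, conventions and design choices behind
`perirec`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with which
defaults, and what the synthetic validation does and does not establish.

## Inputs and coordinate conventions

The pipeline assumes per-case coregistered, brain-extracted, 1 mm isotropic
3D volumes in NIfTI-1: five modalities (T1w, T1ce, T2w, FLAIR, ADC), a
surgical-cavity mask, a peritumoral mask, and — for training/evaluation — a
follow-up enhancing-tumor mask. Registration, bias-field correction and
brain extraction are upstream of this package and are not reimplemented.

Voxel indices are 0-based; world coordinates come from the NIfTI affine, and
every millimeter distance (cavity distance transform, sector geometry, filter
scales) is computed in world space. Orientation is read from the file
header, never assumed. Intensity normalization is z-scoring within a mask
(whole-brain by default; the choice of normalization support is exposed
because nothing in the problem fixes it), using the population SD
(`ddof=0`, configurable). Masks are resampled nearest-neighbour and
re-binarized at 0.5; images trilinearly.

## Ground-truth labels

A peritumoral voxel is recurrence (1) iff it lies in the follow-up
enhancing-tumor mask; otherwise nonrecurrence (0). The labeled support is
exactly the peritumor, so class counts always sum to the peritumoral voxel
count — this conservation is asserted throughout. Follow-up enhancement
outside the peritumor (typically regrowth bulging into the resection cavity)
carries no label. No morphological cleaning is applied to the overlap; in
clinical practice this step is replaced by expert review, which is out of
scope.

## Voxelwise radiomic features

Features are computed per voxel on a cubic kernel of radius r (edge 2r+1,
default r=2) centered at the voxel, intersected with the brain support.
Kernels with fewer than 8 in-support voxels are computed on what is available
and flagged in a QC column.

* **First-order (19)**: energy, total energy (energy × voxel volume),
  entropy, minimum, 10th/90th percentile, maximum, mean, median,
  interquartile range, range, mean absolute deviation, robust MAD (restricted
  to the 10–90 percentile band), RMS, skewness, kurtosis (non-excess),
  variance (population), uniformity, standard deviation. Entropy and
  uniformity use intensities discretized into equal-width bins (default 16)
  over the kernel's own range; all other features use raw values. Skewness
  and kurtosis of a zero-variance kernel are defined as 0.
* **Texture (75)**: GLCM (24), GLRLM (16), GLSZM (16), NGTDM (5), GLDM (14),
  on the same per-kernel discretization. GLCM and GLRLM use the 13 unique
  3D directions at distance 1 with features computed per direction and
  averaged; GLSZM zones, NGTDM neighbourhoods and GLDM dependencies (α=0)
  use 26-connectivity. Degenerate matrices take their analytic limits (e.g.
  a patch with no co-occurring pair takes the constant-patch GLCM limit)
  rather than producing NaN; no non-finite value leaves the module.
* **Filter bank**: original image; Laplacian of Gaussian at σ ∈ {1, 2, 3} mm
  (σ in world units; second derivatives converted to mm⁻²; DC gain of the
  truncated kernel subtracted so constants map to exactly zero); one-level
  separable 3D Haar wavelet, each of the 8 sub-bands reconstructed to source
  resolution (the sub-band images are orthogonal projections, so their
  energies partition the input energy); a rotation-invariant 3D LBP code
  counting the 6 face-neighbours ≥ the center (0–6, replicate padding).

Column names are `modality|filter|family|feature`; the manifest length is a
function of the configuration and is emitted and logged rather than
hard-coded (five modalities × original filter × all families = 470 columns,
94 per modality-and-filter channel). Extraction kernel mechanics, binning,
and the exact filter-bank composition are deliberately configuration, since
voxel-level radiomics has no single canonical setting; the defaults above
are common practice and keep desk-scale cost.

First-order maps run fully vectorized over all kernels at once; texture
families use a per-voxel patch loop. Results are by construction independent
of voxel execution order.

## Class balancing and classifiers

Recurrence voxels are a small minority (roughly 2–10% of the peritumor), so
the majority class is randomly undersampled to the minority size before
fitting — pooled across training cases, seed-deterministic, retaining every
minority row; an already balanced input is returned unchanged. In the
pipeline the undersampling decision is made from the label masks *before*
feature extraction, which retains provably the same row set as undersampling
a fully extracted table with the same seed but skips feature cost for
discarded voxels (this equivalence is tested).

Four backends are exposed under one estimator interface
(`RecurrenceVoxelClassifier`: sklearn `fit`/`predict_proba`, balancing
built in): histogram gradient boosting (scikit-learn), XGBoost, random
forest, and LightGBM. Defaults are each backend's defaults with a fixed
seed and a 200-iteration cap — reproducibility is preferred over tuning, and
no hyperparameter search is performed. Probabilities are used downstream
only as scores: any strictly monotone transform leaves voxelwise AUC
unchanged (tested). Prediction ties (p = 0.5) resolve to nonrecurrence.
Feature importances are normalized to sum to 1 and reported with the
cumulative-importance curve.

## Probability maps, distance correction, Otsu labels

Histopathology places most infiltration within ~15 mm of the resection
margin, so predicted probabilities are attenuated with distance from the
cavity edge: multiplier f(d) = 1 for d ≤ cutoff (default 15 mm) and
f(d) = exp(−λ(d−cutoff)) beyond, λ = 0.5 /mm. The literature supports only
"strong reduction beyond 15 mm", not a functional form; this form was chosen
because it is continuous at the cutoff, nonincreasing, never amplifies, and
has a single interpretable parameter. Both cutoff and decay are config.
Distances are Euclidean distance-transform values in world mm, zero on the
cavity itself; a stage guard prevents applying the correction twice.

The corrected map is binarized at the Otsu threshold of the case's own
peritumoral scores (256-bin histogram, per case — so one case's prediction
never depends on another's). Note a property of Otsu on well-separated
bimodal score distributions: the between-class variance is constant across
an empty gap between modes, so the standard argmax-first convention places
the threshold at the gap's lower edge, not mid-gap. Tests therefore assert
that the threshold attains the exhaustive-search maximum of the objective
and separates the modes, rather than a specific position inside the gap.
Constant score maps have no threshold and raise an explicit error.

## Sector (region-based) evaluation

Because infiltrated regions evolve between scans and follow-up
coregistration is imperfect, exact voxel overlap understates clinically
meaningful agreement. The peritumor is therefore partitioned into up to 26
directional sectors around the cavity centroid: each voxel's unit
displacement is classified per axis as negative/neutral/positive with a
±22.5° neutral band (a component is neutral when |u_axis| < sin 22.5°; at
least one axis is always non-neutral, so the all-neutral triple cannot
occur), and the sign triple indexes one of 3³−1 = 26 sectors — 6 faces, 12
edges, 8 corners — named anatomically from the header orientation. A voxel
exactly at the centroid is assigned positive along the last axis
(documented tie-break; it can occur only when the centroid falls inside the
peritumor).

A sector is called positive when its positive-voxel count reaches an
activation fraction of the sector's peritumoral voxel count, applied
identically to ground truth and prediction. The default fraction is 0.05.
This choice is deliberate: the activation threshold must exceed the
method's background voxelwise false-positive rate, otherwise sector labels
track noise rather than regional recurrence. On held-out phantoms the full
method's false-positive rate is ~2–3% of nonrecurrence voxels (spatially
clumped, because texture is correlated), so a 1% activation would mark
nearly every sector positive under realistic conditions, while 5% sits above
the background rate and an order of magnitude below the fill fraction of
truly recurrent sectors (~20–80%). The fraction is configurable.

Sector metrics are the same six as voxelwise; the continuous sector score
for AUC is the 95th percentile of corrected voxel probabilities within the
sector (configurable among max / mean / percentile; the maximum is fragile
to single-voxel noise and the mean dilutes focal signals). Empty sectors
are excluded and logged; single-class truth reports AUC as missing with a
reason rather than a number. Cohort aggregation is mean ± SD (population
convention) per metric, with missing values excluded and the contributing
case count reported.

## Synthetic phantoms

`generate_phantom` builds a case as: a spherical cavity (default radius
10 mm) centered (with per-case jitter) in a 64³ 1 mm grid; a peritumoral
shell (default 12 mm thick); a recurrence region = the part of the shell
within a cone (default 60° full apex angle) around a per-case random
direction and within a radial depth (default 10 mm) of the cavity edge; and
a follow-up enhancing mask = recurrence ∪ a bulge into the cavity, so the
clipping of follow-up enhancement to the peritumor is exercised. The
64³-at-1 mm default keeps full-pipeline experiments at minutes scale.

Intensities are smoothed Gaussian random fields: white noise blurred at a
correlation length (default 2 mm), unit variance, shared across modalities
through a latent field (mixing weight 0.5) to emulate multiparametric
redundancy, plus i.i.d. noise (SD 0.5). Recurrence voxels differ from the
edematous remainder in two ways: a mean shift of `effect_size` × the
marginal SD in the reference modality (T1ce; other modalities scaled by
fixed physiologically signed weights — positive enhancement on T1ce and
FLAIR, negative on ADC), and a partial substitution (weight 0.5) of a
second random field with a longer correlation length (3.5 mm) that alters
texture without changing mean or variance. When `effect_size = 0` the
texture substitution is disabled too, making the phantom an exact null —
the generator guarantees that zero effect size means statistically
indistinguishable classes, which the null-AUC validation relies on. The
default `effect_size = 2` represents a strong, clearly detectable contrast.

What the phantoms are not: anatomically realistic brains. There is no
anatomy, no registration error, no pseudoprogression, no field
inhomogeneity. Passing phantom validation demonstrates that the machinery —
labeling, feature maps, balancing, training, correction, thresholding,
sector scoring — is correct and recovers planted signal with the right null
behavior; it says nothing about the discriminability of real peritumoral
infiltration, whose intensity contrast is unknown and surely far weaker.
Published quantitative descriptions of that contrast do not exist, so the
effect size is a free simulation parameter, not an estimate of biology.

## Validation experiments and problem sizes

The test suite validates every stage against independent oracles: all 75
texture features against naive enumeration implementations on random
5³ patches (tolerance 1e-8 relative); the Otsu threshold against exhaustive
256-candidate search; the first-order mean map against a box-filter
convolution; the published balancing arithmetic (160,366 / 1,409,124 →
320,732) and per-cohort voxel-count conservation at the published sizes
exactly. Parameter recovery runs the full pipeline on a 40-train/15-test
phantom cohort at 64³ (the design size of the study this emulates): held-out
voxelwise AUC > 0.8 and sector accuracy > 0.8 at strong effect, and
voxelwise AUC in [0.45, 0.55] for the zero-effect null. Monotonicity of
held-out AUC in effect size is checked over three effect sizes × five seeds
on compact 48³ geometries. The acceptance script uses a 10/5 cohort at 64³,
chosen as the smallest size at which cohort means are stable.

## Known limitations

* Voxelwise texture-family extraction is a per-voxel Python loop; at 64³
  phantom scale it is usable, at clinical volumes first-order-only
  configurations are the practical default.
* LightGBM/XGBoost determinism is guaranteed only within a fixed platform
  and thread configuration; backends are run single-threaded by default.
* The distance-correction functional form and the sector activation rule are
  reasoned defaults for under-specified steps, not fitted quantities; both
  are exposed as configuration.
* The Otsu threshold is per case; pooled thresholding across a cohort is not
  implemented.
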
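# Methods

`habitat_rfa` rebuilds, as a tested pipeline, a habitat-based radiomics
analysis of paired pre-/post-ablation chest CT for predicting local response
(complete response, CR, vs non-CR) of small lung metastases treated with
percutaneous radiofrequency ablation. Patient CT data of this kind are not
publicly deposited, so the package ships a synthetic-cohort generator that
reproduces the statistical structure the analysis relies on; every stage is
exercised end to end on that substrate.

## Synthetic cohort

Each lesion is a paired phantom on a small 3-D grid (default voxel spacing
1.0 x 1.0 x 1.25 mm, mimicking sub-1.5 mm CT protocols):

* **Geometry.** The tumour is an axis-aligned ellipsoid whose largest
  diameter is drawn from a log-normal matched to a typical treated cohort
  (1.21 +/- 0.66 cm for CR, 1.35 +/- 0.42 cm for non-CR), truncated to
  (0.4, 3.0] cm — 3 cm being the usual RFA inclusion limit. The other two
  semi-axes are shrunk by factors in [0.75, 1].
* **Latent subregions.** Three concentric zones with irregular, blobby
  boundaries: the zone field is the tercile partition of a noisy radial
  potential (normalised radius plus 0.3 x a Gaussian random field smoothed
  at 3 voxels). Zone HU means rise inner to outer (10, 45, 80 HU —
  necrotic core, effusion band, congested rim); zone SDs are V-shaped
  (16, 4, 16 HU) because effusion is fluid and nearly homogeneous while
  necrotic debris and the congested rim are heterogeneous. Tumour texture
  noise is white at the 1 mm grid scale. With `latent_subregions=1` the
  interior is a single texture population.
* **Post-ablation image.** The ablation zone is the tumour support dilated
  by a uniform random 3-8 mm margin (physical-unit Euclidean distance),
  filled with ablated-tissue texture (-120 +/- 25 HU), surrounded by a 4 mm
  ground-glass halo (-500 +/- 60 HU). In non-CR lesions only, a wedge
  subtending 5-30% of the solid angle is blended toward residual tumour
  texture; it occupies the outer part of the zone and spills a random
  2-5 mm beyond the zone boundary — the incomplete-margin pattern that is
  read clinically as peripheral enhancement around the ablated area, and
  the reason peritumoral features carry predictive information here. The
  blend weight is the `texture` effect size, so zero effect removes the
  label signal entirely.
* **Clinical covariates.** Marginals are moment-matched, per outcome class,
  to a published cohort table (CA19-9 and CEA log-normal with class-specific
  means/SDs; class-conditional frequencies for systemic treatment, lobe,
  electrode type, and the other flags). The non-CR shift of every covariate
  is scaled by the `clinical` effect size. Covariate correlations beyond
  what the class label induces are not modelled (only marginals are
  published).

What the generator deliberately does not emulate: CT physics (beam
hardening, reconstruction kernels), respiratory motion, vessels/airways
inside the ring regions, inter-scanner variation, and longitudinal
follow-up imaging. Tests passing on this substrate therefore demonstrate
the pipeline's statistical and numerical correctness, not clinical
performance on real CT.

## Preprocessing and regions

Volumes are resampled to 1 mm isotropic (cubic B-spline for intensities,
nearest neighbour for masks; output grid `ceil(extent / target)`), then
windowed to [-1200, 600] HU and linearly rescaled to 0-255. Peritumoral
shells of 5 and 10 mm are built from the Euclidean distance transform in
physical millimetres, clipped to the lung mask (a deterministic stand-in
for manual exclusion of heart/vessels/diaphragm overlap). The "Peri-X"
analysis region is the union of the intratumoral/ablation mask and its
X mm shell; the per-phase region of interest is the tumour mask before
ablation and the ablation-zone mask after.

## Habitat construction

The region of interest is tiled with non-overlapping 3x3x3 voxel blocks
(blocks with under 50% ROI coverage are dropped). Each block yields a
77-dimensional local feature vector: 16 first-order statistics; histogram
entropy and uniformity at 8 and 16 bins; normalised energy; and 14
Haralick co-occurrence statistics x 2 grey-level settings (8/16) x 2
direction aggregations (mean and range over the 13 unique 3-D directions).
Block histogram and co-occurrence grey levels span the lesion's own
intensity range rather than the absolute 0-255 scale: after lung
windowing a tumour occupies a ~10-unit band, and absolute coarse bins
would collapse every block to a single level.

Per lesion and phase, block vectors are z-scored and clustered with
k-means (k-means++, fixed seed, fit on canonically sorted rows so the
result is independent of block enumeration order). The cluster count is
chosen by maximising the Calinski-Harabasz (CH) score over k = 2..6 (ties
to the smallest k); the pipeline can also fix K (default study condition
K = 3). Cluster labels are renumbered by ascending mean intensity, so
habitat 1 is always the darkest subregion. Radiomics features are then
extracted per habitat (habitats under 8 voxels are marked missing) along
with the across-habitat mean of each feature.

**A documented limitation of CH-based cluster-count selection.** On
phantom lesions of realistic size (~1.2-1.6 cm), 50-70% of 3 mm blocks
straddle zone boundaries; their partial-volume feature vectors fill the
space between the zone populations. In the full 77-dimensional z-scored
space the CH argmax then lands on K = 2 (the between/within gain from
splitting a bridged, near-collinear trimodal structure does not offset
the k-1 penalty plus the dispersion floor contributed by the many
texture dimensions that noise dominates at 27 voxels per block), while
in low-dimensional projections it overcuts the bridge continuum. The
same undercutting reproduces on clean Gaussian mixtures unless nearly
all 77 dimensions separate the components. CH selection therefore
recovers a planted K reliably only when the planted structure separates
the block populations in most feature dimensions; the corresponding
whole-image recovery check in the acceptance suite documents this
honestly rather than masking it.

## Radiomics features

Per (image, mask) pair: geometry (voxel-counted volume, face-counted
surface area, sphericity, maximum 3-D diameter between surface-voxel
centres, PCA elongation); intensity first-order (mean, median, SD, energy,
entropy, skewness, kurtosis, P10, P90, IQR) with fixed-bin-width
discretisation (width 25 on the 0-255 scale, anchored at the ROI minimum
so intensity shifts relabel nothing); GLCM (contrast, correlation, joint
entropy, homogeneity; symmetric co-occurrence, mean over the 13 unique
directions); GLRLM (SRE, LRE, GLN, RLN; direction-averaged). Degenerate
conventions: constant regions have zero SD/entropy/contrast, skewness and
kurtosis 0, GLCM correlation 1; a single-voxel mask yields geometry only.
Pre- and post-phase vectors are fused under `pre.`/`post.` prefixes.

## Feature selection cascade

On training lesions only: (1) robustness filter keeping features with
ICC(2,1) >= 0.85 between the original extraction and a seeded
one-voxel-morphological-perturbation re-extraction (a stand-in for a
second rater; skipped for habitat features, whose unsupervised labels make
ICC unsuitable); (2) z-scoring with train-fitted moments applied unchanged
to test lesions; (3) Welch t-test keeping p < 0.05; (4) greedy recursive
deletion of the feature with most |r| > 0.9 partners until no pair
exceeds the threshold; (5) mRMR (MID criterion, mutual information on
equal-frequency 4-bin discretised features) taking the top 8 per region
pool; (6) LASSO on the 0/1 outcome with lambda minimising stratified
10-fold cross-validated MSE over 100 log-spaced values from lambda_max
down to 1e-4 x lambda_max. The fused Habitat+Peri-5 signature uses the
union of the Habitat- and Peri-5-selected features.

## Signatures and evaluation

The clinical signature screens covariates by univariate logistic
regression (Wald p < 0.05) and retains multivariate-significant ones;
ill-conditioned joint fits fall back to a ridge-stabilised fit with a
warning. Radiomics signatures are fitted per region with a small
hyperparameter grid searched by stratified five-fold cross-validated AUC
(families: logistic regression, SVM, KNN, random forest, extremely
randomised trees, XGBoost, LightGBM, MLP; per-signature defaults follow
the published winners — RF for Intra, LightGBM for Peri-X, ExtRa Trees
for Habitat, XGBoost for Habitat+Peri-5 and Clinical). The Youden
threshold is frozen on training probabilities before any test evaluation;
a signature whose cascade retains no features falls back to a constant
prevalence predictor.

Evaluation implements the comparison statistics from their formulas: AUC
as the tie-corrected Mann-Whitney statistic with a DeLong
structural-components variance for the CI; the paired two-sided DeLong
test (zero-variance difference gives p = 1); Youden-maximising threshold
metrics; the Hosmer-Lemeshow C-statistic on deciles of risk with G-2
degrees of freedom (degenerate groups merged with a warning; note the G-2
reference describes fitted-model probabilities); and decision-curve net
benefit NB(pt) = TP/n - (FP/n) pt/(1-pt) with treat-all/treat-none
references on a 0.01-0.99 grid.

## Problem sizes and reproducibility

The package's own test and acceptance runs use desk-scale cohorts chosen
so that every stochastic check retains a handful of events per class:
full-pipeline calibration and ordering checks run cohorts of 40-75
lesions at the 4:1 split (test sets of 8-15 lesions with >= 2-3 non-CR
events — the minimum for the DeLong normal approximation to be
meaningful), while split arithmetic and prevalence checks use the full
515-lesion condition. Every random stage (cohort, split, k-means, CV
folds, classifiers) derives its seed from a single config seed; two runs
with identical configs are bit-identical. `run_all` writes per-stage
artifacts, a selection trace, and a provenance record with a config hash.

## Known limitations

* CH-based cluster-count selection on whole images undercuts at realistic
  lesion sizes (see above); the habitat maps themselves (fixed K = 3) are
  stable and well-ordered.
* The ICC re-test perturbation is morphological only; it does not model
  inter-rater bias fields.
* The clinical covariate model matches marginals, not joint structure.
* Printed odds ratios in the emulated study's clinical table cluster
  implausibly near 1 and one CI is malformed; the package implements
  standard logistic screening and does not chase those values.
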
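# Methods

This note documents the models, defaults and design choices behind
`latentrad`, and what the synthetic studies do and do not demonstrate.

## Phantom cohorts and the planted outcome model

Each case is a pseudo-CT volume (default 32³ voxels at 2 mm isotropic,
Hounsfield-like intensities) containing one hyperdense lesion on a noisy
parenchyma-like background (level 30, SD 3). The lesion is an ellipsoid
(axis ratios drawn from [0.6, 1]) whose radius function is perturbed by a
zero-mean combination of degree-2..4 real spherical harmonics; the per-case
perturbation amplitude ("irregularity") is drawn uniformly up to the
configured maximum (default 0.25). Semi-axes are calibrated against the
angular mean of (1 + f)³ so the rasterised volume matches the drawn target
volume (default 1–40 mL) to within discretisation error; the recorded
baseline volume is the exact rasterised volume. Lesion intensity is drawn
from [60, 80] with internal Gaussian texture; a hypodense rim (width 4 mm,
contrast −10) surrounds the lesion, and the rim/lesion texture SD is drawn
per case from [0.5, 6] — this is the "peri-lesional texture" covariate.
The mask is reduced to its largest 26-connected component.

Outcomes are generated from three standardised planted covariates —
rasterised volume, irregularity amplitude, texture SD, each scaled to unit
variance under its uniform sampling range:

* poor outcome: P(mRS > 3) = expit(logit(0.365) + c·z) with default
  c = (1.8, 1.2, 1.2). The intercept is the logit prevalence at covariate
  means; the marginal prevalence is slightly higher (~0.43) because the
  logistic is averaged over the covariate distribution. The coefficient
  norm ‖c‖ ≈ 2.5 puts the Bayes AUC of the true linear predictor near 0.90,
  leaving headroom for feature-measurement noise while keeping the task
  non-trivial. mRS is drawn uniformly from {4..6} given a poor outcome and
  {0..3} otherwise, so mRS > 3 and the label coincide by construction.
* growth: follow-up volume = baseline × exp(g), g ~ N(0.05 + d·z, 0.25²)
  with d = (0.15, 0.10, 0.10). Expansion labels threshold the difference at
  >3/>6/>9 mL, so their probabilities have closed normal-tail forms used as
  a Monte-Carlo oracle in tests. Only the scalar follow-up volume is
  generated; no second image is rasterised.

All randomness derives from one cohort seed through counter-based
`SeedSequence` spawning, so any case is reproducible independently of
cohort size.

What the phantoms do **not** emulate: skull/ventricle anatomy, partial
volume and beam-hardening artifacts, multi-focal hemorrhage, scanner
protocol variation, and any covariate the label model does not contain.
Passing the recovery study therefore shows the pipeline can extract and use
shape/texture signal it is known to contain — not that the same AUCs would
be obtained on clinical data.

## Preprocessing and segmentation network

Volumes are clipped to the [0, 100] window (a soft-tissue analogue),
z-scored with the in-window mean/SD (constant input maps to zeros), and
resampled trilinearly (masks: nearest-neighbour) to the network grid.

The segmentation model is a dual-resolution U-shaped network: two parallel
encoders ingest the full-resolution volume and its 2× average-pooled
half-resolution version (the downsampling operator is the package's choice).
Each encoder level is conv(3³)–instance-norm–leaky-ReLU followed by 2×
average pooling; channels double per level up to `bottleneck_channels`.
The half-resolution bottleneck is nearest-upsampled and fused with the
full-resolution bottleneck by a 1-level conv block; the decoder mirrors the
full-resolution encoder with nearest-upsampling and skip concatenation.
1×1×1 heads emit the full-resolution logit map plus `deep_supervision_levels`
coarser outputs. At reference scale (128³/64³ inputs, depth 4, 512
channels) the bottlenecks are (512, 8, 8, 8) and (512, 4, 4, 4).

Training minimises w_dice·softDice + w_ce·BCE summed over supervision
outputs with per-level weights halving by depth (normalised). Soft Dice
uses ε = 1e-5 in numerator and denominator for empty-mask stability; coarse
targets are average-pooled soft masks. Both Adam (default, lr 3e-3) and
SGD with momentum and polynomial decay are provided; Adam is the default
because it converges within a few epochs at desk scale. Empty-vs-empty
Dice is defined as 1.0. All parameters are initialised from a seeded
generator and training is pure numpy, so identical seeds give bit-identical
loss histories.

The networks run on a small reverse-mode autodiff engine
(`latentrad.nn`): float32 arrays, im2col-based 3D convolution, and exactly
the operations the architectures need. Gradients are verified against
finite differences in the test suite.

## Radiomics

Gray levels are discretised with a fixed bin width (default 5 intensity
units) anchored at the ROI minimum. GLCM features accumulate symmetric
co-occurrence counts over the 13 unique 3D offsets at distance 1, normalise
per direction, and average feature values over directions (matrices are not
merged); GLRLM runs are maximal equal-level sequences along the same 13
directions, restricted to the mask. Constant regions use the documented
conventions contrast = 0, correlation = 1, entropy = 0. The shape set is
exactly 14 features; surface area and mesh volume come from a marching-cubes
iso-surface at level 0.5 after a light Gaussian pre-smoothing of the binary
mask (σ = 0.7 voxel). The smoothing suppresses the staircase bias of
binary-mask triangulations (a digital ball otherwise reads ~9% too much
area, sphericity 0.92 instead of ≈1); with it, ball sphericity is ≈0.99 and
mesh volume is within 1% of the voxel count. Filtered variants recompute
the intensity/texture families on Laplacian-of-Gaussian responses (σ = 2
and 4 mm, spacing-aware) and on the 8 subbands of a level-1 decimated
`coif1` wavelet transform (mask down-sampled by stride 2 to the subband
grid). The default inventory is 311 features per case (14 shape + 27
base intensity/texture + 10 filtered images × 27); the exact emitted list
is fixed by `RadiomicsConfig` so downstream factorization is well defined.

## Latent features

Segmentation latents are the two encoder bottleneck tensors, flattened
channel-major. Autoencoder latents come from a VAE (optional non-saturating
adversarial branch, disabled by default for CPU stability) trained to
reconstruct lesion patches: the predicted mask is dilated with a 5×5×5
cubic structuring element ("size 5" is read as the element's edge length),
the dilated bounding box is padded to a cube, resampled to the patch shape
(64³ at reference scale, 16³ desk) and zeroed outside the dilated mask.
The VAE loss is w_recon·L1 + w_kl·KL(q‖N(0,I)) + w_adv·adversarial with
defaults (1, 1e-4, 0); extraction always uses the latent *mean* map, so
repeated extraction is exactly deterministic. No outcome labels touch
either network.

## Reduction and input assembly

Each family is reduced by Lee–Seung multiplicative-update NMF (Frobenius
objective, seeded uniform(0.1, 1] init), fit on training rows only; the
per-iteration objective is recorded and is non-increasing by construction,
which the tests assert. Before factorization, columns are shifted by their
negative training minima (test rows clipped at 0) and divided by their
training maxima. The unit-max scaling is needed because raw radiomics
scales span ~10 orders of magnitude (energy vs sphericity) and an unscaled
Frobenius objective would fit only the largest columns; both statistics are
estimated from training rows only, so no test-case information leaks.
Transforming new rows runs multiplicative updates on the scores with the
basis frozen.

The two segmentation-encoder sources are factorized separately at k/2
components each and concatenated, so "segmentation latents" has width k —
consistent with reducing each of the three numbered feature sets to the
same dimension (128 at reference scale; the combined latent vector stays
under 300). A `joint` switch fits one NMF at k on the concatenated raw
matrices instead. The seven input configurations have widths k, 14
(shape enters un-reduced, since reduction to more dimensions than inputs is
ill-posed), k, k, 2k, 3k and 14 + 2k.

## Classifier grid and evaluation

Classifiers: random forest, XGBoost and extra trees (1000 estimators at
reference scale; desk studies use 100–150), Gaussian naive Bayes,
elastic-net logistic regression (l1_ratio 0.5, saga solver, feature
standardisation), and an RBF-kernel SVM whose AUC uses the raw decision
function while threshold metrics use a Platt-style logistic fit of the
training decision values. Unstated hyperparameters follow the backing
implementations' defaults and are captured per spec snapshot. Folds are
stratified per outcome; every data-dependent transformation (shift, scale,
NMF) is re-fit inside each training fold, and a leakage guard raises if any
fit set intersects its evaluation set. AUC is the Mann–Whitney rank
statistic with ties counted ½; PPV/NPV with undefined denominators are
reported missing, never 0; the confusion-table threshold is pinned at 0.5.
Calibration curves use quantile bins with the Brier score; decision curves
report net benefit TP/n − (FP/n)·pt/(1−pt) against treat-all/treat-none.

Group-level attribution is a grouped permutation importance: the mean AUC
drop over R seeded joint permutations of a feature family's columns,
floored at zero. It is model-agnostic and seedable; it is not an exact
Shapley decomposition, and with correlated families it attributes shared
signal to the family the fitted model actually relies on.

## Statistics

The comparison cascade is Shapiro–Wilk (gate), Friedman omnibus over
pipelines (blocks = classifiers by default; a `folds` blocking is exposed
because either reading is defensible), then pairwise Wilcoxon signed-rank
tests with Bonferroni, Holm and Benjamini–Hochberg corrections. The
Wilcoxon exact path (enumeration over sign assignments) is used for n ≤ 15
without ties, otherwise the normal approximation with continuity
correction. Cohort tables use chi-square tests — Yates-corrected for 2×2,
which reproduces the reference table's printed p-values (0.020, 0.010) from
its counts, where the uncorrected test does not — and pooled-variance t
tests from summaries (Welch optional). Paired AUC differences use the
DeLong covariance method, cross-checked against a paired bootstrap in the
tests. A null simulation verifies the family-wise error of the full
cascade stays near the nominal level.

## Desk-scale study sizes

The acceptance studies use sizes chosen to exercise every stage faithfully
on one CPU: signal recovery on a 500-case training cohort (150 held-out)
with a 32³ segmentation network (depth 3, 64 bottleneck channels), 16³
autoencoder patches, k = 16 NMF components and 150-tree ensembles; the
segmentation study trains 24³ multiscale and single-scale networks (depth
2) on 12 easy phantoms and evaluates on 8. Reference-scale geometry is
validated by shape arithmetic (`dry_run`) without training.

## Known limitations

* The autodiff engine is minimal by design: stride-1 same-padded
  convolutions, nearest upsampling, no GPU, no mixed precision; reference-
  scale (128³) training is out of its intended envelope.
* Phantom realism is limited to what the label model plants (see above);
  absolute AUCs on phantoms are not comparable to clinical values.
* The GLCM/GLRLM inventory is a representative subset, not the full
  ~1700-feature catalogue of large radiomics toolkits; gray-level size-zone
  and dependence matrices are out of scope.
* Hematoma expansion is defined as the absolute follow-up − baseline
  difference; relative definitions are not implemented.
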
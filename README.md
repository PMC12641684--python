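# latentrad

Handcrafted radiomics versus latent deep features for predicting
hemorrhagic-stroke outcomes from head CT — implemented as a fully synthetic,
reproducible pipeline.

## The problem

After spontaneous intracerebral hemorrhage (ICH), two early endpoints drive
clinical decisions: hematoma expansion on the ~24 h follow-up CT (binarised
at >3, >6 and >9 mL growth) and poor 3-month functional outcome (modified
Rankin Scale > 3). Both can be predicted, imperfectly, from the admission
non-contrast CT. Two families of image features compete for this job:

* **handcrafted radiomics** — fixed formulas on the segmented lesion: shape
  (volume, surface area, sphericity = pi^(1/3)(6V)^(2/3)/A, axis lengths),
  first-order intensity statistics, gray-level co-occurrence (GLCM) and
  run-length (GLRLM) texture matrices, plus Laplacian-of-Gaussian and
  wavelet-filtered variants;
* **latent deep features** — bottleneck activations of (i) a dual-resolution
  U-shaped segmentation network and (ii) a variational autoencoder (optional
  adversarial branch) trained to reconstruct dilated-mask lesion patches.

Each family is reduced by non-negative matrix factorization (X ~ WH, W,H >= 0,
multiplicative updates, fit on training folds only), assembled into seven
input configurations (radiomics, shape-only, each latent set, and their
combinations), and fed to six classifiers (random forest, XGBoost, Gaussian
naive Bayes, extra trees, elastic-net logistic regression, RBF-SVM) for each
of the four outcomes, under stratified 5-fold cross-validation plus a
held-out test cohort. Pipelines are compared with a Friedman omnibus test
and pairwise Wilcoxon signed-rank tests under Bonferroni / Holm /
Benjamini-Hochberg correction.

Clinical CT cohorts are not redistributable, so the package ships a phantom
generator that emulates their statistical structure: hyperdense
spherical-harmonic-perturbed ellipsoidal lesions (1–40 mL, 60–80 intensity
units on a noisy ~30-unit background, hypodense edema rim) whose outcome
labels depend, through a logistic model, on planted lesion volume, surface
irregularity and peri-lesional texture — so the whole pipeline can be
validated end-to-end on signal it is known to contain.

## Worked example

```python
from latentrad import ExperimentConfig, run_experiment
from latentrad.segmentation import MultiscaleNetConfig
from latentrad.latent import VAEGANConfig

cfg = ExperimentConfig(
    n_train=40, n_test=20, n_seg_train=8, n_seg_val=4, seg_epochs=3,
    nmf_k=4, nmf_iters=60, n_estimators=10, n_folds=3,
    net=MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=4,
                            depth=2, bottleneck_channels=16,
                            deep_supervision_levels=1),
    vaegan=VAEGANConfig(patch_shape=(8,) * 3, latent_channels=8,
                        depth=1, epochs=3),
    outcomes=("poor_outcome", "exp3"), seed=1)

result = run_experiment(cfg)
print(result.grid.summary().round(3))
print("median held-out Dice:", round(result.seg_dice["median"], 3))
print(result.attribution)
```

prints (toy scale, ~20 s):

```
outcome             exp3  poor_outcome
configuration
latent_seg         0.721         0.742
latent_seg+vaegan  0.642         0.705
latent_vaegan      0.358         0.481
radiomics+latents  0.664         0.690
radiomics_all      0.702         0.713
radiomics_shape    0.853         0.771
shape+latents      0.777         0.781
median held-out Dice: 0.66
           group  importance
0      radiomics       0.118
1     seg_latent       0.080
2  vaegan_latent       0.073
```

Each number in the table is the mean test-split AUC of the six classifiers
for that input configuration and outcome; the attribution table is the
grouped permutation importance (mean AUC drop when a family's columns are
jointly permuted) of the combined model. At this toy scale the AUCs are
noisy; the desk-scale studies below use 500-case cohorts.

At reference scale the architecture realises the full clinical-sized
geometry (checked without training): encoder bottlenecks (512, 8, 8, 8) and
(512, 4, 4, 4) for 128³/64³ inputs, 64³ autoencoder patches with a
(512, 4, 4, 4) latent mean map, and NMF to 128 components per family.

```bash
latentrad synth --n 100 --seed 7 --out cohort/     # NIfTI phantoms + CSV
latentrad run --config experiment.yaml --out results/
latentrad run --config experiment.yaml --dry-run   # shape validation only
```

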
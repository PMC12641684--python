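"""End-to-end experiment driver: one config, one seed, one reproducible run.

Ties the stages together: synthesise training and test cohorts, train the
segmentation network and the autoencoder, extract radiomics and latent
features, reduce with NMF inside each training fold, run the classifier
grid over the seven input configurations and four outcomes, and apply the
omnibus/post-hoc statistics.  A manifest of content hashes of every
intermediate makes reruns verifiable: the same config and seed reproduce
the manifest exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureBlock
from .latent import VAEGANConfig, extract_latents, make_patch, train_vaegan
from .modeling import (OUTCOMES, ResultGrid, default_classifier_specs,
                       group_attribution, run_grid)
from .radiomics import RadiomicsConfig, cohort_features
from .reduction import INPUT_CONFIGURATION_NAMES
from .segmentation import (MultiscaleNetConfig, build_multiscale_unet,
                           dice_coefficient, predict_mask, prepare_case,
                           train_segmentation)
from .stats import pipeline_comparison
from .synthetic import (LabelModel, PhantomConfig, assign_labels,
                        cohort_manifest, generate_cohort)
from .volume import LesionMask

logger = logging.getLogger(__name__)


def _stage_seed(master: int, stage: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(int(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class ExperimentConfig:
    """Full experiment description; round-trips losslessly through YAML."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    net: MultiscaleNetConfig = field(default_factory=MultiscaleNetConfig)
    vaegan: VAEGANConfig = field(default_factory=VAEGANConfig)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    label_model: LabelModel = field(default_factory=LabelModel)
    nmf_k: int = 16
    nmf_iters: int = 150
    n_train: int = 200
    n_test: int = 100
    n_seg_train: int = 16
    n_seg_val: int = 6
    seg_epochs: int = 12
    n_estimators: int = 100
    n_folds: int = 5
    outcomes: tuple = OUTCOMES
    config_names: tuple = tuple(INPUT_CONFIGURATION_NAMES)
    dilation_size: int = 5
    seg_nmf_joint: bool = False
    use_predicted_masks: bool = False
    seed: int = 0
    scale: str = "desk"

    def __post_init__(self):
        if self.scale not in ("desk", "reference"):
            raise ValueError("scale must be 'desk' or 'reference'")
        self.outcomes = tuple(self.outcomes)
        self.config_names = tuple(self.config_names)
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes {unknown}")
        unknown = set(self.config_names) - set(INPUT_CONFIGURATION_NAMES)
        if unknown:
            raise ValueError(f"unknown configurations {unknown}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sub = dict(phantom=PhantomConfig, net=MultiscaleNetConfig,
                   vaegan=VAEGANConfig, radiomics=RadiomicsConfig,
                   label_model=LabelModel)
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                kwargs = {k: tuple(v) if isinstance(v, list) else v
                          for k, v in d[key].items()}
                d[key] = typ(**kwargs)
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def reference_scale_config() -> ExperimentConfig:
    """Reference-scale geometry (for shape validation, not CPU training)."""
    return ExperimentConfig(
        phantom=PhantomConfig(grid_shape=(128,) * 3, spacing_mm=(1.0,) * 3,
                              lesion_volume_range_ml=(1.0, 60.0)),
        net=MultiscaleNetConfig(full_res_shape=(128,) * 3, base_channels=32,
                                depth=4, bottleneck_channels=512,
                                deep_supervision_levels=2),
        vaegan=VAEGANConfig(patch_shape=(64,) * 3, latent_channels=512, depth=4),
        nmf_k=128, n_estimators=1000, scale="reference")


def dry_run(cfg: ExperimentConfig) -> dict:
    """Validate every cross-constraint without computation.

    Returns the derived shapes (bottlenecks, latent tensor, widths) so
    callers can assert reference-scale arithmetic such as (512, 8, 8, 8) /
    (512, 4, 4, 4) bottlenecks and 64^3 patches.
    """
    net = cfg.net
    shapes = dict(
        bottleneck_full=net.bottleneck_shape_full,
        bottleneck_half=net.bottleneck_shape_half,
        vae_patch=cfg.vaegan.patch_shape,
        vae_latent=cfg.vaegan.latent_shape,
    )
    widths = dict(
        radiomics_all=cfg.nmf_k, radiomics_shape=14, latent_seg=cfg.nmf_k,
        latent_vaegan=cfg.nmf_k, **{"latent_seg+vaegan": 2 * cfg.nmf_k},
        **{"radiomics+latents": 3 * cfg.nmf_k},
        **{"shape+latents": 14 + 2 * cfg.nmf_k},
    )
    # NMF needs at least k training rows per fold
    min_fold_train = cfg.n_train * (cfg.n_folds - 1) // cfg.n_folds
    if cfg.nmf_k > min_fold_train:
        raise ValueError(f"nmf_k={cfg.nmf_k} exceeds fold training size {min_fold_train}")
    if cfg.n_seg_train + cfg.n_seg_val > cfg.n_train:
        raise ValueError("segmentation train+val exceeds the training cohort")
    return dict(shapes=shapes, widths=widths)


def _sha(arr) -> str:
    if isinstance(arr, pd.DataFrame):
        data = arr.to_csv(index=False).encode()
    else:
        data = np.ascontiguousarray(np.asarray(arr)).tobytes()
    return hashlib.sha256(data).hexdigest()


@dataclass
class ExperimentResult:
    grid: ResultGrid
    stats: dict
    seg_dice: dict
    attribution: pd.DataFrame
    labels: pd.DataFrame
    manifest: dict
    raw_blocks: dict
    wall_times: dict


def _feature_stages(cfg: ExperimentConfig):
    """Cohort synthesis, network training and feature extraction stages.

    Returns ``(raw_blocks, labels, seg_dice, times)``; ``raw_blocks`` holds
    the un-reduced radiomics/shape/latent FeatureBlocks covering the whole
    (train + test) cohort.
    """
    dry_run(cfg)
    if cfg.scale == "reference":
        raise ValueError("reference-scale configs validate shapes only; use dry_run")
    times: dict = {}
    t0 = time.time()

    # --- cohorts ---------------------------------------------------------
    train_cases = generate_cohort(cfg.phantom, cfg.n_train, cfg.label_model,
                                  seed=_stage_seed(cfg.seed, 0), id_prefix="train")
    test_cases = generate_cohort(cfg.phantom, cfg.n_test, cfg.label_model,
                                 seed=_stage_seed(cfg.seed, 1), id_prefix="test")
    all_cases = train_cases + test_cases
    labels = cohort_manifest(all_cases).set_index("case_id")
    train_ids = [c.case_id for c in train_cases]
    test_ids = [c.case_id for c in test_cases]
    times["synth"] = time.time() - t0
    logger.info("stage=synth n=%d+%d seed=%d wall=%.1fs", cfg.n_train, cfg.n_test,
                cfg.seed, times["synth"])

    # --- segmentation ----------------------------------------------------
    t0 = time.time()
    seg_train = train_cases[:cfg.n_seg_train]
    seg_val = train_cases[cfg.n_seg_train:cfg.n_seg_train + cfg.n_seg_val]
    seg_model = build_multiscale_unet(cfg.net, seed=_stage_seed(cfg.seed, 2))
    train_segmentation(seg_model, seg_train, epochs=cfg.seg_epochs,
                       seed=_stage_seed(cfg.seed, 3))
    dices = []
    for c in seg_val:
        pred = predict_mask(seg_model, c.image)
        _, t = prepare_case(c.image, cfg.net, c.mask)
        dices.append(dice_coefficient(pred, LesionMask(t[0] > 0.5, (1.0,) * 3)))
    seg_dice = dict(median=float(np.median(dices)), per_case=dices)
    times["segmentation"] = time.time() - t0
    logger.info("stage=segmentation median_dice=%.3f wall=%.1fs",
                seg_dice["median"], times["segmentation"])

    # --- VAE(-GAN) -------------------------------------------------------
    t0 = time.time()
    patches = [make_patch(c, dilation_size=cfg.dilation_size,
                          out_shape=cfg.vaegan.patch_shape) for c in seg_train]
    vae_cfg = dataclasses.replace(cfg.vaegan, seed=_stage_seed(cfg.seed, 4))
    vae_model = train_vaegan(patches, vae_cfg)
    times["vaegan"] = time.time() - t0
    logger.info("stage=vaegan final_loss=%.4f wall=%.1fs",
                vae_model.loss_history[-1], times["vaegan"])

    # --- features --------------------------------------------------------
    t0 = time.time()
    masks = None
    if cfg.use_predicted_masks:
        masks = [predict_mask(seg_model, c.image) for c in all_cases]
    radiomics_block = cohort_features(all_cases, cfg.radiomics, masks=masks)
    shape_cols = [i for i, n in enumerate(radiomics_block.names)
                  if n.startswith("shape_")]
    shape_block = FeatureBlock(
        names=[radiomics_block.names[i] for i in shape_cols],
        matrix=radiomics_block.matrix[:, shape_cols], family="shape",
        case_ids=list(radiomics_block.case_ids))
    times["radiomics"] = time.time() - t0

    t0 = time.time()
    seg_latents = extract_latents(seg_model, all_cases)
    vae_latents = extract_latents(vae_model, all_cases,
                                  dilation_size=cfg.dilation_size)
    raw_blocks = dict(radiomics=radiomics_block, shape=shape_block,
                      seg_full=seg_latents["seg_full"],
                      seg_half=seg_latents.get("seg_half", seg_latents["seg_full"]),
                      vaegan=vae_latents["vaegan"])
    times["latents"] = time.time() - t0
    logger.info("stage=features radiomics=%d latents=%s wall=%.1fs",
                radiomics_block.n_features,
                {k: v.n_features for k, v in raw_blocks.items()},
                times["radiomics"] + times["latents"])
    return raw_blocks, labels, seg_dice, times


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Execute synth -> segmentation -> features -> NMF -> grid -> stats."""
    raw_blocks, labels, seg_dice, times = _feature_stages(cfg)
    train_ids = [c for c in labels.index if c.startswith("train")]
    test_ids = [c for c in labels.index if c.startswith("test")]
    radiomics_block = raw_blocks["radiomics"]

    # --- classifier grid -------------------------------------------------
    t0 = time.time()
    specs = default_classifier_specs(seed=_stage_seed(cfg.seed, 5),
                                     n_estimators=cfg.n_estimators)
    grid = run_grid(raw_blocks, labels, train_ids, test_ids, specs=specs,
                    outcomes=cfg.outcomes, k=cfg.nmf_k, n_folds=cfg.n_folds,
                    nmf_iters=cfg.nmf_iters, seed=_stage_seed(cfg.seed, 6),
                    config_names=cfg.config_names, seg_joint=cfg.seg_nmf_joint)
    times["grid"] = time.time() - t0
    logger.info("stage=grid cells=%d wall=%.1fs", len(grid.rows), times["grid"])

    # --- statistics ------------------------------------------------------
    t0 = time.time()
    stats_results = {}
    for outcome in cfg.outcomes:
        df = grid.to_frame()
        cv = df[(df.split == "cv") & (df.outcome == outcome)]
        mat = cv.pivot_table(index="classifier", columns="configuration",
                             values="auc", aggfunc="mean")
        if mat.shape[0] >= 2 and mat.shape[1] >= 2:
            stats_results[outcome] = pipeline_comparison(mat)
    times["stats"] = time.time() - t0

    # --- grouped attribution on the combined configuration ---------------
    t0 = time.time()
    attribution = _attribution(cfg, raw_blocks, labels, train_ids, test_ids,
                               seed=_stage_seed(cfg.seed, 7))
    times["attribution"] = time.time() - t0

    manifest = dict(
        config=cfg.to_dict(),
        labels=_sha(labels.reset_index()),
        radiomics=_sha(radiomics_block.matrix),
        seg_full=_sha(raw_blocks["seg_full"].matrix),
        vaegan=_sha(raw_blocks["vaegan"].matrix),
        grid=_sha(grid.to_frame().drop(columns=["fold"]).fillna(-1)),
    )
    result = ExperimentResult(grid=grid, stats=stats_results, seg_dice=seg_dice,
                              attribution=attribution, labels=labels,
                              manifest=manifest, raw_blocks=raw_blocks,
                              wall_times=times)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _attribution(cfg, raw_blocks, labels, train_ids, test_ids, seed):
    """Grouped permutation importance of {radiomics, seg, vaegan} on the
    combined configuration, using an extra-trees model and the test split."""
    from .modeling import ClassifierSpec, _reduced_configs

    if "radiomics+latents" not in cfg.config_names:
        return pd.DataFrame()
    cache: dict = {}
    all_ids = list(train_ids) + list(test_ids)
    configs = _reduced_configs(raw_blocks, all_ids, list(train_ids),
                               cfg.nmf_k, cfg.nmf_iters, seed, cache)
    config = next(c for c in configs if c.name == "radiomics+latents")
    X = config.matrix()
    groups = {}
    for i, name in enumerate(X.names):
        if name.startswith("radiomics"):
            groups.setdefault("radiomics", []).append(i)
        elif name.startswith(("seg_full", "seg_half")):
            groups.setdefault("seg_latent", []).append(i)
        else:
            groups.setdefault("vaegan_latent", []).append(i)
    spec = ClassifierSpec("ExtraTrees", {"n_estimators": cfg.n_estimators}, seed)
    est = spec.build()
    est.fit(X.subset(list(train_ids)).matrix,
            labels.loc[list(train_ids), "poor_outcome"].to_numpy().astype(int))
    return group_attribution(
        est, X.subset(list(test_ids)).matrix,
        labels.loc[list(test_ids), "poor_outcome"].to_numpy().astype(int),
        groups, seed=seed)


def signal_recovery_study(seed: int = 0, n_train: int = 500, n_test: int = 150,
                          n_estimators: int = 150, k: int = 16,
                          nmf_iters: int = 100, with_permuted: bool = True) -> dict:
    """Planted-signal recovery on a desk-scale cohort.

    Generates a cohort whose poor-outcome label depends on lesion volume,
    surface irregularity and peri-lesional texture; trains the segmentation
    network and autoencoder; extracts radiomics and latents; and
    cross-validates the tree-ensemble classifiers on the combined
    radiomics+latents input.  Returns cross-validated AUCs, the same AUCs
    under label permutation (null calibration), and the grouped attribution
    ranking.
    """
    from .modeling import ClassifierSpec

    cfg = ExperimentConfig(
        n_train=n_train, n_test=n_test, nmf_k=k, nmf_iters=nmf_iters,
        n_estimators=n_estimators, seg_epochs=10, n_seg_train=16, n_seg_val=6,
        outcomes=("poor_outcome",), config_names=("radiomics+latents",),
        seed=seed)
    raw_blocks, labels, seg_dice, _times = _feature_stages(cfg)
    train_ids = [c for c in labels.index if c.startswith("train")]
    test_ids = [c for c in labels.index if c.startswith("test")]

    specs = [ClassifierSpec(nm, {"n_estimators": n_estimators},
                            _stage_seed(seed, 5))
             for nm in ("RF", "XGBoost", "ExtraTrees")]
    cache: dict = {}
    grid = run_grid(raw_blocks, labels, train_ids, test_ids, specs=specs,
                    outcomes=("poor_outcome",), k=k, nmf_iters=nmf_iters,
                    seed=_stage_seed(seed, 6), config_names=("radiomics+latents",),
                    reduction_cache=cache)
    cv_auc = {s.name: float(np.mean(grid.cv_fold_aucs("radiomics+latents",
                                                      s.name, "poor_outcome")))
              for s in specs}

    permuted_auc = {}
    if with_permuted:
        rng = np.random.default_rng(_stage_seed(seed, 8))
        perm_labels = labels.copy()
        perm_labels["poor_outcome"] = rng.permutation(
            perm_labels["poor_outcome"].to_numpy())
        pgrid = run_grid(raw_blocks, perm_labels, train_ids, test_ids,
                         specs=specs, outcomes=("poor_outcome",), k=k,
                         nmf_iters=nmf_iters, seed=_stage_seed(seed, 6),
                         config_names=("radiomics+latents",),
                         reduction_cache=cache)
        permuted_auc = {s.name: float(np.mean(pgrid.cv_fold_aucs(
            "radiomics+latents", s.name, "poor_outcome"))) for s in specs}

    attribution = _attribution(cfg, raw_blocks, labels, train_ids, test_ids,
                               seed=_stage_seed(seed, 7))
    return dict(cv_auc=cv_auc, permuted_auc=permuted_auc,
                attribution=attribution, seg_dice=seg_dice,
                labels=labels, grid=grid)


def segmentation_study(seed: int = 0, n_train: int = 12, n_val: int = 8,
                       epochs: int = 15) -> dict:
    """Held-out Dice of the multiscale and single-scale networks.

    Easy phantoms (high contrast, mild irregularity) at desk scale; returns
    the median held-out Dice per architecture and the loss histories.
    """
    phantom = PhantomConfig(
        grid_shape=(24,) * 3, spacing_mm=(2.5,) * 3,
        lesion_volume_range_ml=(4.0, 25.0), irregularity=0.10,
        background_noise_sd=2.0, rim_noise_sd_range=(0.5, 2.0))
    cases = generate_cohort(phantom, n_train + n_val, LabelModel(),
                            seed=_stage_seed(seed, 10))
    train, val = cases[:n_train], cases[n_train:]
    out = {}
    for name, single in (("multiscale", False), ("single_scale", True)):
        net_cfg = MultiscaleNetConfig(full_res_shape=(24,) * 3, base_channels=4,
                                      depth=2, bottleneck_channels=32,
                                      deep_supervision_levels=1,
                                      single_scale=single)
        model = build_multiscale_unet(net_cfg, seed=_stage_seed(seed, 11))
        state = train_segmentation(model, train, epochs=epochs,
                                   seed=_stage_seed(seed, 12))
        dices = []
        for c in val:
            pred = predict_mask(model, c.image)
            _, t = prepare_case(c.image, net_cfg, c.mask)
            dices.append(dice_coefficient(pred, LesionMask(t[0] > 0.5, (1.0,) * 3)))
        out[name] = dict(median_dice=float(np.median(dices)), dices=dices,
                         loss_history=state.loss_history)
    return out


def _write_outputs(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.grid.to_csv(out / "result_grid.csv")
    result.labels.to_csv(out / "labels.csv")
    if len(result.attribution):
        result.attribution.to_csv(out / "attribution.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    from .stats import write_stats_report

    write_stats_report(result.stats, out / "stats_report.md")
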
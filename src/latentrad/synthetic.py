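"""Synthetic pseudo-CT phantom cohorts with planted outcome signal.

Real admission head-CT cohorts for intracerebral hemorrhage are not publicly
available, so this module emulates their statistical structure: hyperdense,
roughly ellipsoidal hematomas (about 50-80 intensity units above brain-like
background) of 1-60 mL on a noisy parenchyma background, an optional
hypodense peri-lesional edema rim, per-case baseline and follow-up volumes
defining hematoma-expansion labels at >3 / >6 / >9 mL, and a 3-month
poor-outcome label (modified Rankin Scale > 3) whose probability depends on
lesion volume, surface irregularity, and peri-lesional texture.

Lesions are spherical-harmonic-perturbed ellipsoids rasterised on the voxel
grid; follow-up volume comes from a lognormal growth factor applied to the
rasterised baseline volume.  All randomness flows from one cohort seed via a
counter-based per-case derivation, so any subset of a cohort is reproducible
bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special
from scipy.special import expit, logit

from .volume import ImageVolume, LesionMask


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the phantom generator.

    Defaults follow the cohort the generator emulates: background parenchyma
    near 30 intensity units, hematomas 60-80, a slightly hypodense edema rim,
    and baseline volumes spanning about 1-40 mL on a grid large enough to
    hold the largest lesion plus its rim.
    """

    grid_shape: tuple = (32, 32, 32)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    background_level: float = 30.0
    background_noise_sd: float = 3.0
    lesion_intensity_range: tuple = (60.0, 80.0)
    lesion_volume_range_ml: tuple = (1.0, 40.0)
    irregularity: float = 0.25
    edema_rim_width_mm: float = 4.0
    rim_contrast: float = -10.0
    lesion_noise_sd: float = 2.0
    rim_noise_sd_range: tuple = (0.5, 6.0)
    axis_ratio_range: tuple = (0.6, 1.0)

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        for name in ("lesion_intensity_range", "lesion_volume_range_ml",
                     "rim_noise_sd_range", "axis_ratio_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must be in [0, 1]")
        # the largest lesion plus rim must fit inside the grid
        vmax = self.lesion_volume_range_ml[1]
        r_mm = (3.0 * vmax * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        r_mm = r_mm * (1.0 + 0.6 * self.irregularity) + self.edema_rim_width_mm
        half_extent = min(g * s / 2.0 for g, s in zip(self.grid_shape, self.spacing_mm))
        if r_mm >= half_extent:
            raise ValueError(
                f"max lesion radius {r_mm:.1f} mm (incl. rim) does not fit in a grid of "
                f"half-extent {half_extent:.1f} mm"
            )


@dataclass
class LabelModel:
    """Logistic outcome model and lognormal growth model with planted signal.

    ``poor_coefs`` are the logistic coefficients of poor outcome (mRS > 3) on
    the standardised planted covariates (lesion volume, surface irregularity
    amplitude, peri-lesional texture noise SD).  ``poor_intercept`` is the
    logit prevalence at covariate means.  Follow-up volume is
    ``baseline * exp(g)`` with ``g ~ Normal(growth_mu + growth_coefs . z,
    growth_sd)``, so expansion probabilities have a closed normal-tail form.
    """

    poor_intercept: float = float(logit(0.365))
    poor_coefs: tuple = (1.8, 1.2, 1.2)
    growth_mu: float = 0.05
    growth_coefs: tuple = (0.15, 0.10, 0.10)
    growth_sd: float = 0.25

    def poor_probability(self, z: np.ndarray) -> float:
        """P(mRS > 3) given standardised covariates ``z``."""
        return float(expit(self.poor_intercept + np.dot(self.poor_coefs, z)))

    def growth_mean(self, z: np.ndarray) -> float:
        return float(self.growth_mu + np.dot(self.growth_coefs, z))

    def expansion_probability(self, baseline_ml: float, z: np.ndarray,
                              threshold_ml: float) -> float:
        """Closed-form P(follow-up - baseline > threshold) under the model.

        With log growth factor g ~ N(mu(z), sd), expansion beyond t mL occurs
        iff g > log(1 + t / baseline); the probability is the normal tail.
        """
        if baseline_ml <= 0:
            return 0.0
        cut = np.log1p(threshold_ml / baseline_ml)
        zscore = (cut - self.growth_mean(z)) / self.growth_sd
        return float(special.ndtr(-zscore))


@dataclass
class SyntheticCase:
    """One phantom: image, ground-truth mask, volumes, outcome and provenance."""

    image: ImageVolume
    mask: LesionMask
    baseline_volume_ml: float
    followup_volume_ml: float
    mrs: int
    case_id: str
    seed: int
    planted: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= int(self.mrs) <= 6:
            raise ValueError("mrs must be in [0, 6]")
        self.mrs = int(self.mrs)


@dataclass
class OutcomeLabels:
    """Binary endpoints: poor 3-month outcome and nested expansion thresholds."""

    poor_outcome: int
    exp3: int
    exp6: int
    exp9: int

    def __post_init__(self):
        if not (self.exp9 <= self.exp6 <= self.exp3):
            raise ValueError("expansion labels must nest: exp9 <= exp6 <= exp3")


EXPANSION_THRESHOLDS_ML = (3.0, 6.0, 9.0)


def assign_labels(case: SyntheticCase) -> OutcomeLabels:
    """Derive the four binary endpoints from a case.

    Expansion at threshold k is (follow-up - baseline) > k mL; poor outcome
    is mRS > 3.
    """
    if case.baseline_volume_ml < 0 or case.followup_volume_ml < 0:
        raise ValueError("volumes must be nonnegative")
    growth = case.followup_volume_ml - case.baseline_volume_ml
    e3, e6, e9 = (int(growth > t) for t in EXPANSION_THRESHOLDS_ML)
    return OutcomeLabels(poor_outcome=int(case.mrs > 3), exp3=e3, exp6=e6, exp9=e9)


def _case_seed(cohort_seed: int, index: int) -> int:
    """Counter-based per-case seed derivation (stable across cohort sizes)."""
    ss = np.random.SeedSequence(entropy=int(cohort_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic basis (polar angle theta, azimuth phi)."""
    # scipy >= 1.15 renamed sph_harm to sph_harm_y with (l, m, theta, phi)
    if hasattr(special, "sph_harm_y"):
        y = special.sph_harm_y(l, abs(m), theta, phi)
    else:  # pragma: no cover - older scipy
        y = special.sph_harm(abs(m), l, phi, theta)
    if m > 0:
        return np.sqrt(2.0) * np.real(y)
    if m < 0:
        return np.sqrt(2.0) * np.imag(y)
    return np.real(y)


def _perturbation(rng: np.random.Generator, irregularity: float,
                  theta: np.ndarray, phi: np.ndarray, coefs=None):
    """Zero-mean angular radius perturbation from low-order harmonics."""
    if coefs is None:
        coefs = []
        for l in range(2, 5):
            for m in range(-l, l + 1):
                coefs.append((l, m, rng.normal(0.0, 1.0)))
    f = np.zeros_like(theta, dtype=float)
    for l, m, a in coefs:
        f += a * _real_sph_harm(l, m, theta, phi)
    # normalise so the perturbation amplitude is comparable across draws
    scale = np.sqrt(np.mean(np.square(f))) if np.any(f) else 1.0
    if scale > 0:
        f = f / scale
    return irregularity * f, coefs


def generate_phantom(config: PhantomConfig, seed: int, case_id: str | None = None,
                     label_model: LabelModel | None = None) -> SyntheticCase:
    """Generate one pseudo-CT phantom with ground-truth mask and outcome.

    The lesion is an ellipsoid with a zero-mean spherical-harmonic surface
    perturbation, rasterised on the voxel grid and reduced to its largest
    26-connected component.  The semi-axes are calibrated so the rasterised
    volume matches the drawn target volume; ``baseline_volume_ml`` is the
    exact rasterised volume.  Planted parameters (target volume,
    irregularity, rim texture SD, growth factor, mRS) are recorded under
    ``case.planted``.
    """
    rng = np.random.default_rng(seed)
    lm = label_model if label_model is not None else LabelModel()
    shape = config.grid_shape
    sp = np.asarray(config.spacing_mm)

    target_ml = rng.uniform(*config.lesion_volume_range_ml)
    lesion_level = rng.uniform(*config.lesion_intensity_range)
    rim_noise_sd = rng.uniform(*config.rim_noise_sd_range)
    # per-case surface irregularity up to the configured amplitude, so shape
    # carries between-case signal
    irregularity = rng.uniform(0.0, config.irregularity)
    ratios = np.array([1.0, rng.uniform(*config.axis_ratio_range),
                       rng.uniform(*config.axis_ratio_range)])

    # background parenchyma
    img = config.background_level + rng.normal(0.0, config.background_noise_sd, shape)

    mask = np.zeros(shape, dtype=bool)
    if target_ml > 0:
        # physical coordinates relative to a jittered centre
        centre_frac = 0.5 + rng.uniform(-0.05, 0.05, 3)
        centre = centre_frac * np.asarray(shape) * sp
        axes = [np.arange(n) * s + s / 2.0 for n, s in zip(shape, sp)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        dx, dy, dz = X - centre[0], Y - centre[1], Z - centre[2]

        # base semi-axes for the target volume at the drawn axis ratios
        r0 = (3.0 * target_ml * 1000.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
        semi = r0 * ratios

        u = np.stack([dx / semi[0], dy / semi[1], dz / semi[2]])
        rho = np.sqrt(np.sum(np.square(u), axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.where(rho > 0, u[2] / np.maximum(rho, 1e-12), 1.0), -1, 1))
            phi = np.arctan2(u[1], u[0])

        f, coefs = _perturbation(rng, irregularity, theta, phi)
        # calibrate: E[(1+f)^3] over the sphere rescales the target radius
        tg = np.linspace(0.0, np.pi, 32)
        pg = np.linspace(-np.pi, np.pi, 64, endpoint=False)
        TT, PP = np.meshgrid(tg, pg, indexing="ij")
        fg, _ = _perturbation(rng, irregularity, TT, PP, coefs=coefs)
        vol_factor = float(np.mean((1.0 + fg) ** 3 * np.sin(TT)) / np.mean(np.sin(TT)))
        radius_scale = vol_factor ** (-1.0 / 3.0)

        mask = rho <= radius_scale * (1.0 + f)
        if mask.any():
            lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
            if n > 1:
                sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
                mask = lab == (1 + int(np.argmax(sizes)))

    voxel_ml = float(np.prod(sp)) / 1000.0
    baseline_ml = mask.sum() * voxel_ml
    if target_ml > 0 and not mask.any():
        raise ValueError("lesion rasterised to an empty mask; enlarge the grid or lesion")

    rim = np.zeros(shape, dtype=bool)
    if mask.any() and config.edema_rim_width_mm > 0:
        dist = ndimage.distance_transform_edt(~mask, sampling=sp)
        rim = (dist > 0) & (dist <= config.edema_rim_width_mm)

    if mask.any():
        img[rim] = (config.background_level + config.rim_contrast
                    + rng.normal(0.0, rim_noise_sd, int(rim.sum())))
        img[mask] = lesion_level + rng.normal(
            0.0, config.lesion_noise_sd + rim_noise_sd, int(mask.sum()))

    # planted covariates, standardised against the config ranges
    z = _standardised_covariates(config, baseline_ml, irregularity, rim_noise_sd)
    p_poor = lm.poor_probability(z)
    poor = rng.uniform() < p_poor
    mrs = int(rng.integers(4, 7)) if poor else int(rng.integers(0, 4))

    g = rng.normal(lm.growth_mean(z), lm.growth_sd)
    followup_ml = baseline_ml * float(np.exp(g)) if baseline_ml > 0 else 0.0

    image = ImageVolume(img, tuple(sp))
    return SyntheticCase(
        image=image,
        mask=LesionMask(mask, tuple(sp)),
        baseline_volume_ml=float(baseline_ml),
        followup_volume_ml=float(followup_ml),
        mrs=mrs,
        case_id=case_id if case_id is not None else f"case_{seed:010d}",
        seed=int(seed),
        planted=dict(
            target_volume_ml=float(target_ml),
            lesion_level=float(lesion_level),
            rim_noise_sd=float(rim_noise_sd),
            irregularity=float(irregularity),
            axis_ratios=ratios.tolist(),
            log_growth=float(g) if baseline_ml > 0 else 0.0,
            poor_probability=float(p_poor),
            covariates_z=np.asarray(z).tolist(),
        ),
    )


def _standardised_covariates(config: PhantomConfig, volume_ml: float,
                             irregularity: float, rim_noise_sd: float) -> np.ndarray:
    """Standardise (volume, irregularity, rim texture SD) by their config ranges."""

    def std(x, lo, hi):
        if hi <= lo:
            return 0.0
        mid = (lo + hi) / 2.0
        half = (hi - lo) / 2.0
        return (x - mid) / (half / np.sqrt(3.0))  # unit variance for uniform draws

    return np.array([
        std(volume_ml, *config.lesion_volume_range_ml),
        std(irregularity, 0.0, config.irregularity) if config.irregularity > 0 else 0.0,
        std(rim_noise_sd, *config.rim_noise_sd_range),
    ])


def generate_cohort(config: PhantomConfig, n: int,
                    label_model: LabelModel | None = None,
                    seed: int = 0, id_prefix: str = "case") -> list:
    """Generate ``n`` phantoms with per-case seeds derived from one cohort seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lm = label_model if label_model is not None else LabelModel()
    cases = []
    for i in range(n):
        cs = _case_seed(seed, i)
        cases.append(generate_phantom(config, cs, case_id=f"{id_prefix}_{i:04d}",
                                      label_model=lm))
    return cases


def cohort_manifest(cases) -> pd.DataFrame:
    """Tabulate labels and planted parameters for a cohort."""
    rows = []
    for c in cases:
        lab = assign_labels(c)
        rows.append(dict(
            case_id=c.case_id, baseline_volume_ml=c.baseline_volume_ml,
            followup_volume_ml=c.followup_volume_ml, mrs=c.mrs,
            poor_outcome=lab.poor_outcome, exp3=lab.exp3, exp6=lab.exp6,
            exp9=lab.exp9, seed=c.seed,
            rim_noise_sd=c.planted.get("rim_noise_sd", np.nan),
            target_volume_ml=c.planted.get("target_volume_ml", np.nan),
        ))
    return pd.DataFrame(rows)


def write_cohort(cases, out_dir) -> pd.DataFrame:
    """Write images/masks as NIfTI and the label manifest as CSV."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for c in cases:
        c.image.save(out / "images" / f"{c.case_id}.nii.gz")
        c.mask.save(out / "masks" / f"{c.case_id}.nii.gz")
    manifest = cohort_manifest(cases)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def config_to_dict(config: PhantomConfig) -> dict:
    return dataclasses.asdict(config)
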
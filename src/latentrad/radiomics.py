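"""Handcrafted radiomic features of a segmented lesion.

Implements a documented, reproducible subset of the classical feature
families computed from a binary region of interest on a 3D image:

* the 14-feature shape set (mesh/voxel volume, surface area, sphericity,
  diameters, principal axis lengths, elongation, flatness),
* first-order intensity statistics,
* gray-level co-occurrence matrix (GLCM) features over the 13 unique 3D
  offsets, feature values averaged over directions,
* gray-level run-length matrix (GLRLM) features over the same 13 directions,
* filtered variants (Laplacian-of-Gaussian at configurable scales and a
  level-1 decimated 3D wavelet transform), recomputing the intensity and
  texture families on each filtered image.

Gray levels are discretised with a fixed bin width anchored at the ROI
minimum (IBSI-style).  Degenerate single-level regions follow documented
conventions (GLCM contrast 0, correlation 1, entropy 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .features import FeatureBlock

# the 13 unique direction offsets of the 26-neighbourhood (one per +/- pair)
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

SHAPE_FEATURE_NAMES = [
    "shape_mesh_volume", "shape_voxel_volume", "shape_surface_area",
    "shape_surface_volume_ratio", "shape_sphericity", "shape_max_3d_diameter",
    "shape_max_2d_diameter_axial", "shape_max_2d_diameter_coronal",
    "shape_max_2d_diameter_sagittal", "shape_major_axis_length",
    "shape_minor_axis_length", "shape_least_axis_length",
    "shape_elongation", "shape_flatness",
]

FIRSTORDER_FEATURE_NAMES = [
    "firstorder_mean", "firstorder_median", "firstorder_variance",
    "firstorder_skewness", "firstorder_kurtosis", "firstorder_energy",
    "firstorder_entropy", "firstorder_min", "firstorder_max",
    "firstorder_range", "firstorder_p10", "firstorder_p90",
    "firstorder_iqr", "firstorder_rmad",
]

GLCM_FEATURE_NAMES = [
    "glcm_contrast", "glcm_correlation", "glcm_joint_energy",
    "glcm_joint_entropy", "glcm_homogeneity", "glcm_dissimilarity",
    "glcm_cluster_shade", "glcm_cluster_prominence",
]

GLRLM_FEATURE_NAMES = [
    "glrlm_short_run_emphasis", "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity", "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage",
]


@dataclass
class RadiomicsConfig:
    """Extraction settings.

    ``bin_width`` is in image intensity units; discretisation anchors at the
    ROI minimum.  ``log_sigmas_mm`` are Laplacian-of-Gaussian scales in mm;
    ``wavelet`` is any 3D-capable PyWavelets name (level-1 decimated
    transform, 8 subbands).
    """

    bin_width: float = 5.0
    glcm_distance: int = 1
    filters: tuple = ("log", "wavelet")
    log_sigmas_mm: tuple = (2.0, 4.0)
    wavelet: str = "coif1"

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")


class EmptyROIError(ValueError):
    """Raised when a feature is requested for an empty mask."""


# ---------------------------------------------------------------------------
# shape


_MESH_SMOOTH_SIGMA = 0.7  # voxels; suppresses staircase surface-area bias


def _mesh(mask: np.ndarray, spacing):
    padded = np.pad(mask.astype(np.float64), 4)  # >= smoothing kernel radius + 1
    smoothed = ndimage.gaussian_filter(padded, _MESH_SMOOTH_SIGMA)
    # smoothing can push all values below the iso level for tiny masks
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0))


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def shape_features(mask, spacing_mm=None) -> FeatureBlock:
    """The 14-feature shape set of a binary lesion mask.

    Surface area and mesh volume come from an iso-surface triangulation of
    the binary mask at level 0.5; sphericity is
    pi^(1/3) (6V)^(2/3) / A.  Principal axis lengths are 4 sqrt(lambda) of
    the physical-coordinate covariance eigenvalues; elongation and flatness
    are sqrt(lambda_minor / lambda_major) and sqrt(lambda_least /
    lambda_major).
    """
    arr = np.asarray(mask.data if hasattr(mask, "data") else mask, dtype=bool)
    if spacing_mm is None:
        spacing_mm = getattr(mask, "spacing_mm", (1.0, 1.0, 1.0))
    sp = np.asarray(spacing_mm, dtype=float)
    if not arr.any():
        raise EmptyROIError("shape features require a nonempty mask")

    nvox = int(arr.sum())
    voxel_volume = nvox * float(np.prod(sp))

    verts, faces = _mesh(arr, sp)
    area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * mesh_volume) ** (2.0 / 3.0) / area

    coords = np.argwhere(arr) * sp  # physical voxel-centre coordinates
    max3d = _max_pairwise_distance(coords)

    # slice-wise maximum in-plane diameters (axial = axes (0,1), etc.)
    plane_axes = {"axial": (0, 1, 2), "coronal": (0, 2, 1), "sagittal": (1, 2, 0)}
    max2d = {}
    for name, (a0, a1, sl) in plane_axes.items():
        best = 0.0
        idx = np.argwhere(arr)
        for s in np.unique(idx[:, sl]):
            pts = idx[idx[:, sl] == s][:, [a0, a1]] * sp[[a0, a1]]
            best = max(best, _max_pairwise_distance(pts))
        max2d[name] = best

    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / nvox
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    values = [mesh_volume, voxel_volume, area, area / mesh_volume, sphericity,
              max3d, max2d["axial"], max2d["coronal"], max2d["sagittal"],
              major, minor, least, elongation, flatness]
    return FeatureBlock.single_row(SHAPE_FEATURE_NAMES, values, family="shape")


# ---------------------------------------------------------------------------
# first-order


def firstorder_features(vol, mask, cfg: RadiomicsConfig | None = None) -> FeatureBlock:
    """First-order intensity statistics within the ROI.

    Variance is the population variance; kurtosis is the non-excess (Fisher
    + 3) form; entropy is over the fixed-bin-width histogram in bits.
    """
    cfg = cfg or RadiomicsConfig()
    x = _roi_values(vol, mask)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4))
    else:
        skew, kurt = 0.0, 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    levels = _discretise(x, cfg.bin_width)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0
    values = [mean, float(p50), var, skew, kurt, float(np.sum(x ** 2)), entropy,
              float(x.min()), float(x.max()), float(x.max() - x.min()),
              float(p10), float(p90), float(p75 - p25), rmad]
    return FeatureBlock.single_row(FIRSTORDER_FEATURE_NAMES, values, family="firstorder")


def _roi_values(vol, mask) -> np.ndarray:
    img = np.asarray(vol.data if hasattr(vol, "data") else vol, dtype=np.float64)
    m = np.asarray(mask.data if hasattr(mask, "data") else mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError("image and mask grids differ")
    if not m.any():
        raise EmptyROIError("empty ROI")
    return img[m]


def _discretise(x: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels anchored at the ROI minimum, 1-based."""
    return (np.floor((x - x.min()) / bin_width)).astype(np.int64) + 1


def _discretise_volume(img, mask, bin_width):
    """Level image over the ROI (0 outside the mask)."""
    lev = np.zeros(img.shape, dtype=np.int64)
    lev[mask] = _discretise(img[mask], bin_width)
    return lev


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, offset, distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset (unnormalised)."""
    d = tuple(int(o) * distance for o in offset)
    nlev = int(levels.max())
    src = [slice(max(0, -di), levels.shape[k] - max(0, di)) for k, di in enumerate(d)]
    dst = [slice(max(0, di), levels.shape[k] - max(0, -di)) for k, di in enumerate(d)]
    a = levels[tuple(src)]
    b = levels[tuple(dst)]
    valid = mask[tuple(src)] & mask[tuple(dst)]
    ai, bi = a[valid] - 1, b[valid] - 1
    mat = np.zeros((nlev, nlev), dtype=np.float64)
    np.add.at(mat, (ai, bi), 1.0)
    return mat + mat.T


def _glcm_features_from_matrix(P: np.ndarray) -> dict:
    s = P.sum()
    if s == 0 or P.shape[0] == 1:
        # constant-region convention
        return dict(contrast=0.0, correlation=1.0, joint_energy=1.0,
                    joint_entropy=0.0, homogeneity=1.0, dissimilarity=0.0,
                    cluster_shade=0.0, cluster_prominence=0.0)
    P = P / s
    nlev = P.shape[0]
    i = np.arange(1, nlev + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    diff = I - J
    contrast = float((diff ** 2 * P).sum())
    dissimilarity = float((np.abs(diff) * P).sum())
    if sigma2 > 0:
        correlation = float((((I - mu) * (J - mu) * P).sum()) / sigma2)
    else:
        correlation = 1.0
    joint_energy = float((P ** 2).sum())
    nz = P[P > 0]
    joint_entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((P / (1.0 + diff ** 2)).sum())
    cs = I + J - 2.0 * mu
    cluster_shade = float((cs ** 3 * P).sum())
    cluster_prominence = float((cs ** 4 * P).sum())
    return dict(contrast=contrast, correlation=correlation,
                joint_energy=joint_energy, joint_entropy=joint_entropy,
                homogeneity=homogeneity, dissimilarity=dissimilarity,
                cluster_shade=cluster_shade, cluster_prominence=cluster_prominence)


def glcm_features(vol, mask, cfg: RadiomicsConfig | None = None) -> FeatureBlock:
    """GLCM features averaged over the 13 unique 3D directions."""
    cfg = cfg or RadiomicsConfig()
    img = np.asarray(vol.data if hasattr(vol, "data") else vol, dtype=np.float64)
    m = np.asarray(mask.data if hasattr(mask, "data") else mask, dtype=bool)
    _roi_values(img, m)  # validates
    levels = _discretise_volume(img, m, cfg.bin_width)
    per_dir = []
    for off in DIRECTIONS_13:
        mat = glcm_matrix(levels, m, off, cfg.glcm_distance)
        per_dir.append(_glcm_features_from_matrix(mat))
    keys = ["contrast", "correlation", "joint_energy", "joint_entropy",
            "homogeneity", "dissimilarity", "cluster_shade", "cluster_prominence"]
    values = [float(np.mean([d[k] for d in per_dir])) for k in keys]
    return FeatureBlock.single_row(GLCM_FEATURE_NAMES, values, family="glcm")


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, offset) -> np.ndarray:
    """Run-length counts R[level-1, length-1] along one direction.

    Runs are maximal sequences of equal discretised level along the offset
    direction, restricted to masked voxels (a gap in the mask breaks a run).
    """
    d = np.asarray(offset, dtype=int)
    nlev = int(levels.max())
    shape = np.asarray(levels.shape)

    def shifted_valid(coords):
        nxt = coords + d
        ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
        return nxt, ok

    coords = np.argwhere(mask)
    if coords.size == 0:
        return np.zeros((max(nlev, 1), 1))
    lev_of = lambda c: levels[c[:, 0], c[:, 1], c[:, 2]]
    in_mask = lambda c: mask[c[:, 0], c[:, 1], c[:, 2]]

    # run starts: predecessor out of bounds, out of mask, or different level
    prev = coords - d
    prev_ok = np.all((prev >= 0) & (prev < shape), axis=1)
    start = ~prev_ok.copy()
    pv = prev[prev_ok]
    same_prev = in_mask(pv) & (lev_of(np.clip(pv, 0, None)) == lev_of(coords[prev_ok]))
    start[prev_ok] = ~same_prev

    starts = coords[start]
    run_levels = lev_of(starts)
    run_len = np.ones(len(starts), dtype=np.int64)
    cur = starts.copy()
    active = np.arange(len(starts))
    while active.size:
        nxt, ok = shifted_valid(cur[active])
        cont = np.zeros(active.size, dtype=bool)
        if ok.any():
            nn = nxt[ok]
            cont_ok = in_mask(nn) & (lev_of(nn) == run_levels[active[ok]])
            cont[ok] = cont_ok
        run_len[active[cont]] += 1
        cur[active[cont]] += d
        active = active[cont]

    maxlen = int(run_len.max()) if len(run_len) else 1
    R = np.zeros((nlev, maxlen), dtype=np.float64)
    np.add.at(R, (run_levels - 1, run_len - 1), 1.0)
    return R


def _glrlm_features_from_matrix(R: np.ndarray, n_voxels: int) -> dict:
    nr = R.sum()
    if nr == 0:
        return dict(sre=0.0, lre=0.0, gln=0.0, rln=0.0, rp=0.0)
    lengths = np.arange(1, R.shape[1] + 1, dtype=np.float64)
    r_l = R.sum(axis=0)  # by length
    r_g = R.sum(axis=1)  # by gray level
    sre = float((r_l / lengths ** 2).sum() / nr)
    lre = float((r_l * lengths ** 2).sum() / nr)
    gln = float((r_g ** 2).sum() / nr)
    rln = float((r_l ** 2).sum() / nr)
    rp = float(nr / n_voxels)
    return dict(sre=sre, lre=lre, gln=gln, rln=rln, rp=rp)


def glrlm_features(vol, mask, cfg: RadiomicsConfig | None = None) -> FeatureBlock:
    """GLRLM features averaged over the 13 unique 3D directions."""
    cfg = cfg or RadiomicsConfig()
    img = np.asarray(vol.data if hasattr(vol, "data") else vol, dtype=np.float64)
    m = np.asarray(mask.data if hasattr(mask, "data") else mask, dtype=bool)
    _roi_values(img, m)
    levels = _discretise_volume(img, m, cfg.bin_width)
    nvox = int(m.sum())
    per_dir = []
    for off in DIRECTIONS_13:
        R = glrlm_matrix(levels, m, off)
        per_dir.append(_glrlm_features_from_matrix(R, nvox))
    keys = ["sre", "lre", "gln", "rln", "rp"]
    values = [float(np.mean([d[k] for d in per_dir])) for k in keys]
    return FeatureBlock.single_row(GLRLM_FEATURE_NAMES, values, family="glrlm")


# ---------------------------------------------------------------------------
# filtered variants


def _wavelet_subbands(img: np.ndarray, wavelet: str) -> dict:
    """Level-1 decimated 3D DWT: 8 subbands, each about half-size per axis."""
    coeffs = pywt.dwtn(img, wavelet, mode="periodization")
    return {f"wavelet_{k.upper()}": v for k, v in sorted(coeffs.items())}


def filtered_features(vol, mask, cfg: RadiomicsConfig | None = None) -> FeatureBlock:
    """First-order + GLCM + GLRLM on filtered images, names prefixed by filter.

    LoG responses are computed on the full image at each configured scale
    (sigma in mm, converted to voxels via the spacing) and evaluated on the
    original ROI.  Wavelet subbands are decimated, so the mask is
    down-sampled by stride 2 to the subband grid.
    """
    cfg = cfg or RadiomicsConfig()
    img = np.asarray(vol.data if hasattr(vol, "data") else vol, dtype=np.float64)
    m = np.asarray(mask.data if hasattr(mask, "data") else mask, dtype=bool)
    spacing = np.asarray(getattr(vol, "spacing_mm", (1.0, 1.0, 1.0)), dtype=float)
    _roi_values(img, m)

    variants: list[tuple[str, np.ndarray, np.ndarray]] = []
    if "log" in cfg.filters:
        for sigma in cfg.log_sigmas_mm:
            if sigma <= 0:
                raise ValueError("LoG sigma must be positive")
            resp = ndimage.gaussian_laplace(img, sigma=tuple(sigma / spacing))
            variants.append((f"log_sigma_{sigma:g}mm", resp, m))
    if "wavelet" in cfg.filters:
        sub_mask = m[::2, ::2, ::2]
        for name, band in _wavelet_subbands(img, cfg.wavelet).items():
            if sub_mask.shape != band.shape or not sub_mask.any():
                continue
            variants.append((name, band, sub_mask))

    names: list[str] = []
    values: list[float] = []
    for prefix, fimg, fmask in variants:
        for fn in (firstorder_features, glcm_features, glrlm_features):
            blk = fn(fimg, fmask, cfg)
            names.extend(f"{prefix}_{n}" for n in blk.names)
            values.extend(blk.matrix[0].tolist())
    if not names:
        raise ValueError("no filters requested in config")
    return FeatureBlock.single_row(names, values, family="filtered")


# ---------------------------------------------------------------------------
# per-case assembly


def extract_all_features(vol, mask, cfg: RadiomicsConfig | None = None) -> FeatureBlock:
    """Concatenate shape + first-order + GLCM + GLRLM + filtered for one case."""
    cfg = cfg or RadiomicsConfig()
    blocks = [
        shape_features(mask, getattr(vol, "spacing_mm", None)),
        firstorder_features(vol, mask, cfg),
        glcm_features(vol, mask, cfg),
        glrlm_features(vol, mask, cfg),
    ]
    if cfg.filters:
        blocks.append(filtered_features(vol, mask, cfg))
    names = [n for b in blocks for n in b.names]
    values = np.concatenate([b.matrix[0] for b in blocks])
    return FeatureBlock.single_row(names, values, family="radiomics")


def cohort_features(cases, cfg: RadiomicsConfig | None = None,
                    masks=None) -> FeatureBlock:
    """Radiomics matrix for a cohort of synthetic cases (rows = cases)."""
    cfg = cfg or RadiomicsConfig()
    rows, ids = [], []
    names = None
    for i, case in enumerate(cases):
        mask = masks[i] if masks is not None else case.mask
        blk = extract_all_features(case.image, mask, cfg)
        if names is None:
            names = blk.names
        elif names != blk.names:
            raise ValueError("inconsistent feature names across cases")
        rows.append(blk.matrix[0])
        ids.append(case.case_id)
    return FeatureBlock(names=list(names), matrix=np.vstack(rows),
                        family="radiomics", case_ids=ids)
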
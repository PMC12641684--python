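"""Latent deep features from segmentation-encoder bottlenecks and a VAE-GAN.

Two sources of learned features complement handcrafted radiomics:

* the bottleneck activations of the segmentation network's two encoders
  (``seg_full``, ``seg_half``), capturing what distinguishes the lesion from
  the surrounding parenchyma, and
* the latent mean map of a variational autoencoder (optionally with an
  adversarial discriminator, i.e. a VAE-GAN) trained to reconstruct
  dilated-mask lesion patches cropped from the image, capturing texture
  inside and around the lesion.

Both stages are outcome-agnostic: no labels are used.  Latent tensors are
flattened channel-major into rows of a :class:`FeatureBlock`; NMF reduction
downstream requires nonnegative values, supplied by :func:`nonneg_shift`
(a per-column shift fit on training rows only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .features import FeatureBlock
from .nn import Adam, Conv3d, ConvBlock, Module, Tensor, avg_pool3d, upsample_nearest3d
from .volume import ImageVolume, LesionMask

logger = logging.getLogger(__name__)


def dilate_mask(mask: LesionMask, size: int = 5) -> LesionMask:
    """Binary dilation with a size x size x size cubic structuring element.

    The element is clipped at volume borders; the output always contains the
    input.  ``size`` must be odd so the element is centred.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and >= 1")
    if size == 1:
        return LesionMask(mask.data.copy(), mask.spacing_mm, mask.affine)
    out = ndimage.binary_dilation(mask.data, structure=np.ones((size,) * 3, dtype=bool))
    return LesionMask(out, mask.spacing_mm, mask.affine)


def crop_roi(vol: ImageVolume, dmask: LesionMask, out_shape=(16, 16, 16)) -> ImageVolume:
    """Crop the dilated-mask bounding box to a cube and resample to ``out_shape``.

    Voxels outside the dilated mask are zeroed, so the patch contains only
    the lesion and its peri-lesional context.  The bounding box is padded
    symmetrically to a cube before resampling, keeping the lesion centred.
    """
    if np.isscalar(out_shape):
        out_shape = (int(out_shape),) * 3
    m = dmask.data
    if not m.any():
        raise ValueError("empty dilated mask")
    img = np.where(m, vol.data, 0.0)
    idx = np.argwhere(m)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    side = int((hi - lo).max())
    # symmetric padding to a cube (crop window may extend past the volume)
    starts, stops, pads = [], [], []
    for a in range(3):
        extent = hi[a] - lo[a]
        extra = side - extent
        s = lo[a] - extra // 2
        e = hi[a] + (extra - extra // 2)
        pads.append((max(0, -s), max(0, e - vol.data.shape[a])))
        starts.append(max(0, s))
        stops.append(min(vol.data.shape[a], e))
    patch = img[starts[0]:stops[0], starts[1]:stops[1], starts[2]:stops[2]]
    patch = np.pad(patch, pads)
    factors = [o / s for o, s in zip(out_shape, patch.shape)]
    out = ndimage.zoom(patch, factors, order=1, mode="nearest", grid_mode=True)
    return ImageVolume(out, (1.0, 1.0, 1.0))


@dataclass
class VAEGANConfig:
    """VAE(-GAN) architecture and training settings.

    ``loss_weights`` is (w_recon, w_kl, w_adv); with ``w_adv = 0`` the model
    is a plain VAE, which is the stable default for small CPU runs.  Reference
    scale is 64**3 patches with 512 latent channels; desk scale shrinks both.
    """

    patch_shape: tuple = (16, 16, 16)
    latent_channels: int = 32
    base_channels: int = 4
    depth: int = 2
    loss_weights: tuple = (1.0, 1e-4, 0.0)
    epochs: int = 20
    batch_size: int = 4
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if np.isscalar(self.patch_shape):
            self.patch_shape = (int(self.patch_shape),) * 3
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        if len(set(self.patch_shape)) != 1:
            raise ValueError("patch_shape must be cubic")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be nonnegative")
        if self.patch_shape[0] % 2 ** self.depth != 0:
            raise ValueError("patch extent must be divisible by 2**depth")

    @property
    def latent_shape(self) -> tuple:
        s = self.patch_shape[0] // 2 ** self.depth
        return (self.latent_channels, s, s, s)


class _VAEEncoder(Module):
    def __init__(self, cfg: VAEGANConfig, rng):
        chans = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.blocks = []
        cin = 1
        for c in chans:
            self.blocks.append(ConvBlock(cin, c, rng))
            cin = c
        self.mu_head = Conv3d(cin, cfg.latent_channels, 3, rng)
        self.logvar_head = Conv3d(cin, cfg.latent_channels, 3, rng)

    def __call__(self, x: Tensor):
        h = x
        for blk in self.blocks:
            h = avg_pool3d(blk(h), 2)
        return self.mu_head(h), self.logvar_head(h)


class _VAEDecoder(Module):
    def __init__(self, cfg: VAEGANConfig, rng):
        chans = [cfg.base_channels * 2 ** i for i in range(cfg.depth)][::-1]
        self.blocks = []
        cin = cfg.latent_channels
        for c in chans:
            self.blocks.append(ConvBlock(cin, c, rng))
            cin = c
        self.out = Conv3d(cin, 1, 3, rng)

    def __call__(self, z: Tensor) -> Tensor:
        h = z
        for blk in self.blocks:
            h = blk(upsample_nearest3d(h, 2))
        return self.out(h)


class _Discriminator(Module):
    def __init__(self, cfg: VAEGANConfig, rng):
        chans = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.blocks = []
        cin = 1
        for c in chans:
            self.blocks.append(ConvBlock(cin, c, rng))
            cin = c
        self.out = Conv3d(cin, 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.blocks:
            h = avg_pool3d(blk(h), 2)
        return self.out(h).mean(axis=(1, 2, 3, 4))  # per-sample logit


class VAEGANModel(Module):
    """Variational autoencoder with optional adversarial discriminator."""

    def __init__(self, cfg: VAEGANConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = _VAEEncoder(cfg, rng)
        self.decoder = _VAEDecoder(cfg, rng)
        self.discriminator = _Discriminator(cfg, rng) if cfg.loss_weights[2] > 0 else None
        self.trained = False
        self.loss_history: list = []
        self.disc_loss_history: list = []

    def encode_mean(self, patch: np.ndarray) -> np.ndarray:
        """Latent mean map (sample-free, deterministic) for one patch."""
        x = np.asarray(patch, dtype=np.float32)[None, None]
        mu, _ = self.encoder(Tensor(x))
        return mu.data[0].copy()

    def gen_parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()


def _kl_term(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL(q || N(0, I)) averaged over batch, summed over latent elements."""
    n = mu.data.shape[0]
    term = (mu * mu + logvar.exp() - logvar - 1.0) * 0.5
    return term.sum() * (1.0 / float(n))


def train_vaegan(patches, cfg: VAEGANConfig) -> VAEGANModel:
    """Train the VAE(-GAN) on lesion patches.

    Total generator loss = w_recon * L1(reconstruction, input)
    + w_kl * KL(q || N(0,I)) + w_adv * non-saturating adversarial term.
    The discriminator (when ``w_adv > 0``) is updated alternately with the
    generator.  Seeded and deterministic.
    """
    if len(patches) < 8:
        raise ValueError("need at least 8 patches")
    arrs = [np.asarray(p.data if hasattr(p, "data") else p, dtype=np.float32)
            for p in patches]
    if any(a.shape != cfg.patch_shape for a in arrs):
        raise ValueError("patch shape mismatch with config")
    X = np.stack(arrs)[:, None]  # (N,1,D,H,W)
    # scale to a stable range for L1 reconstruction
    scale = float(np.abs(X).max()) or 1.0
    X = X / scale
    if float(X.std()) == 0:
        logger.warning("all patches are identical; latent features will be constant")

    w_recon, w_kl, w_adv = cfg.loss_weights
    model = VAEGANModel(cfg)
    model.input_scale = scale
    opt_g = Adam(model.gen_parameters(), lr=cfg.lr)
    opt_d = Adam(model.discriminator.parameters(), lr=cfg.lr) if model.discriminator else None
    rng = np.random.default_rng(cfg.seed)

    for _ in range(cfg.epochs):
        order = rng.permutation(len(X))
        ep_losses, ep_dlosses = [], []
        for s in range(0, len(X), cfg.batch_size):
            xb = X[order[s:s + cfg.batch_size]]
            x = Tensor(xb)
            mu, logvar = model.encoder(x)
            noise = rng.standard_normal(mu.data.shape).astype(np.float32)
            z = mu + Tensor(noise) * (logvar * 0.5).exp()
            recon = model.decoder(z)
            loss = (recon - x).abs().mean() * w_recon
            if w_kl > 0:
                loss = loss + _kl_term(mu, logvar) * w_kl
            if model.discriminator is not None:
                # generator: non-saturating, wants D(recon) high
                g_adv = (-model.discriminator(recon)).softplus().mean()
                loss = loss + g_adv * w_adv
            opt_g.zero_grad()
            model.discriminator and model.discriminator.zero_grad()
            loss.backward()
            opt_g.step()
            ep_losses.append(float(loss.data))

            if model.discriminator is not None:
                d_real = model.discriminator(Tensor(xb))
                d_fake = model.discriminator(Tensor(recon.data))
                d_loss = ((-d_real).softplus().mean() + d_fake.softplus().mean()) * 0.5
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
                ep_dlosses.append(float(d_loss.data))
        model.loss_history.append(float(np.mean(ep_losses)))
        if ep_dlosses:
            model.disc_loss_history.append(float(np.mean(ep_dlosses)))
    model.trained = True
    return model


def make_patch(case, seg_cfg=None, dilation_size: int = 5,
               out_shape=(16, 16, 16)) -> ImageVolume:
    """Dilated-mask lesion patch for one case (VAE-GAN input)."""
    dmask = dilate_mask(case.mask, dilation_size)
    return crop_roi(case.image, dmask, out_shape)


def extract_latents(model, cases, source: str | None = None,
                    seg_cfg=None, dilation_size: int = 5) -> dict:
    """Flattened bottleneck latents for a cohort.

    For a segmentation model, returns blocks keyed ``seg_full`` and
    ``seg_half`` (one when single-scale); for a VAE-GAN, the latent *mean*
    map under key ``vaegan``.  Flattening order is channel-major, then
    depth, height, width; repeated extraction is deterministic.
    """
    from .segmentation import SegmentationModel, prepare_case

    if not getattr(model, "trained", False):
        raise RuntimeError("model has not been trained")

    blocks: dict[str, list] = {}
    shapes: dict[str, tuple] = {}
    ids = []
    for case in cases:
        ids.append(case.case_id)
        if isinstance(model, SegmentationModel):
            x, _ = prepare_case(case.image, model.cfg)
            lat = model.bottlenecks(x[None])
        elif isinstance(model, VAEGANModel):
            patch = make_patch(case, dilation_size=dilation_size,
                               out_shape=model.cfg.patch_shape)
            arr = patch.data / getattr(model, "input_scale", 1.0)
            lat = {"vaegan": model.encode_mean(arr)}
        else:
            raise TypeError(f"unsupported model type {type(model).__name__}")
        for key, tensor in lat.items():
            shapes[key] = tensor.shape
            blocks.setdefault(key, []).append(tensor.ravel(order="C"))

    out = {}
    for key, rows in blocks.items():
        shape = shapes[key]
        names = [f"{key}_{i:05d}" for i in range(int(np.prod(shape)))]
        blk = FeatureBlock(names=names, matrix=np.vstack(rows), family="latent",
                           case_ids=ids)
        blk.tensor_shape = shape
        out[key] = blk
    if source is not None:
        return {source: out[source]}
    return out


def nonneg_shift(block: FeatureBlock, train_ids) -> FeatureBlock:
    """Shift each column by its minimum over *training rows only*; clip at 0.

    The training submatrix minimum becomes exactly 0 per column.  Test rows
    falling below the training minimum are clipped to 0 (count logged) so
    downstream NMF sees only nonnegative values and no test-row statistics
    leak into the fit.
    """
    if not train_ids:
        raise ValueError("train_ids must be nonempty")
    index = {c: i for i, c in enumerate(block.case_ids)}
    rows = [index[c] for c in train_ids]
    # shift only columns with negative training minima, so an already
    # nonnegative block passes through unchanged
    mins = np.minimum(block.matrix[rows].min(axis=0), 0.0)
    shifted = block.matrix - mins[None, :]
    clipped = int((shifted < 0).sum())
    if clipped:
        logger.info("nonneg_shift clipped %d test-row values below the training minimum",
                    clipped)
    out = FeatureBlock(names=list(block.names), matrix=np.clip(shifted, 0.0, None),
                       family=block.family, case_ids=list(block.case_ids))
    out.n_clipped = clipped
    return out
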
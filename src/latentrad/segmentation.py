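"""Dual-resolution U-shaped lesion segmentation with deep supervision.

The network ingests the preprocessed volume at two isotropic grids (full
resolution and half resolution, the latter produced by average pooling) via
two parallel encoders.  Each encoder ends in a bottleneck tensor with
``bottleneck_channels`` channels and spatial extent ``input/2**depth``; the
half-resolution bottleneck is upsampled and fused into the decoder, which
emits a voxel-wise foreground probability map at full resolution plus
deep-supervision outputs at coarser scales.  Training minimises a combined
soft-Dice + cross-entropy loss summed over the supervision outputs with
per-level weights halving by depth.

At reference scale (inputs 128**3 / 64**3, depth 4, 512 bottleneck channels) the
bottlenecks are (512, 8, 8, 8) and (512, 4, 4, 4); desk-scale configs shrink
every dimension proportionally so the same code trains in minutes on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import Adam, Conv3d, ConvBlock, Module, SGDPoly, Tensor, avg_pool3d, concat, upsample_nearest3d
from .volume import ImageVolume, LesionMask, normalize_intensity

DICE_EPS = 1e-5


def _cube(shape) -> tuple:
    if np.isscalar(shape):
        return (int(shape),) * 3
    t = tuple(int(s) for s in shape)
    return t


@dataclass
class MultiscaleNetConfig:
    """Architecture geometry of the dual-resolution segmentation network."""

    full_res_shape: tuple = (32, 32, 32)
    half_res_shape: tuple = None  # type: ignore[assignment]
    base_channels: int = 4
    depth: int = 3
    bottleneck_channels: int = 64
    deep_supervision_levels: int = 2
    single_scale: bool = False
    clip_window: tuple = (0.0, 100.0)

    def __post_init__(self):
        self.full_res_shape = _cube(self.full_res_shape)
        if self.half_res_shape is None:
            self.half_res_shape = tuple(s // 2 for s in self.full_res_shape)
        self.half_res_shape = _cube(self.half_res_shape)
        if tuple(s // 2 for s in self.full_res_shape) != self.half_res_shape:
            raise ValueError("half_res_shape must be full_res_shape / 2 per axis")
        for shp, name in ((self.full_res_shape, "full"), (self.half_res_shape, "half")):
            for s in shp:
                if s % (2 ** self.depth) != 0:
                    raise ValueError(
                        f"{name}-res extent {s} not divisible by 2**depth={2 ** self.depth}")
        if self.deep_supervision_levels >= self.depth:
            raise ValueError("deep_supervision_levels must be < depth")

    @property
    def bottleneck_shape_full(self) -> tuple:
        d = 2 ** self.depth
        return (self.bottleneck_channels,) + tuple(s // d for s in self.full_res_shape)

    @property
    def bottleneck_shape_half(self) -> tuple:
        d = 2 ** self.depth
        return (self.bottleneck_channels,) + tuple(s // d for s in self.half_res_shape)


@dataclass
class SegTrainState:
    """Per-epoch training record."""

    epoch: int
    loss_history: list
    val_dice_history: list
    seed: int

    def __post_init__(self):
        if len(self.loss_history) != self.epoch:
            raise ValueError("loss history length must equal epoch count")
        if self.val_dice_history and len(self.val_dice_history) != self.epoch:
            raise ValueError("val history length must equal epoch count")


class _Encoder(Module):
    def __init__(self, cfg: MultiscaleNetConfig, rng: np.random.Generator):
        chans = [min(cfg.base_channels * 2 ** i, cfg.bottleneck_channels)
                 for i in range(cfg.depth)]
        self.level_blocks = []
        cin = 1
        for c in chans:
            self.level_blocks.append(ConvBlock(cin, c, rng))
            cin = c
        self.bottom = ConvBlock(cin, cfg.bottleneck_channels, rng)
        self.channels = chans

    def __call__(self, x: Tensor):
        skips = []
        h = x
        for blk in self.level_blocks:
            h = blk(h)
            skips.append(h)
            h = avg_pool3d(h, 2)
        return skips, self.bottom(h)


class SegmentationModel(Module):
    """Multiscale (or single-scale) U-shaped segmentation network."""

    def __init__(self, cfg: MultiscaleNetConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.seed = int(seed)
        self.trained = False
        self.encoder_full = _Encoder(cfg, rng)
        self.encoder_half = None if cfg.single_scale else _Encoder(cfg, rng)
        bc = cfg.bottleneck_channels
        self.fuse = None if cfg.single_scale else ConvBlock(2 * bc, bc, rng)
        # decoder mirrors the full-resolution encoder
        chans = self.encoder_full.channels
        self.up_blocks = []
        cin = bc
        for c in reversed(chans):
            self.up_blocks.append(ConvBlock(cin + c, c, rng))
            cin = c
        # supervision heads: full resolution + deep_supervision_levels coarser
        self.heads = []
        head_channels = [chans[i] for i in range(cfg.deep_supervision_levels, -1, -1)]
        for c in head_channels:
            self.heads.append(Conv3d(c, 1, 1, rng))

    def forward(self, x_full: np.ndarray):
        """Run the network; returns (logits list coarse->full order fixed), bottlenecks.

        ``x_full`` is (N, 1, D, H, W) preprocessed intensity.  The
        half-resolution branch input is the average-pooled full-resolution
        volume.  Returns a dict with ``logits`` ordered full-resolution
        first, then each coarser deep-supervision output, and the two
        (or one) encoder bottleneck tensors.
        """
        t_full = x_full if isinstance(x_full, Tensor) else Tensor(x_full)
        skips, bott_full = self.encoder_full(t_full)
        bott_half = None
        if self.encoder_half is not None:
            t_half = avg_pool3d(t_full, 2)
            _, bott_half = self.encoder_half(t_half)
            fused = self.fuse(concat([bott_full, upsample_nearest3d(bott_half, 2)], axis=1))
        else:
            fused = bott_full

        h = fused
        decoder_feats = []
        for blk, skip in zip(self.up_blocks, reversed(skips)):
            h = blk(concat([upsample_nearest3d(h, 2), skip], axis=1))
            decoder_feats.append(h)
        # heads attach to the last (finest) levels; full-resolution head last
        ds = self.cfg.deep_supervision_levels
        logits = []
        feats = decoder_feats[-(ds + 1):]  # coarse..fine
        for head, f in zip(self.heads, feats):
            logits.append(head(f))
        logits = logits[::-1]  # full-resolution first
        return dict(logits=logits, bottleneck_full=bott_full, bottleneck_half=bott_half)

    def bottlenecks(self, x_full: np.ndarray) -> dict:
        """Encoder bottleneck activations (inference, no gradients)."""
        out = self.forward(np.asarray(x_full, dtype=np.float32))
        res = {"seg_full": out["bottleneck_full"].data[0].copy()}
        if out["bottleneck_half"] is not None:
            res["seg_half"] = out["bottleneck_half"].data[0].copy()
        return res


def build_multiscale_unet(cfg: MultiscaleNetConfig, seed: int = 0) -> SegmentationModel:
    """Construct the (seeded) segmentation network for a given geometry."""
    return SegmentationModel(cfg, seed)


def soft_dice_loss(logits: Tensor, target: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """1 - soft Dice between sigmoid(logits) and the (soft) target."""
    p = logits.sigmoid()
    t = Tensor(np.asarray(target, dtype=np.float32))
    axes = (1, 2, 3, 4)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (inter * 2.0 + eps) / (denom + eps)
    return (1.0 - dice).mean()


def bce_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on logits: softplus(z) - z t."""
    t = Tensor(np.asarray(target, dtype=np.float32))
    return (logits.softplus() - logits * t).mean()


def combined_loss(outputs: list, target: np.ndarray, w_dice: float, w_ce: float) -> Tensor:
    """Deep-supervised loss: sum over output scales, level weights halving.

    The full-resolution output gets weight 1, each coarser level half the
    previous (weights normalised to sum to 1).  Coarse targets are
    average-pooled soft masks.
    """
    weights = np.array([0.5 ** l for l in range(len(outputs))])
    weights = weights / weights.sum()
    total = None
    tgt = np.asarray(target, dtype=np.float32)
    for wl, logit in zip(weights, outputs):
        if tgt.shape[2:] != logit.data.shape[2:]:
            f = tgt.shape[2] // logit.data.shape[2]
            n, c, d, h, w = tgt.shape
            tgt_l = tgt.reshape(n, c, d // f, f, h // f, f, w // f, f).mean(axis=(3, 5, 7))
        else:
            tgt_l = tgt
        term = None
        if w_dice > 0:
            term = soft_dice_loss(logit, tgt_l) * w_dice
        if w_ce > 0:
            ce = bce_loss(logit, tgt_l) * w_ce
            term = ce if term is None else term + ce
        scaled = term * float(wl)
        total = scaled if total is None else total + scaled
    return total


def prepare_case(image: ImageVolume, cfg: MultiscaleNetConfig,
                 mask: LesionMask | None = None):
    """Window/z-score the image and fit it to the network grid.

    Returns ``(x, t)`` arrays shaped (1, D, H, W); ``t`` is None when no
    mask is given.  Resizing to the configured grid uses trilinear
    interpolation for the image and nearest-neighbour for the mask.
    """
    norm = normalize_intensity(image, *cfg.clip_window)
    x = norm.data
    if x.shape != cfg.full_res_shape:
        factors = [o / s for o, s in zip(cfg.full_res_shape, x.shape)]
        x = ndimage.zoom(x, factors, order=1, mode="nearest", grid_mode=True)
    t = None
    if mask is not None:
        m = mask.data.astype(np.float32)
        if m.shape != cfg.full_res_shape:
            factors = [o / s for o, s in zip(cfg.full_res_shape, m.shape)]
            m = ndimage.zoom(m, factors, order=0, mode="nearest", grid_mode=True)
        t = m[None].astype(np.float32)
    return x[None].astype(np.float32), t


def train_segmentation(model: SegmentationModel, cases, loss_weights=(1.0, 1.0),
                       epochs: int = 20, seed: int = 0, batch_size: int = 2,
                       lr: float = 3e-3, optimizer: str = "adam",
                       val_cases=None) -> SegTrainState:
    """Train on synthetic cases with ground-truth masks.

    ``loss_weights`` is (w_dice, w_ce).  Identical seed, data and config
    reproduce the loss history bit-identically (pure numpy arithmetic).
    """
    w_dice, w_ce = loss_weights
    if len(cases) < 2:
        raise ValueError("need at least 2 training cases")
    if w_dice < 0 or w_ce < 0 or (w_dice == 0 and w_ce == 0):
        raise ValueError("loss weights must be nonnegative and not both zero")
    if all(c.mask.voxel_count == 0 for c in cases):
        raise ValueError("degenerate labels: every training mask is empty")

    data = [prepare_case(c.image, model.cfg, c.mask) for c in cases]
    xs = np.concatenate([d[0][None] for d in data])
    ts = np.concatenate([d[1][None] for d in data])

    params = model.parameters()
    if optimizer == "adam":
        opt = Adam(params, lr=lr)
    elif optimizer == "sgd":
        steps = epochs * int(np.ceil(len(cases) / batch_size))
        opt = SGDPoly(params, lr=lr, t_max=steps)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    rng = np.random.default_rng(seed)
    loss_hist, val_hist = [], []
    for _ in range(epochs):
        order = rng.permutation(len(cases))
        epoch_losses = []
        for s in range(0, len(cases), batch_size):
            idx = order[s:s + batch_size]
            out = model.forward(xs[idx])
            loss = combined_loss(out["logits"], ts[idx], w_dice, w_ce)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        loss_hist.append(float(np.mean(epoch_losses)))
        if val_cases is not None:
            model.trained = True
            dices = []
            for c in val_cases:
                pred = predict_mask(model, c.image)
                xv, tv = prepare_case(c.image, model.cfg, c.mask)
                gt = LesionMask(tv[0] > 0.5, (1.0,) * 3)
                dices.append(dice_coefficient(pred, gt))
            val_hist.append(float(np.median(dices)))
    model.trained = True
    return SegTrainState(epoch=epochs, loss_history=loss_hist,
                         val_dice_history=val_hist, seed=int(seed))


def predict_mask(model: SegmentationModel, vol: ImageVolume,
                 threshold: float = 0.5) -> LesionMask:
    """Binary mask from the full-resolution probability map (prob >= threshold)."""
    if not getattr(model, "trained", False):
        raise RuntimeError("model has not been trained")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    x, _ = prepare_case(vol, model.cfg)
    out = model.forward(x[None])
    prob = 1.0 / (1.0 + np.exp(-out["logits"][0].data[0, 0].astype(np.float64)))
    return LesionMask(prob >= threshold, (1.0,) * 3)


def dice_coefficient(a: LesionMask, b: LesionMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    ad = a.data if hasattr(a, "data") else np.asarray(a, dtype=bool)
    bd = b.data if hasattr(b, "data") else np.asarray(b, dtype=bool)
    if ad.shape != bd.shape:
        raise ValueError(f"mask grids differ: {ad.shape} vs {bd.shape}")
    denom = int(ad.sum()) + int(bd.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ad & bd).sum()) / denom


def save_checkpoint(model: SegmentationModel, path) -> None:
    """Single-file checkpoint with the config embedded."""
    import dataclasses as dc
    import json

    cfgd = dc.asdict(model.cfg)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez_compressed(path, __config__=json.dumps(
        dict(cfg=cfgd, seed=model.seed, trained=model.trained)), **arrays)


def load_checkpoint(path) -> SegmentationModel:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__config__"]))
        cfg = MultiscaleNetConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in meta["cfg"].items()})
        model = SegmentationModel(cfg, meta["seed"])
        model.load_state_arrays([z[f"p{i}"] for i in range(len(model.parameters()))])
        model.trained = bool(meta["trained"])
    return model
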
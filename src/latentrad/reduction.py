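"""Non-negative matrix factorization of feature families and input assembly.

Each feature family (radiomics, the two segmentation-encoder latent sets,
the autoencoder latents) is reduced by NMF — fit on training cases only —
and the reduced sets are assembled into the seven classifier input
configurations.  Multiplicative (Lee-Seung, Frobenius) updates are used
because their objective is provably non-increasing per iteration, which the
tests assert directly; transforming new cases solves a nonnegative
least-squares projection onto the *fixed* basis (updates on scores only),
so no test-case statistics ever touch the basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureBlock, concat_blocks

_MU_EPS = 1e-9


@dataclass
class NMFModel:
    """A fitted nonnegative factor pair X ~ W H.

    ``basis`` is H (k x features); training scores W are kept for the
    consistency guarantee that transforming a training row reproduces its
    fitted scores.  ``train_ids`` records exactly which cases the fit saw.
    """

    basis: np.ndarray
    k: int
    train_ids: list
    objective_history: list
    train_scores: np.ndarray = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self):
        if np.any(self.basis < 0):
            raise ValueError("basis must be nonnegative")
        diffs = np.diff(self.objective_history)
        if np.any(diffs > 1e-8 * max(self.objective_history[0], 1.0)):
            raise ValueError("objective history must be non-increasing")

    def basis_hash(self) -> str:
        import hashlib

        return hashlib.sha256(np.ascontiguousarray(self.basis).tobytes()).hexdigest()


def _mu_update_w(X, W, H):
    numer = X @ H.T
    denom = W @ (H @ H.T) + _MU_EPS
    return W * (numer / denom)


def _mu_update_h(X, W, H):
    numer = W.T @ X
    denom = (W.T @ W) @ H + _MU_EPS
    return H * (numer / denom)


def nmf_fit(X: np.ndarray, k: int, iters: int = 200, seed: int = 0,
            train_ids=None) -> NMFModel:
    """Fit NMF by multiplicative updates with seeded uniform(0.1, 1] init.

    Minimises ||X - W H||_F over nonnegative W (cases x k) and H
    (k x features); the Frobenius objective is recorded every iteration and
    is non-increasing by construction.
    """
    X = np.asarray(X, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("NMF input must be nonnegative")
    n, d = X.shape
    if k > min(n, d):
        raise ValueError(f"k={k} exceeds min(n, d)={min(n, d)}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, (n, k))
    H = rng.uniform(0.1, 1.0, (k, d))
    history = []
    for _ in range(iters):
        W = _mu_update_w(X, W, H)
        H = _mu_update_h(X, W, H)
        history.append(float(np.linalg.norm(X - W @ H)))
    return NMFModel(basis=H, k=k, train_ids=list(train_ids or []),
                    objective_history=history, train_scores=W, seed=int(seed))


def nmf_transform(model: NMFModel, Xnew: np.ndarray, iters: int = 200,
                  seed: int = 0) -> np.ndarray:
    """Project new rows onto the fixed basis (multiplicative updates on W only)."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=np.float64))
    if np.any(Xnew < 0):
        raise ValueError("NMF input must be nonnegative")
    H = model.basis
    if Xnew.shape[1] != H.shape[1]:
        raise ValueError(f"feature count {Xnew.shape[1]} does not match basis {H.shape[1]}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, (Xnew.shape[0], model.k))
    HHt = H @ H.T
    XHt = Xnew @ H.T
    for _ in range(iters):
        W = W * (XHt / (W @ HHt + _MU_EPS))
    return W


def reduce_block(block: FeatureBlock, k: int, train_ids, iters: int = 200,
                 seed: int = 0, prefix: str | None = None,
                 unit_scale: bool = True):
    """Shift-to-nonnegative, scale, fit NMF on training rows, transform all.

    With ``unit_scale`` each column is divided by its training maximum after
    the shift, so heterogeneous feature scales (e.g. energy vs sphericity)
    contribute comparably to the Frobenius objective.  Both the shift and the
    scale are estimated from training rows only.  Returns ``(reduced
    FeatureBlock, NMFModel)``; test rows are transformed against the fixed
    basis, training rows reuse their fitted scores.
    """
    from .latent import nonneg_shift

    shifted = nonneg_shift(block, train_ids)
    if unit_scale:
        index = {c: i for i, c in enumerate(shifted.case_ids)}
        tr = [index[c] for c in train_ids]
        scale = shifted.matrix[tr].max(axis=0)
        scale[scale == 0] = 1.0
        shifted = FeatureBlock(names=list(shifted.names),
                               matrix=shifted.matrix / scale[None, :],
                               family=shifted.family,
                               case_ids=list(shifted.case_ids))
    index = {c: i for i, c in enumerate(shifted.case_ids)}
    train_rows = [index[c] for c in train_ids]
    model = nmf_fit(shifted.matrix[train_rows], k=k, iters=iters, seed=seed,
                    train_ids=list(train_ids))
    scores = np.zeros((shifted.n_cases, k))
    scores[train_rows] = model.train_scores
    test_rows = [i for i in range(shifted.n_cases) if i not in set(train_rows)]
    if test_rows:
        scores[test_rows] = nmf_transform(model, shifted.matrix[test_rows],
                                          iters=iters, seed=seed)
    p = prefix or block.family
    names = [f"{p}_nmf_{j:03d}" for j in range(k)]
    reduced = FeatureBlock(names=names, matrix=scores, family="reduced",
                           case_ids=list(shifted.case_ids))
    return reduced, model


def reduce_seg_latents(seg_full: FeatureBlock, seg_half: FeatureBlock, k: int,
                       train_ids, iters: int = 200, seed: int = 0,
                       joint: bool = False) -> FeatureBlock:
    """Reduce the two segmentation-encoder latent sets to a width-k block.

    Default: one NMF per source at k/2 components each, concatenated.  With
    ``joint=True`` a single NMF at k is fit on the column-concatenated raw
    matrices instead.
    """
    if joint:
        merged = concat_blocks([seg_full, seg_half], family="latent")
        reduced, _ = reduce_block(merged, k, train_ids, iters, seed, prefix="seg_joint")
        return reduced
    kf = max(1, k // 2)
    full_r, _ = reduce_block(seg_full, kf, train_ids, iters, seed, prefix="seg_full")
    half_r, _ = reduce_block(seg_half, k - kf, train_ids, iters, seed, prefix="seg_half")
    return concat_blocks([full_r, half_r], family="reduced")


INPUT_CONFIGURATION_NAMES = [
    "radiomics_all", "radiomics_shape", "latent_seg", "latent_vaegan",
    "latent_seg+vaegan", "radiomics+latents", "shape+latents",
]


@dataclass
class InputConfiguration:
    """One of the seven classifier input assemblies."""

    name: str
    blocks: list
    width: int = field(init=False)

    def __post_init__(self):
        if self.name not in INPUT_CONFIGURATION_NAMES:
            raise ValueError(f"unknown configuration {self.name!r}")
        self.width = sum(b.n_features for b in self.blocks)

    def matrix(self) -> FeatureBlock:
        if len(self.blocks) == 1:
            return self.blocks[0]
        return concat_blocks(self.blocks, family=self.name)


def build_input_configurations(radiomics_reduced: FeatureBlock,
                               shape_block: FeatureBlock,
                               seg_reduced: FeatureBlock,
                               vaegan_reduced: FeatureBlock) -> list:
    """Assemble the seven input configurations from reduced blocks.

    The shape block enters un-reduced (14 columns); ``seg_reduced`` is the
    (already concatenated) segmentation-encoder latent set of width k; widths are
    k, 14, k, k, 2k, 3k and 14+2k respectively.
    """
    ids = radiomics_reduced.case_ids
    for b in (shape_block, seg_reduced, vaegan_reduced):
        if b.case_ids != ids:
            raise ValueError("case sets/ordering differ across blocks")
    return [
        InputConfiguration("radiomics_all", [radiomics_reduced]),
        InputConfiguration("radiomics_shape", [shape_block]),
        InputConfiguration("latent_seg", [seg_reduced]),
        InputConfiguration("latent_vaegan", [vaegan_reduced]),
        InputConfiguration("latent_seg+vaegan", [seg_reduced, vaegan_reduced]),
        InputConfiguration("radiomics+latents",
                           [radiomics_reduced, seg_reduced, vaegan_reduced]),
        InputConfiguration("shape+latents", [shape_block, seg_reduced, vaegan_reduced]),
    ]
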
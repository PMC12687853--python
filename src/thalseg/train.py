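"""Data augmentation, the sparse-label masked Dice loss, and train schedules.

Supervision is sparse: raters labeled only high-confidence voxels, so label
volumes contain class ids 0–13 plus a sentinel value 100 marking
unlabeled-within-thalamus voxels. The Dice loss is computed exclusively over
the labeled voxel set; sentinel voxels contribute nothing to the loss or its
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import N_CLASSES, SENTINEL, UsageError, check_sparse_labels

__all__ = [
    "AugmentationConfig",
    "LossConfig",
    "TrainSchedule",
    "augment",
    "masked_dice_loss",
    "masked_dice_loss_and_grad",
    "train_model",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Spatial + intensity augmentation parameters (all stages disableable).

    Spatial stages apply jointly to image and labels (trilinear for the
    image, nearest-neighbor for labels): left-right flip with probability
    ``flip_prob``, an affine with per-axis rotations up to ±``rot_max_deg``,
    one isotropic scale in ``scale_range`` and per-axis translations within
    ``translate_max_vox`` voxels, then an elastic deformation from a B-spline
    grid of ``elastic_grid_points`` control points per axis with maximum
    displacement ``elastic_max_disp_vox``. Intensity augmentation is gamma
    correction with log-gamma uniform in ``log_gamma_range``, image only.
    """

    flip_prob: float = 0.5
    rot_max_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_max_vox: float = 5.0
    elastic_grid_points: int = 7
    elastic_max_disp_vox: float = 7.0
    log_gamma_range: tuple[float, float] = (-0.3, 0.3)

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls(
            flip_prob=0.0,
            rot_max_deg=0.0,
            scale_range=(1.0, 1.0),
            translate_max_vox=0.0,
            elastic_max_disp_vox=0.0,
            log_gamma_range=(0.0, 0.0),
        )


@dataclass(frozen=True)
class LossConfig:
    """Masked Dice loss parameters: stability epsilon and the class set size."""

    epsilon: float = 1e-5
    n_classes: int = N_CLASSES
    ignore_absent: bool = False

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise UsageError("epsilon must be positive")


@dataclass(frozen=True)
class TrainSchedule:
    """Optimization schedule.

    ``mode='crossval'``: reduce the learning rate by 10% after 5 epochs
    without validation improvement, stop early after 15, up to
    ``max_epochs``. ``mode='full'``: decay by 10% every 10 epochs and run
    exactly ``max_epochs`` epochs. Batch size is 1 throughout (volumetric
    inputs); ``max_steps`` optionally caps total gradient steps for
    desk-scale runs.
    """

    mode: str = "crossval"
    lr: float = 1e-3
    weight_decay: float = 1e-4
    max_epochs: int = 200
    plateau_patience: int = 5
    early_stop_patience: int = 15
    decay_every: int = 10
    decay_factor: float = 0.9
    seed: int = 1234
    crop_size: int = 96
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("crossval", "full"):
            raise UsageError("schedule mode must be 'crossval' or 'full'")


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _affine_matrices(cfg: AugmentationConfig, rng: np.random.Generator):
    deg = np.deg2rad(
        rng.uniform(-cfg.rot_max_deg, cfg.rot_max_deg, size=3)
        if cfg.rot_max_deg > 0
        else np.zeros(3)
    )
    lo, hi = cfg.scale_range
    scale = rng.uniform(lo, hi) if hi > lo else lo
    shift = (
        rng.uniform(-cfg.translate_max_vox, cfg.translate_max_vox, size=3)
        if cfg.translate_max_vox > 0
        else np.zeros(3)
    )
    cz, sz = np.cos(deg[0]), np.sin(deg[0])
    cy, sy = np.cos(deg[1]), np.sin(deg[1])
    cx, sx = np.cos(deg[2]), np.sin(deg[2])
    r0 = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    r1 = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    r2 = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    mat = (r0 @ r1 @ r2) * scale
    identity = scale == 1.0 and not deg.any() and not shift.any()
    return mat, shift, identity


def _elastic_field(shape, cfg: AugmentationConfig, rng: np.random.Generator):
    pts = cfg.elastic_grid_points
    ctrl = rng.uniform(
        -cfg.elastic_max_disp_vox, cfg.elastic_max_disp_vox, size=(3, pts, pts, pts)
    )
    disp = np.empty((3, *shape))
    zoom = [n / pts for n in shape]
    for ax in range(3):
        disp[ax] = ndimage.zoom(
            ctrl[ax], zoom, order=3, mode="nearest", grid_mode=True
        )
    return disp


def augment(
    image: np.ndarray,
    labels: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random augmentation draw jointly to image and labels.

    The same spatial transform is applied to both grids — trilinear
    interpolation for the image, nearest-neighbor for the labels, so no new
    label values can be created. Gamma correction touches the image only.
    Degenerate configurations collapse to the exact identity.
    """
    image = np.asarray(image, dtype=np.float64)
    labels = check_sparse_labels(labels)
    if image.shape != labels.shape:
        raise UsageError("image and labels must share a grid")

    if cfg.flip_prob > 0 and rng.random() < cfg.flip_prob:
        image = image[::-1].copy()
        labels = labels[::-1].copy()

    mat, shift, is_identity = _affine_matrices(cfg, rng)
    if not is_identity:
        center = (np.array(image.shape) - 1) / 2.0
        inv = np.linalg.inv(mat)
        offset = center - inv @ (center + shift)
        image = ndimage.affine_transform(image, inv, offset, order=1, mode="nearest")
        labels = ndimage.affine_transform(
            labels, inv, offset, order=0, mode="constant", cval=0
        )

    if cfg.elastic_max_disp_vox > 0:
        disp = _elastic_field(image.shape, cfg, rng)
        grid = np.indices(image.shape, dtype=np.float64)
        coords = grid + disp
        image = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
        labels = ndimage.map_coordinates(
            labels, coords, order=0, mode="constant", cval=0
        )

    lo, hi = cfg.log_gamma_range
    log_gamma = rng.uniform(lo, hi) if hi > lo else lo
    if log_gamma != 0.0:
        gamma = float(np.exp(log_gamma))
        peak = image.max()
        if peak > 0:
            image = np.clip(image, 0, None)
            image = peak * (image / peak) ** gamma

    return image, check_sparse_labels(labels)


# ---------------------------------------------------------------------------
# Masked Dice loss
# ---------------------------------------------------------------------------

def _dice_terms(probs, labels, cfg: LossConfig):
    probs = np.asarray(probs)
    labels = check_sparse_labels(labels)
    if probs.ndim != 4 or probs.shape[0] != cfg.n_classes:
        raise UsageError(f"expected ({cfg.n_classes}, D, H, W) probabilities")
    if probs.shape[1:] != labels.shape:
        raise UsageError("probability and label grids are misaligned")
    mask = labels != SENTINEL
    if not mask.any():
        raise UsageError("no labeled voxels: loss undefined")
    lab = labels[mask]
    p = probs[:, mask].astype(np.float64)  # (C, n_labeled)
    onehot = lab[None, :] == np.arange(cfg.n_classes)[:, None]
    inter = (p * onehot).sum(axis=1)
    psum = p.sum(axis=1)
    qsum = onehot.sum(axis=1)
    return p, onehot, mask, inter, psum, qsum


def masked_dice_loss(probs, labels, cfg: LossConfig = LossConfig()) -> float:
    """Mean class-wise soft Dice loss over labeled voxels only.

    ``L = 1 - (1/|C|) * sum_c 2*sum(p_c q_c) / (sum p_c + sum q_c + eps)``
    restricted to the labeled voxel set; the sentinel is excluded so
    predictions at unlabeled voxels never influence the loss. A class absent
    from the labeled voxels scores Dice 0 under this formula (it contributes
    maximally to the loss); ``ignore_absent=True`` averages over present
    classes instead.
    """
    _, _, _, inter, psum, qsum = _dice_terms(probs, labels, cfg)
    dice = 2.0 * inter / (psum + qsum + cfg.epsilon)
    if cfg.ignore_absent:
        present = qsum > 0
        return float(1.0 - dice[present].mean())
    return float(1.0 - dice.mean() )


def masked_dice_loss_and_grad(probs, labels, cfg: LossConfig = LossConfig()):
    """Loss value plus its analytic gradient w.r.t. the probability volume."""
    p, onehot, mask, inter, psum, qsum = _dice_terms(probs, labels, cfg)
    denom = psum + qsum + cfg.epsilon
    dice = 2.0 * inter / denom
    if cfg.ignore_absent:
        sel = qsum > 0
        n_eff = int(sel.sum())
    else:
        sel = np.ones_like(qsum, dtype=bool)
        n_eff = cfg.n_classes
    loss = float(1.0 - dice[sel].mean())
    # d(dice_c)/dp_c(x) = (2 q_c(x) * denom_c - 2 inter_c) / denom_c^2
    gsel = sel / n_eff
    gp = -(2.0 * onehot * denom[:, None] - 2.0 * inter[:, None]) / denom[:, None] ** 2
    gp *= gsel[:, None]
    grad = np.zeros_like(np.asarray(probs), dtype=np.float64)
    grad[:, mask] = gp
    return loss, grad


# ---------------------------------------------------------------------------
# Training entry point (thin wrapper over the estimator)
# ---------------------------------------------------------------------------

def train_model(
    dataset,
    net_cfg=None,
    sched: TrainSchedule = TrainSchedule(mode="full"),
    aug: AugmentationConfig | None = None,
    val_dataset=None,
):
    """Train the coordinate-aware U-Net on (image, sparse-label) pairs.

    Thin wrapper over :class:`thalseg.estimators.ThalamicNucleiSegmenter`;
    returns the fitted estimator, whose ``history_`` records the executed
    schedule (epoch, lr, train loss, val loss) and whose ``net_`` holds the
    final weights.
    """
    from .estimators import ThalamicNucleiSegmenter
    from .model import NetworkConfig

    net_cfg = net_cfg or NetworkConfig()
    est = ThalamicNucleiSegmenter(
        levels=net_cfg.levels,
        base_width=net_cfg.base_width,
        mode=sched.mode,
        lr=sched.lr,
        weight_decay=sched.weight_decay,
        max_epochs=sched.max_epochs,
        plateau_patience=sched.plateau_patience,
        early_stop_patience=sched.early_stop_patience,
        decay_every=sched.decay_every,
        decay_factor=sched.decay_factor,
        crop_size=sched.crop_size,
        max_steps=sched.max_steps,
        augmentation=aug,
        seed=sched.seed,
    )
    images = [im for im, _ in dataset]
    labels = [lb for _, lb in dataset]
    if val_dataset is not None:
        val_dataset = (
            [im for im, _ in val_dataset],
            [lb for _, lb in val_dataset],
        )
    est.fit(images, labels, validation=val_dataset)
    return est
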
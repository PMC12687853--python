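"""scikit-learn style estimator hosting the segmentation training loop.

:class:`ThalamicNucleiSegmenter` is the trainable core of the package: it
fits the coordinate-aware 3D U-Net to (image, sparse-label) pairs with the
masked Dice loss and Adam, and predicts hard 14-class segmentations with the
inference pipeline (center-crop, coordinate channels, forward pass, argmax,
pad back). It follows the scikit-learn estimator contract — ``get_params`` /
``set_params``, fitted attributes with a trailing underscore, ``fit`` /
``predict`` / ``score`` — so it composes with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import CoordUNet3D, NetworkConfig, build_coord_channels
from .preprocess import center_crop, crop_slices, pad_back
from .train import (
    AugmentationConfig,
    LossConfig,
    TrainSchedule,
    augment,
    masked_dice_loss,
    masked_dice_loss_and_grad,
)
from ._nn import Adam
from .types import UsageError, check_sparse_labels

__all__ = ["ThalamicNucleiSegmenter", "predict_volume"]


def predict_volume(image: np.ndarray, net: CoordUNet3D, crop_size: int):
    """Inference for one volume: crop → coords → forward → argmax → pad back.

    Returns ``(hard_segmentation, probabilities)`` at the original extent;
    voxels outside the crop window are background 0 in the segmentation and
    carry background probability 1. Argmax ties break toward the lower class
    index (``numpy.argmax`` convention).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise UsageError("expected a 3D volume")
    size = tuple(min(crop_size, n) for n in image.shape)
    divisor = 2**net.cfg.levels
    if any(n % divisor for n in size):
        raise UsageError(
            f"crop extents {size} must be divisible by 2^levels={divisor}"
        )
    cropped = center_crop(image, size)
    probs_crop = net.predict_probs(cropped)
    seg_crop = np.argmax(probs_crop, axis=0).astype(np.int16)
    seg = pad_back(seg_crop, image.shape, fill=0)
    probs = np.zeros((probs_crop.shape[0], *image.shape), dtype=probs_crop.dtype)
    probs[0] = 1.0
    sl = crop_slices(image.shape, size)
    probs[(slice(None),) + sl] = probs_crop
    return seg, probs


class ThalamicNucleiSegmenter(BaseEstimator):
    """Coordinate-aware 3D U-Net segmenter for sparse-labeled thalamic nuclei.

    Parameters
    ----------
    levels, base_width : int
        U-Net depth (pooling stages) and first-level channel width.
    mode : {'crossval', 'full'}
        Learning-rate schedule: plateau-based reduction with early stopping
        (requires validation data), or fixed decay every ``decay_every``
        epochs for exactly ``max_epochs`` epochs.
    lr, weight_decay : float
        Adam initial learning rate and L2 weight decay.
    crop_size : int
        Center-crop extent fed to the network (96 covers the thalamus in
        template space; smaller crops serve desk-scale data).
    max_steps : int or None
        Optional cap on total gradient steps, for reduced-scale runs.
    augmentation : AugmentationConfig or None
        ``None`` enables the default augmentation; pass
        ``AugmentationConfig.identity()`` to disable.
    epsilon, ignore_absent
        Masked-Dice-loss settings.
    seed : int
        Seeds weight initialisation, augmentation and data ordering.

    Attributes
    ----------
    net_ : CoordUNet3D
        The trained network.
    history_ : list of dict
        Per-epoch records: epoch, lr, train_loss, val_loss.
    n_steps_ : int
        Total gradient steps executed.
    """

    def __init__(
        self,
        levels: int = 4,
        base_width: int = 16,
        mode: str = "crossval",
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        max_epochs: int = 200,
        plateau_patience: int = 5,
        early_stop_patience: int = 15,
        decay_every: int = 10,
        decay_factor: float = 0.9,
        crop_size: int = 96,
        max_steps: int | None = None,
        augmentation: AugmentationConfig | None = None,
        epsilon: float = 1e-5,
        ignore_absent: bool = False,
        seed: int = 1234,
    ):
        self.levels = levels
        self.base_width = base_width
        self.mode = mode
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.decay_every = decay_every
        self.decay_factor = decay_factor
        self.crop_size = crop_size
        self.max_steps = max_steps
        self.augmentation = augmentation
        self.epsilon = epsilon
        self.ignore_absent = ignore_absent
        self.seed = seed

    # ------------------------------------------------------------------
    def _prepare_pair(self, image, labels, aug_cfg, rng):
        if aug_cfg is not None:
            image, labels = augment(image, labels, aug_cfg, rng)
        size = tuple(min(self.crop_size, n) for n in np.asarray(image).shape)
        image = center_crop(np.asarray(image, dtype=np.float64), size)
        labels = center_crop(check_sparse_labels(labels), size)
        return image, labels

    def _loss_cfg(self) -> LossConfig:
        return LossConfig(epsilon=self.epsilon, ignore_absent=self.ignore_absent)

    def fit(self, X, y, validation=None):
        """Train on lists of 3D images ``X`` and sparse label grids ``y``.

        ``validation`` is an optional ``(images, labels)`` pair required by
        the ``'crossval'`` schedule, evaluated with center cropping only.
        """
        TrainSchedule(mode=self.mode)  # validates the mode string
        if len(X) != len(y) or len(X) == 0:
            raise UsageError("need >= 1 (image, labels) training pair")
        if self.mode == "crossval" and validation is None:
            raise UsageError("'crossval' schedule requires validation data")
        aug_cfg = (
            AugmentationConfig() if self.augmentation is None else self.augmentation
        )
        rng = np.random.default_rng(self.seed)
        net = CoordUNet3D(
            NetworkConfig(levels=self.levels, base_width=self.base_width),
            rng=np.random.default_rng(self.seed),
        )
        params = net.named_params()
        opt = Adam(params, lr=self.lr, weight_decay=self.weight_decay)
        loss_cfg = self._loss_cfg()

        history: list[dict] = []
        best_val = np.inf
        plateau = 0
        since_best = 0
        n_steps = 0
        stop = False
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(X))
            epoch_losses = []
            for idx in order:
                image, labels = self._prepare_pair(X[idx], y[idx], aug_cfg, rng)
                coords = build_coord_channels(image.shape)
                inp = np.concatenate(
                    [image[None].astype(np.float32), coords], axis=0
                )
                probs = net.forward(inp)
                loss, gprobs = masked_dice_loss_and_grad(probs, labels, loss_cfg)
                net.zero_grad()
                net.backward(gprobs)
                opt.step(net.named_grads())
                epoch_losses.append(loss)
                n_steps += 1
                if self.max_steps is not None and n_steps >= self.max_steps:
                    stop = True
                    break
            val_loss = None
            if validation is not None:
                val_losses = []
                for vim, vlb in zip(*validation):
                    vim_c, vlb_c = self._prepare_pair(vim, vlb, None, rng)
                    vprobs = net.predict_probs(vim_c)
                    val_losses.append(masked_dice_loss(vprobs, vlb_c, loss_cfg))
                val_loss = float(np.mean(val_losses))
            history.append(
                {
                    "epoch": epoch,
                    "lr": opt.lr,
                    "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss,
                }
            )
            if stop:
                break
            if self.mode == "full":
                if epoch % self.decay_every == 0:
                    opt.lr *= self.decay_factor
            else:
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    plateau = 0
                    since_best = 0
                else:
                    plateau += 1
                    since_best += 1
                    if plateau >= self.plateau_patience:
                        opt.lr *= self.decay_factor
                        plateau = 0
                    if since_best >= self.early_stop_patience:
                        break
        self.net_ = net
        self.history_ = history
        self.n_steps_ = n_steps
        return self

    def predict(self, X):
        """Hard segmentations (original extents) for a list of 3D images."""
        self._check_fitted()
        return [predict_volume(im, self.net_, self.crop_size)[0] for im in X]

    def predict_proba(self, X):
        """14-channel probability volumes for a list of 3D images."""
        self._check_fitted()
        return [predict_volume(im, self.net_, self.crop_size)[1] for im in X]

    def score(self, X, y):
        """Mean volume-weighted-average TPR against sparse labels."""
        from .metrics import vwa_tpr

        self._check_fitted()
        return float(np.mean([vwa_tpr(p, t) for p, t in zip(self.predict(X), y)]))

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise UsageError("estimator is not fitted; call fit first")
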
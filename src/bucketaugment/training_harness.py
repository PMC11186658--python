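"""Segmentation training loop with the augmentation controller inside.

The harness is model-agnostic: any object implementing the
:class:`TrainerContract` protocol (``fit_step`` / ``validate`` /
``predict``) can be trained. Preprocessing follows the usual CT pipeline —
per-sample min-max intensity normalization to [0, 1] and non-overlapping
cubic patching — and evaluation uses the Sørensen–Dice coefficient.
Training loss is the unweighted sum of soft-Dice and cross-entropy.

In ``bucketaugment`` mode the controller's current bucket augments every
training patch; every K epochs a validation pass produces a loss that
updates the Q-table and possibly advances the bucket. ``trivialaugment``
mode applies one random transform per patch with no controller; ``none``
passes patches through untouched. Validation and test sets are never
augmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .bucket_space import SearchSpace, apply_bucket, init_search_space, sample_trivial
from .qcontroller import init_controller, observe_validation
from .transforms3d import VolumePatch

AUGMENTATION_MODES = ("none", "bucketaugment", "trivialaugment")


@dataclass(frozen=True)
class TrainConfig:
    n_buckets: int = 10
    n_ops: int = 5
    val_every_k_epochs: int = 1
    epochs: int = 10
    patch_size: tuple[int, int, int] = (96, 96, 96)
    seed: int = 0
    batch_size: int = 2
    augmentation_mode: str = "bucketaugment"

    def __post_init__(self) -> None:
        for name in ("n_buckets", "n_ops", "val_every_k_epochs", "epochs",
                     "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(p < 1 for p in self.patch_size):
            raise ValueError("patch_size entries must be positive")
        if self.augmentation_mode not in AUGMENTATION_MODES:
            raise ValueError(
                f"augmentation_mode must be one of {AUGMENTATION_MODES}, "
                f"got {self.augmentation_mode!r}"
            )


@runtime_checkable
class TrainerContract(Protocol):
    """Minimal contract a pluggable segmentation model must satisfy."""

    def fit_step(self, batch: list[VolumePatch]) -> float:
        """Consume a batch of patches, take one optimization step, return
        the training loss."""

    def validate(self, val_set: list[VolumePatch]) -> float:
        """Return a scalar validation loss; deterministic for fixed model
        state and data."""

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Return an integer label grid for one image patch."""


@dataclass(frozen=True)
class ValidationLogEntry:
    epoch: int
    val_loss: float
    reward: int
    bucket: int


# ---------------------------------------------------------------------------
# preprocessing


def normalize_volume(raw_image: np.ndarray) -> np.ndarray:
    """Per-sample min-max rescale of acquisition-unit intensities to [0, 1]."""
    raw_image = np.asarray(raw_image, dtype=np.float64)
    if not np.all(np.isfinite(raw_image)):
        raise ValueError("raw image contains non-finite values")
    lo, hi = raw_image.min(), raw_image.max()
    if lo == hi:
        raise ValueError("constant volume has zero dynamic range")
    return (raw_image - lo) / (hi - lo)


def patchify(volume: VolumePatch,
             patch_size: tuple[int, int, int]) -> list[VolumePatch]:
    """Zero-pad each axis up to a multiple of patch_size and tile without
    overlap; every output patch has exactly patch_size shape."""
    if any(p < 1 for p in patch_size):
        raise ValueError("patch_size entries must be positive")
    shape = volume.image.shape
    padded_shape = tuple(-(-s // p) * p for s, p in zip(shape, patch_size))
    pad = [(0, ps - s) for s, ps in zip(shape, padded_shape)]
    image = np.pad(volume.image, pad, mode="constant")
    label = np.pad(volume.label, pad, mode="constant")

    patches = []
    for i in range(0, padded_shape[0], patch_size[0]):
        for j in range(0, padded_shape[1], patch_size[1]):
            for k in range(0, padded_shape[2], patch_size[2]):
                sl = (slice(i, i + patch_size[0]),
                      slice(j, j + patch_size[1]),
                      slice(k, k + patch_size[2]))
                patches.append(VolumePatch(image[sl].copy(), label[sl].copy(),
                                           volume.spacing))
    return patches


def unpatchify(patches: list[VolumePatch], original_shape: tuple[int, int, int],
               patch_size: tuple[int, int, int]) -> VolumePatch:
    """Inverse of :func:`patchify`: reassemble the tiling and crop the
    zero padding."""
    padded_shape = tuple(-(-s // p) * p
                         for s, p in zip(original_shape, patch_size))
    image = np.zeros(padded_shape)
    label = np.zeros(padded_shape, dtype=patches[0].label.dtype)
    idx = 0
    for i in range(0, padded_shape[0], patch_size[0]):
        for j in range(0, padded_shape[1], patch_size[1]):
            for k in range(0, padded_shape[2], patch_size[2]):
                sl = (slice(i, i + patch_size[0]),
                      slice(j, j + patch_size[1]),
                      slice(k, k + patch_size[2]))
                image[sl] = patches[idx].image
                label[sl] = patches[idx].label
                idx += 1
    crop = tuple(slice(0, s) for s in original_shape)
    return VolumePatch(image[crop], label[crop], patches[0].spacing)


# ---------------------------------------------------------------------------
# metrics and loss


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|) between binary masks;
    1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def dice_ce_loss(pred_probabilities: np.ndarray, truth: np.ndarray,
                 eps: float = 1e-7) -> float:
    """Unweighted sum of soft-Dice loss and voxel-mean cross-entropy.

    ``pred_probabilities`` has shape (C, *spatial) and must be normalized
    over the class axis; ``truth`` is an integer label grid.
    """
    probs = np.asarray(pred_probabilities, dtype=np.float64)
    truth = np.asarray(truth)
    if probs.ndim != truth.ndim + 1 or probs.shape[1:] != truth.shape:
        raise ValueError(
            f"probabilities shape {probs.shape} does not match truth "
            f"shape {truth.shape}"
        )
    sums = probs.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("class probabilities must sum to 1 per voxel")

    n_classes = probs.shape[0]
    onehot = np.stack([(truth == c) for c in range(n_classes)]).astype(np.float64)

    # soft Dice averaged over classes; empty class with empty prediction -> 1
    inter = (probs * onehot).sum(axis=tuple(range(1, probs.ndim)))
    denom = probs.sum(axis=tuple(range(1, probs.ndim))) + onehot.sum(
        axis=tuple(range(1, probs.ndim)))
    soft_dice = np.where(denom > 0, 2.0 * inter / np.maximum(denom, eps), 1.0)
    dice_loss = 1.0 - soft_dice.mean()

    p_true = np.take_along_axis(probs, truth[np.newaxis].astype(np.int64),
                                axis=0)[0]
    ce = float(-np.log(np.clip(p_true, eps, 1.0)).mean())
    return float(dice_loss + ce)


# ---------------------------------------------------------------------------
# built-in test model


class GaussianFeatureSegmenter:
    """Tiny voxelwise softmax segmenter over multi-scale Gaussian features.

    A deliberately small, CPU-fast, fully deterministic model used as the
    harness's built-in test fixture: each voxel is described by its raw
    intensity plus Gaussian-smoothed intensities at two scales, and a
    linear softmax over those features is fit by gradient descent on the
    Dice + cross-entropy objective. It segments intensity-separable
    structures (such as the synthetic phantoms) but is explicitly not a
    deep segmentation network; real experiments plug in any
    TrainerContract implementation.
    """

    SIGMAS = (1.0, 2.0)

    def __init__(self, n_classes: int = 3, lr: float = 2.0, seed: int = 0):
        self.n_classes = n_classes
        self.lr = lr
        rng = np.random.default_rng(seed)
        n_features = 2 + len(self.SIGMAS)  # bias + raw + smoothed scales
        self.weights = rng.normal(0.0, 0.01, size=(n_classes, n_features))

    def _features(self, image: np.ndarray) -> np.ndarray:
        feats = [np.ones_like(image), image]
        feats += [ndimage.gaussian_filter(image, s) for s in self.SIGMAS]
        return np.stack(feats)  # (F, *spatial)

    def _forward(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        feats = self._features(image)
        logits = np.tensordot(self.weights, feats, axes=(1, 0))
        logits -= logits.max(axis=0, keepdims=True)
        exp = np.exp(logits)
        return exp / exp.sum(axis=0, keepdims=True), feats

    def fit_step(self, batch: list[VolumePatch]) -> float:
        total_loss = 0.0
        grad = np.zeros_like(self.weights)
        for patch in batch:
            probs, feats = self._forward(patch.image)
            total_loss += dice_ce_loss(probs, patch.label)
            onehot = np.stack([(patch.label == c)
                               for c in range(self.n_classes)]).astype(float)
            # cross-entropy gradient with inverse-frequency voxel weights,
            # otherwise the background swamps the small foreground classes;
            # the Dice term shares this descent direction for a voxelwise model
            counts = onehot.sum(axis=tuple(range(1, onehot.ndim)))
            class_w = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0)
            voxel_w = np.tensordot(class_w, onehot, axes=(0, 0))
            voxel_w /= max(voxel_w.sum(), 1e-12)
            err = (probs - onehot) * voxel_w  # (C, *spatial)
            grad += np.tensordot(err, feats,
                                 axes=(tuple(range(1, err.ndim)),
                                       tuple(range(1, feats.ndim))))
        self.weights -= self.lr * grad / len(batch)
        return total_loss / len(batch)

    def validate(self, val_set: list[VolumePatch]) -> float:
        losses = [dice_ce_loss(self._forward(p.image)[0], p.label)
                  for p in val_set]
        return float(np.mean(losses))

    def predict(self, image: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(image, dtype=np.float64))
        return probs.argmax(axis=0).astype(np.int16)


# ---------------------------------------------------------------------------
# training and evaluation


def train(
    dataset: list[VolumePatch],
    val_set: list[VolumePatch],
    trainer: TrainerContract,
    config: TrainConfig,
    search_space: SearchSpace | None = None,
):
    """Run the training loop with the configured augmentation policy.

    Returns ``(trainer, controller_state, log)`` where ``log`` is one
    :class:`ValidationLogEntry` per validation pass (``floor(epochs / K)``
    of them). The controller and search space are only active in
    ``bucketaugment`` mode; in the other modes the returned controller
    state has an empty history.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    if len(val_set) == 0:
        raise ValueError("validation set is empty")

    mode = config.augmentation_mode
    if search_space is None and mode == "bucketaugment":
        search_space = init_search_space(config.n_buckets, config.n_ops,
                                         config.seed)
    n_buckets = search_space.n_buckets if search_space else config.n_buckets
    controller = init_controller(n_buckets, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    log: list[ValidationLogEntry] = []

    for epoch in range(1, config.epochs + 1):
        if mode == "bucketaugment":
            bucket = search_space.buckets[controller.current]
            epoch_patches = [apply_bucket(p, bucket, rng) for p in dataset]
        elif mode == "trivialaugment":
            epoch_patches = [sample_trivial(p, rng) for p in dataset]
        else:
            epoch_patches = dataset

        for start in range(0, len(epoch_patches), config.batch_size):
            trainer.fit_step(epoch_patches[start:start + config.batch_size])

        if epoch % config.val_every_k_epochs == 0:
            val_loss = float(trainer.validate(val_set))
            if mode == "bucketaugment":
                applied = controller.current
                controller, reward = observe_validation(controller, val_loss)
            else:
                applied, reward = -1, 0
            log.append(ValidationLogEntry(epoch=epoch, val_loss=val_loss,
                                          reward=reward, bucket=applied))

    return trainer, controller, log


def evaluate_dice(trainer: TrainerContract,
                  test_set: list[VolumePatch]) -> dict[int, float]:
    """Mean per-class Dice between predictions and truth over a test set.

    Classes are the union of foreground ids present in the truth; per
    volume, a class absent from both prediction and truth scores 1.
    """
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    classes = sorted(
        {int(c) for p in test_set for c in np.unique(p.label) if c != 0}
    )
    scores: dict[int, list[float]] = {c: [] for c in classes}
    for patch in test_set:
        pred = trainer.predict(patch.image)
        for c in classes:
            scores[c].append(dice_score(pred == c, patch.label == c))
    return {c: float(np.mean(v)) for c, v in scores.items()}
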
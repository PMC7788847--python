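"""Phalange segmentation: trainable encoder-decoder, classical baseline, QC.

The learned segmenter (:class:`UNetSegmenter`) and the intensity-threshold
baseline (:class:`ThresholdBoneSegmenter`) are scikit-learn style estimators:
hyperparameters in ``__init__``, ``fit(X, y)``, ``predict(X)``, fitted state
in trailing-underscore attributes. ``X`` is a stack of images with shape
``(n, H, W)`` (or a list of :class:`~calciquant.grids.ImageGrid`), ``y`` the
matching stack of boolean bone masks.

Also here: the Dice overlap statistic, an epoch-sweep helper that replaces
eyeballing successive training runs with a validation-Dice plateau rule, and
:func:`check_visibility`, which flags images whose phalanges are incompletely
visualised (too few bone components, or bone clipped by the image border) —
such images must be excluded from lesion quantification and counted as
failures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from ._unet import Adam, UNet, bce_dice_loss, sigmoid
from .grids import BinaryMask, ImageGrid

__all__ = [
    "TrainConfig",
    "UNetSegmenter",
    "ThresholdBoneSegmenter",
    "VisibilityReport",
    "EpochSweepResult",
    "DivergenceError",
    "train_segmenter",
    "epoch_sweep",
    "segment_bone",
    "classical_segment_bone",
    "check_visibility",
    "dice",
]

_EIGHT = np.ones((3, 3), dtype=int)


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; carries the offending epoch."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for the encoder-decoder segmenter.

    The epoch count is deliberately a configuration value with a small
    default: full-scale runs (hundreds of epochs) remain available but are
    not needed for the bundled phantoms.
    """

    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 8
    depth: int = 3
    base_channels: int = 8
    loss: str = "sum"  # "dice" | "cross-entropy" | "sum"
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass(frozen=True)
class VisibilityReport:
    """Phalange-visibility QC verdict for one bone mask."""

    n_components: int
    components_touching_border: int
    complete: bool


def _as_image_stack(X) -> tuple[np.ndarray, float | None]:
    """Accept (n,H,W) array or list of ImageGrid; return float array + spacing."""
    if isinstance(X, np.ndarray):
        if X.ndim != 3:
            raise ValueError("X must have shape (n_images, height, width)")
        return X.astype(np.float64), None
    imgs = list(X)
    if not imgs:
        raise ValueError("empty image list")
    if isinstance(imgs[0], ImageGrid):
        arr = np.stack([im.pixels for im in imgs])
        return arr, imgs[0].spacing
    return np.stack([np.asarray(im, dtype=np.float64) for im in imgs]), None


def _as_mask_stack(y) -> np.ndarray:
    if isinstance(y, np.ndarray):
        if y.ndim != 3:
            raise ValueError("y must have shape (n_images, height, width)")
        return y.astype(bool)
    masks = list(y)
    if masks and isinstance(masks[0], BinaryMask):
        return np.stack([m.pixels for m in masks])
    return np.stack([np.asarray(m, dtype=bool) for m in masks])


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    pa = a.pixels if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    pb = b.pixels if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    denom = int(pa.sum()) + int(pb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / denom


class UNetSegmenter(BaseEstimator):
    """Trainable encoder-decoder bone segmenter (scikit-learn estimator API).

    Parameters mirror :class:`TrainConfig`; ``threshold`` is the probability
    cut applied by :meth:`predict`. Input images are z-scored with statistics
    learned at fit time and reflect-padded to a multiple of ``2**depth``.

    Attributes (after ``fit``)
    --------------------------
    net_ : the trained network
    val_dice_ : float | None
        Mean Dice on the held-out validation split, or None when
        ``validation_fraction`` yields zero validation images.
    history_ : list of per-epoch mean training losses
    provenance_ : dict with config, dataset fingerprint, and val_dice
    """

    def __init__(
        self,
        epochs: int = 30,
        learning_rate: float = 1e-3,
        batch_size: int = 8,
        depth: int = 3,
        base_channels: int = 8,
        loss: str = "sum",
        validation_fraction: float = 0.15,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.depth = depth
        self.base_channels = base_channels
        self.loss = loss
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _pad(self, arr: np.ndarray) -> np.ndarray:
        mult = 2**self.depth
        h, w = arr.shape[-2:]
        ph = (-h) % mult
        pw = (-w) % mult
        if ph == 0 and pw == 0:
            return arr
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        return np.pad(arr, pad, mode="reflect")

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            depth=self.depth,
            base_channels=self.base_channels,
            loss=self.loss,
            validation_fraction=self.validation_fraction,
            seed=self.seed,
        )

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y) -> "UNetSegmenter":
        cfg = self._config()  # validates hyperparameters
        imgs, _ = _as_image_stack(X)
        masks = _as_mask_stack(y)
        if imgs.shape != masks.shape:
            raise ValueError(f"image stack {imgs.shape} and mask stack {masks.shape} differ")
        n = imgs.shape[0]
        if n == 0:
            raise ValueError("empty dataset")

        self.norm_mean_ = float(imgs.mean())
        self.norm_std_ = float(imgs.std()) or 1.0
        xs = self._pad((imgs - self.norm_mean_) / self.norm_std_)[:, None]
        ys = self._pad(masks.astype(np.float64))[:, None]
        self._orig_shape_ = imgs.shape[1:]

        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(n)
        n_val = int(np.floor(n * cfg.validation_fraction))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = order, order[:0]

        self.net_ = UNet(depth=cfg.depth, base_channels=cfg.base_channels, seed=cfg.seed)
        opt = Adam(self.net_, lr=cfg.learning_rate)
        self.history_ = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(perm), cfg.batch_size):
                batch = perm[start : start + cfg.batch_size]
                logits = self.net_.forward(xs[batch])
                loss_val, dl = bce_dice_loss(logits, ys[batch], cfg.loss)
                if not np.isfinite(loss_val):
                    raise DivergenceError(epoch + 1)
                self.net_.backward(dl)
                opt.step()
                losses.append(loss_val)
            self.history_.append(float(np.mean(losses)))

        if len(val_idx) > 0:
            scores = []
            for i in val_idx:
                prob = sigmoid(self.net_.forward(xs[i : i + 1]))[0, 0]
                pred = prob >= self.threshold
                h, w = self._orig_shape_
                scores.append(dice(pred[:h, :w], masks[i]))
            self.val_dice_ = float(np.mean(scores))
        else:
            self.val_dice_ = None

        fp = hashlib.sha256()
        fp.update(imgs.tobytes())
        fp.update(masks.tobytes())
        self.provenance_ = {
            "config": dataclasses.asdict(cfg),
            "dataset_sha256": fp.hexdigest(),
            "n_train": int(len(train_idx)),
            "n_val": int(len(val_idx)),
            "val_dice": self.val_dice_,
        }
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities, shape (n, H, W)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not fitted")
        imgs, _ = _as_image_stack(X)
        xs = self._pad((imgs - self.norm_mean_) / self.norm_std_)[:, None]
        h, w = imgs.shape[1:]
        out = np.empty((imgs.shape[0], h, w))
        for start in range(0, imgs.shape[0], max(self.batch_size, 1)):
            chunk = xs[start : start + max(self.batch_size, 1)]
            prob = sigmoid(self.net_.forward(chunk))[:, 0]
            out[start : start + chunk.shape[0]] = prob[:, :h, :w]
        return out

    def predict(self, X) -> np.ndarray:
        """Boolean bone masks, shape (n, H, W)."""
        return self.predict_proba(X) >= self.threshold

    def score(self, X, y) -> float:
        """Mean Dice against reference masks."""
        masks = _as_mask_stack(y)
        preds = self.predict(X)
        return float(np.mean([dice(p, m) for p, m in zip(preds, masks)]))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters plus JSON provenance."""
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not fitted")
        arrays = {f"p{i:03d}": a for i, a in enumerate(self.net_.state_arrays())}
        meta = {
            "params": self.get_params(),
            "norm_mean": self.norm_mean_,
            "norm_std": self.norm_std_,
            "provenance": self.provenance_,
            "history": self.history_,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = [data[k] for k in sorted(k for k in data.files if k.startswith("p"))]
        est = cls(**meta["params"])
        est.net_ = UNet(depth=est.depth, base_channels=est.base_channels, seed=est.seed)
        est.net_.load_state_arrays(arrays)
        est.norm_mean_ = meta["norm_mean"]
        est.norm_std_ = meta["norm_std"]
        est.provenance_ = meta["provenance"]
        est.history_ = meta["history"]
        est.val_dice_ = meta["provenance"]["val_dice"]
        return est


class ThresholdBoneSegmenter(BaseEstimator):
    """Classical baseline: global threshold, component filtering, hole fill.

    ``fit`` is a no-op (present for pipeline compatibility); the estimator is
    fully specified by its two parameters. Useful as a CPU-trivial oracle on
    phantoms whose bone intensity is separable from everything else.
    """

    def __init__(self, intensity_threshold: float = 600.0, min_region_px: int = 20):
        self.intensity_threshold = intensity_threshold
        self.min_region_px = min_region_px

    def fit(self, X=None, y=None) -> "ThresholdBoneSegmenter":
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be >= 1")
        self.fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be >= 1")
        imgs, _ = _as_image_stack(X)
        out = np.empty(imgs.shape, dtype=bool)
        for i, img in enumerate(imgs):
            raw = img >= self.intensity_threshold
            labels, n = ndimage.label(raw, structure=_EIGHT)
            if n:
                sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
                keep = np.flatnonzero(sizes >= self.min_region_px) + 1
                raw = np.isin(labels, keep)
            out[i] = ndimage.binary_fill_holes(raw)
        return out


# ---------------------------------------------------------------------------
# Functional wrappers over the estimators (the module-level spec surface).
# ---------------------------------------------------------------------------


def train_segmenter(
    dataset: list[tuple[ImageGrid, BinaryMask]], config: TrainConfig
) -> UNetSegmenter:
    """Fit a :class:`UNetSegmenter` on (image, bone mask) pairs."""
    if not dataset:
        raise ValueError("empty dataset")
    images = [im for im, _ in dataset]
    masks = [mk for _, mk in dataset]
    for im, mk in dataset:
        mk.check_aligned(im)
    est = UNetSegmenter(**dataclasses.asdict(config))
    return est.fit(images, masks)


@dataclass(frozen=True)
class EpochSweepResult:
    """Outcome of an epoch sweep: per-grid-point Dice and a recommendation."""

    table: pd.DataFrame  # columns: epochs, val_dice
    recommended_epochs: int
    plateau_tolerance: float


def epoch_sweep(
    dataset: list[tuple[ImageGrid, BinaryMask]],
    config: TrainConfig,
    epoch_grid: list[int],
    plateau_tolerance: float = 0.005,
) -> EpochSweepResult:
    """Train once per epoch count and recommend the cheapest adequate one.

    The recommendation is the smallest epoch count whose validation Dice is
    within ``plateau_tolerance`` of the sweep maximum — an automated,
    reproducible stand-in for visually comparing successive training runs.
    """
    if len(epoch_grid) == 0:
        raise ValueError("epoch_grid must be non-empty")
    if list(epoch_grid) != sorted(epoch_grid):
        raise ValueError("epoch_grid must be sorted ascending")
    rows = []
    for e in epoch_grid:
        model = train_segmenter(dataset, dataclasses.replace(config, epochs=int(e)))
        if model.val_dice_ is None:
            raise ValueError("epoch_sweep requires a non-empty validation split")
        rows.append({"epochs": int(e), "val_dice": model.val_dice_})
    table = pd.DataFrame(rows)
    best = table["val_dice"].max()
    ok = table[table["val_dice"] >= best - plateau_tolerance]
    recommended = int(ok["epochs"].min())
    return EpochSweepResult(table=table, recommended_epochs=recommended, plateau_tolerance=plateau_tolerance)


def segment_bone(image: ImageGrid, model: UNetSegmenter, threshold: float = 0.5) -> BinaryMask:
    """Segment phalanges in one image with a trained model."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    prob = model.predict_proba([image])[0]
    return BinaryMask(prob >= threshold, image.spacing)


def classical_segment_bone(
    image: ImageGrid, intensity_threshold: float, min_region_px: int = 20
) -> BinaryMask:
    """Threshold-based bone segmentation (components filtered, holes filled)."""
    est = ThresholdBoneSegmenter(intensity_threshold, min_region_px).fit()
    return BinaryMask(est.predict([image])[0], image.spacing)


def check_visibility(
    bone_mask: BinaryMask, expected_components: int = 3, border_margin_px: int = 1
) -> VisibilityReport:
    """Decide whether the phalanges are completely visualised.

    ``complete`` requires at least ``expected_components`` 8-connected bone
    components and none of them intersecting the ``border_margin_px``-wide
    image border. Quantification must skip incomplete images and record them
    as failures.
    """
    if expected_components < 1:
        raise ValueError("expected_components must be >= 1")
    labels, n = ndimage.label(bone_mask.pixels, structure=_EIGHT)
    h, w = labels.shape
    m = border_margin_px
    border = np.zeros((h, w), dtype=bool)
    if m > 0:
        border[:m, :] = border[-m:, :] = True
        border[:, :m] = border[:, -m:] = True
    touching = len(np.unique(labels[border & (labels > 0)]))
    complete = (n >= expected_components) and touching == 0
    return VisibilityReport(n_components=int(n), components_touching_border=int(touching), complete=complete)
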
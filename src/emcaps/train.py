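"""Optional trainable per-pixel segmentation engine (desk scale).

A deliberately small stand-in for a full encoder-decoder network: a
multinomial logistic regression over hand-crafted per-pixel features
(normalized intensity, two Gaussian-smoothed copies, and the six
matched-filter correlation maps), trained by SGD on pixels sampled from
the training stripes of a simulated dataset manifest.  It satisfies the
same ``predict`` contract as the matched-filter engine and exists so
that the training/checkpoint-selection recipe (epoch loop, validation
loss, best-checkpoint selection) has a concrete, dependency-light
implementation; it is never required by the reference pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.linear_model import SGDClassifier

from .core import PixelScale, class_templates
from .segment import N_CHANNELS, MatchedFilterEngine, normalize_percentile

__all__ = ["TrainingConfig", "TrainedPixelEngine", "train_pixel_classifier",
           "dice_bce_loss"]

#: Desk-scale safety caps (override with ``allow_full_scale=True``).
DESK_MAX_EPOCHS = 50
DESK_MAX_CROP = 256


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyper-parameters.

    The reference recipe is 3000 epochs, initial learning rate 1e-2,
    batch size 2 with 20 random 512 px crops per batch item, dropout
    0.1, mish activation, and an equally weighted soft-Dice +
    binary-cross-entropy loss; the desk-scale profile caps epochs at 50
    and crops at 256 px so the engine trains in seconds on one CPU.
    """

    epochs: int = 3000
    initial_lr: float = 1e-2
    batch_size: int = 2
    crops_per_batch_item: int = 20
    crop_size_px: int = 512
    dropout: float = 0.1
    activation: str = "mish"
    loss: str = "dice+bce"
    augmentations: tuple[str, ...] = ("gaussian_noise", "flips", "random_affine")
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "crops_per_batch_item", "crop_size_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def desk_scale(self) -> "TrainingConfig":
        return replace(self, epochs=min(self.epochs, DESK_MAX_EPOCHS),
                       crop_size_px=min(self.crop_size_px, DESK_MAX_CROP))


def dice_bce_loss(pred: np.ndarray, target: np.ndarray,
                  eps: float = 1e-7) -> float:
    """Equally weighted soft Dice + binary cross-entropy.

    ``pred`` holds foreground probabilities in [0, 1], ``target`` binary
    foreground.  A perfect prediction scores 0 in both terms.
    """
    pred = np.clip(np.asarray(pred, float), eps, 1 - eps)
    target = np.asarray(target, float)
    inter = (pred * target).sum()
    dice = 1.0 - 2.0 * inter / (pred.sum() + target.sum() + eps)
    bce = float(-(target * np.log(pred) + (1 - target) * np.log(1 - pred)).mean())
    return float(dice + bce)


class TrainedPixelEngine:
    """Per-pixel logistic engine with the matched-filter predict contract."""

    def __init__(self, model: SGDClassifier, scale: PixelScale,
                 feature_engine: MatchedFilterEngine):
        self.model = model
        self.scale = scale
        self._features = feature_engine

    def features(self, raster: np.ndarray) -> np.ndarray:
        img = normalize_percentile(np.asarray(raster, float))
        maps = [img, gaussian_filter(img, 1.5), gaussian_filter(img, 4.0)]
        ncc = self._features_ncc(img)
        return np.stack(maps + ncc, axis=-1)

    def _features_ncc(self, img: np.ndarray) -> list[np.ndarray]:
        from skimage.feature import match_template
        out = []
        for cls in sorted(self._features.templates):
            kern = self._features._kernels[cls]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = match_template(img, kern, pad_input=True)
            out.append(np.nan_to_num(r))
        return out

    def predict(self, raster: np.ndarray) -> np.ndarray:
        feats = self.features(raster)
        h, w, f = feats.shape
        proba = self.model.predict_proba(feats.reshape(-1, f))
        stack = np.zeros((N_CHANNELS, h, w))
        for j, cls in enumerate(self.model.classes_):
            stack[int(cls)] = proba[:, j].reshape(h, w)
        stack[7] = 0.0
        total = stack.sum(axis=0, keepdims=True)
        return stack / np.maximum(total, 1e-12)


def train_pixel_classifier(manifest: dict | str | Path,
                           config: TrainingConfig | None = None,
                           data_dir: str | Path | None = None,
                           allow_full_scale: bool = False,
                           pixels_per_crop: int = 400) -> TrainedPixelEngine:
    """Train the per-pixel engine on a simulated dataset manifest.

    Pixels are sampled from random crops restricted to each image's
    training stripes; the checkpoint (epoch) with the lowest validation
    loss is kept.  Empty training sets raise ``ValueError``.
    """
    from . import io as eio

    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        manifest = json.loads(manifest_path.read_text())
        data_dir = data_dir or manifest_path.parent
    data_dir = Path(data_dir or ".")
    config = config or TrainingConfig()
    if not allow_full_scale:
        config = config.desk_scale()
    if not manifest.get("images"):
        raise ValueError("empty training set: manifest lists no images")

    scale = PixelScale(float(manifest.get("nm_per_pixel", 1.81)))
    feat_engine = MatchedFilterEngine(class_templates(scale), scale)
    engine = TrainedPixelEngine(
        SGDClassifier(loss="log_loss", learning_rate="constant",
                      eta0=config.initial_lr, random_state=config.seed),
        scale, feat_engine)

    rng = np.random.default_rng(config.seed)
    images, labels, val_masks = [], [], []
    for entry in manifest["images"]:
        mic = eio.read_image(data_dir / entry["image"])
        lbl = eio.read_labels(data_dir / entry["labels"])
        val_cols = np.zeros(lbl.shape[1], bool)
        for a, b in entry.get("validation_columns", []):
            val_cols[a:b] = True
        images.append(engine.features(mic.pixels))
        labels.append(lbl)
        val_masks.append(np.broadcast_to(val_cols, lbl.shape))

    classes = np.arange(7)
    best = None
    best_loss = np.inf
    for _ in range(config.epochs):
        xs, ys = [], []
        for feats, lbl, val in zip(images, labels, val_masks):
            train_mask = ~val
            rows, cols = np.nonzero(train_mask)
            n = min(len(rows),
                    config.crops_per_batch_item * config.batch_size
                    * pixels_per_crop // max(len(images), 1))
            pick = rng.choice(len(rows), size=n, replace=False)
            xs.append(feats[rows[pick], cols[pick]])
            ys.append(lbl[rows[pick], cols[pick]])
        X = np.concatenate(xs)
        y = np.concatenate(ys).astype(int)
        engine.model.partial_fit(X, y, classes=classes)
        loss = _validation_loss(engine, images, labels, val_masks, rng)
        if loss < best_loss:
            best_loss = loss
            best = {"coef": engine.model.coef_.copy(),
                    "intercept": engine.model.intercept_.copy()}
    if best is not None:
        engine.model.coef_ = best["coef"]
        engine.model.intercept_ = best["intercept"]
    return engine


def _validation_loss(engine: TrainedPixelEngine, images, labels, val_masks,
                     rng, n_sample: int = 2000) -> float:
    xs, ys = [], []
    for feats, lbl, val in zip(images, labels, val_masks):
        rows, cols = np.nonzero(val)
        if not len(rows):
            continue
        pick = rng.choice(len(rows), size=min(n_sample, len(rows)), replace=False)
        xs.append(feats[rows[pick], cols[pick]])
        ys.append(lbl[rows[pick], cols[pick]])
    if not xs:
        return np.inf
    X = np.concatenate(xs)
    y = np.concatenate(ys).astype(int)
    proba = engine.model.predict_proba(X)
    fg_pred = 1.0 - proba[:, list(engine.model.classes_).index(0)]
    return dice_bce_loss(fg_pred, y > 0)
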
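"""Atypical-cell classification.

Two routes with the same contract (a probability of atypia per 64x64
single-cell crop):

* :class:`CancerNetClassifier` — a compact trainable CNN: three blocks of
  [3x3 conv → BN → ReLU] x2 followed by a 1x1 conv → BN → ReLU and a 2x2
  max-pool, with 4/8/16 filters per block (27 weight/norm/activation
  layers in total), then global average pooling and a dense sigmoid head.
  Trained with Adam on binary cross-entropy, default batch size 16.
* :func:`rule_atypia_score` — a deterministic logistic scorer over the
  nuclear/cytoplasmic area ratio, used as an oracle and fallback when no
  trained weights exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "AugmentationConfig",
    "EvalReport",
    "CancerNetClassifier",
    "rule_atypia_score",
    "evaluate",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Random crop augmentation ranges (applied on the fly per epoch)."""

    rotation_range: float = 20.0     # degrees
    width_shift: float = 0.08        # fraction of width
    height_shift: float = 0.08
    shear_range: float = 0.1         # radians
    zoom_range: float = 0.1          # +- fraction
    horizontal_flip: bool = True
    vertical_flip: bool = True

    def __post_init__(self) -> None:
        for v in (self.rotation_range, self.width_shift, self.height_shift,
                  self.shear_range, self.zoom_range):
            if v < 0:
                raise ValueError("augmentation ranges must be >= 0")


def _augment_batch(X: np.ndarray, cfg: AugmentationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(X)
    n, c, h, w = X.shape
    for i in range(n):
        ang = math.radians(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
        shear = rng.uniform(-cfg.shear_range, cfg.shear_range)
        zoom = 1.0 + rng.uniform(-cfg.zoom_range, cfg.zoom_range)
        ty = rng.uniform(-cfg.height_shift, cfg.height_shift) * h
        tx = rng.uniform(-cfg.width_shift, cfg.width_shift) * w
        ca, sa = math.cos(ang), math.sin(ang)
        A = np.array([[ca, -sa], [sa, ca]]) @ np.array([[1, shear], [0, 1]]) / zoom
        center = np.array([h / 2, w / 2])
        offset = center - A @ center + np.array([ty, tx])
        for ci in range(c):
            out[i, ci] = ndimage.affine_transform(X[i, ci], A, offset=offset, order=1)
        if cfg.horizontal_flip and rng.random() < 0.5:
            out[i] = out[i, :, :, ::-1]
        if cfg.vertical_flip and rng.random() < 0.5:
            out[i] = out[i, :, ::-1, :]
    return out


def _minmax_per_crop(X: np.ndarray) -> np.ndarray:
    """Per-crop min-max normalisation to [0, 1]."""
    X = np.asarray(X, dtype=np.float32)
    lo = X.min(axis=(1, 2, 3), keepdims=True)
    hi = X.max(axis=(1, 2, 3), keepdims=True)
    span = np.where(hi - lo > 1e-9, hi - lo, 1.0)
    return (X - lo) / span


class CancerNetClassifier(BaseEstimator, ClassifierMixin):
    """Compact CNN for atypical-vs-normal single-cell crops.

    Expects crops of shape (n, channels, size, size) with ``size``
    divisible by 8, values on any scale (each crop is min-max normalised).
    Training is deterministic for a fixed ``random_state``.

    Parameters
    ----------
    epochs : training epochs (default 30; 150 matches the full schedule).
    batch_size : minibatch size (default 16).
    lr : Adam learning rate.
    filters : filters per block (default (4, 8, 16)).
    augmentation : optional :class:`AugmentationConfig`; None disables.
    random_state : seed for initialisation, shuffling and augmentation.
    """

    def __init__(self, epochs: int = 30, batch_size: int = 16, lr: float = 3e-3,
                 filters: tuple[int, int, int] = (4, 8, 16),
                 augmentation: AugmentationConfig | None = None,
                 random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.filters = filters
        self.augmentation = augmentation
        self.random_state = random_state

    def _build(self, in_ch: int, rng: np.random.Generator) -> nn.Sequential:
        layers: list[nn.Layer] = []
        prev = in_ch
        for f in self.filters:
            for _ in range(2):
                layers += [nn.Conv2d(prev, f, 3, rng), nn.BatchNorm2d(f), nn.ReLU()]
                prev = f
            layers += [nn.Conv2d(prev, f, 1, rng), nn.BatchNorm2d(f), nn.ReLU(),
                       nn.MaxPool2()]
        layers += [nn.GlobalAvgPool(), nn.Dense(prev, 1, rng)]
        return nn.Sequential(layers)

    def fit(self, X, y):
        X = _minmax_per_crop(np.asarray(X))
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("training set must contain both classes")
        if X.ndim != 4 or X.shape[2] % 8 or X.shape[3] % 8:
            raise ValueError("crops must be (n, ch, H, W) with H, W divisible by 8")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(float)
        rng = np.random.default_rng(self.random_state)
        self.model_ = self._build(X.shape[1], rng)
        opt = nn.Adam(self.model_, lr=self.lr)
        n = len(X)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx]
                if self.augmentation is not None:
                    xb = _augment_batch(xb, self.augmentation, rng)
                logits = self.model_.forward(xb, train=True)
                loss, grad = nn.bce_with_logits(logits, y01[idx])
                self.model_.backward(grad)
                opt.step()
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = _minmax_per_crop(np.asarray(X))
        probs = []
        for start in range(0, len(X), 64):
            logits = self.model_.forward(X[start:start + 64], train=False)
            probs.append(1.0 / (1.0 + np.exp(-logits.ravel())))
        p1 = np.concatenate(probs) if probs else np.zeros(0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


def rule_atypia_score(nc_area_ratio: float, theta: float = 0.3,
                      tau: float = 0.05) -> float:
    """Deterministic atypia score: logistic in the N/C area ratio.

    Returns 1 / (1 + exp(−(r − θ)/τ)); 0.5 at r = θ, strictly increasing
    in r.  θ sits between the normal and atypical N/C populations.
    """
    return float(1.0 / (1.0 + math.exp(-(nc_area_ratio - theta) / tau)))


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def evaluate(probs, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion-matrix metrics at a probability threshold."""
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if len(probs) != len(labels):
        raise ValueError("probs and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    pred = (probs > threshold).astype(int)
    tp = int(np.sum((labels == 1) & (pred == 1)))
    fp = int(np.sum((labels == 0) & (pred == 1)))
    tn = int(np.sum((labels == 0) & (pred == 0)))
    fn = int(np.sum((labels == 1) & (pred == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return EvalReport(accuracy=(tp + tn) / len(labels), f1=f1,
                      sensitivity=sens, specificity=spec,
                      tp=tp, fp=fp, tn=tn, fn=fn)
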
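"""Fully convolutional networks with skip fusion for muscle segmentation.

The family FCN-32s .. FCN-2s shares one VGG-style encoder of five stages,
each stage a short stack of 3x3 convolutions followed by 2x2 max pooling,
so stage i produces features at stride 2^i.  Class score maps are computed
from the deepest stage (stride 32) with a 1x1 convolution and then, for a
variant with fusion stride s, repeatedly upsampled 2x (learned transposed
convolution, bilinear-initialized) and fused by elementwise addition with
zero-initialized 1x1 score maps from progressively earlier pooling stages,
until stride s is reached; a final learned upsampling restores full
resolution.  FCN-32s performs no fusion; FCN-2s fuses pool4, pool3, pool2
and pool1 (log2(32/s) fusions in general).  The finer the fusion stride,
the thinner the structures the network can delineate — which is what a
muscle ring a few pixels wide demands.

Training is plain SGD with momentum.  Two loss conventions are provided:
the historical unnormalized softmax loss (summed over pixels, workable only
with minuscule learning rates such as 1e-10) and per-pixel-normalized
cross-entropy, the default at phantom scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _layers as L
from .phantom import LabelMap
from .threshold import BinaryMask
from .windowing import GrayImage

__all__ = [
    "FCNConfig",
    "TrainConfig",
    "TrainedModel",
    "FCNNet",
    "FCNSegmenter",
    "build_fcn",
    "train",
    "predict",
    "muscle_mask",
]

_ALLOWED_STRIDES = (32, 16, 8, 4, 2)


@dataclass(frozen=True)
class FCNConfig:
    """Architecture knobs: fusion depth, class count, encoder width."""

    fusion_stride: int = 2
    n_classes: int = 3
    base_channels: int = 8
    input_channels: int = 1
    pretrained_backbone: bool = False

    def validate(self) -> None:
        if self.fusion_stride not in _ALLOWED_STRIDES:
            raise ValueError(
                f"fusion_stride must be one of {_ALLOWED_STRIDES}, got {self.fusion_stride}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.input_channels not in (1, 3):
            raise ValueError("input_channels must be 1 or 3")

    @property
    def n_fusions(self) -> int:
        return int(np.log2(32 // self.fusion_stride))


@dataclass(frozen=True)
class TrainConfig:
    """SGD recipe: step size, momentum, decay, batching, loss convention."""

    learning_rate: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-6
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    loss_mode: str = "normalized"
    max_grad_norm: float | None = 1.0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss_mode not in ("normalized", "unnormalized"):
            raise ValueError("loss_mode must be 'normalized' or 'unnormalized'")

    @classmethod
    def fullscale_preset(cls) -> "TrainConfig":
        """The published full-scale recipe: unnormalized softmax loss with
        momentum 0.9, minibatch 8, lr 1e-10, weight decay 1e-12, 500 epochs,
        last model kept."""
        return cls(
            learning_rate=1e-10,
            momentum=0.9,
            weight_decay=1e-12,
            batch_size=8,
            epochs=500,
            loss_mode="unnormalized",
            max_grad_norm=None,
        )

    @classmethod
    def desk_preset(cls, epochs: int = 30, seed: int = 0) -> "TrainConfig":
        """Phantom-scale recipe: normalized loss, lr 0.05, clipped SGD."""
        return cls(epochs=epochs, seed=seed)


@dataclass
class TrainedModel:
    """A fitted network plus its provenance and loss trace."""

    config: FCNConfig
    net: "FCNNet"
    loss_history: list[float] = field(default_factory=list)
    train_config: TrainConfig | None = None


class FCNNet:
    """The layer graph; parameters live in the layers themselves."""

    # convolutions per encoder stage (deeper stages are cheap at low res)
    STAGE_DEPTH = (1, 1, 2, 2, 2)

    def __init__(self, cfg: FCNConfig, seed: int = 0, dtype=np.float32):
        cfg.validate()
        if cfg.pretrained_backbone:
            raise NotImplementedError(
                "pretrained 3-channel backbone weights are not bundled; "
                "train from scratch (pretrained_backbone=False)"
            )
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xFC]))
        b = cfg.base_channels
        widths = (b, 2 * b, 4 * b, 8 * b, 8 * b)
        self.stages: list[list[L.Layer]] = []
        cin = cfg.input_channels
        for depth, cout in zip(self.STAGE_DEPTH, widths):
            stage: list[L.Layer] = []
            for _ in range(depth):
                stage.append(L.Conv2D(cin, cout, 3, 1, 1, rng=rng, dtype=dtype))
                stage.append(L.ReLU())
                cin = cout
            stage.append(L.MaxPool2())
            self.stages.append(stage)
        k = cfg.n_classes
        self.score5 = L.Conv2D(widths[4], k, 1, rng=rng, dtype=dtype)
        self.score5.params["w"] *= 0.01  # near-zero head: stable warm start
        # one (upsample, skip-score) pair per fusion, from pool4 downward
        self.ups: list[L.ConvTranspose2D] = []
        self.skips: list[L.Conv2D] = []
        for i in range(self.cfg.n_fusions):
            self.ups.append(L.ConvTranspose2D(k, k, 4, 2, 1, dtype=dtype))
            self.skips.append(
                L.Conv2D(widths[3 - i], k, 1, init="zero", dtype=dtype)
            )
        f = cfg.fusion_stride
        self.final_up = L.ConvTranspose2D(k, k, 2 * f, f, f // 2, dtype=dtype)

    def layers(self) -> list[L.Layer]:
        out: list[L.Layer] = [l for st in self.stages for l in st]
        out += [self.score5, *self.ups, *self.skips, self.final_up]
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(n, c, h, w) floats -> (n, n_classes, h, w) scores."""
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {x.shape[2:]}")
        pools = []
        cur = x.astype(self.dtype, copy=False)
        for stage in self.stages:
            for layer in stage:
                cur = layer.forward(cur)
            pools.append(cur)
        score = self.score5.forward(pools[4])
        for i in range(self.cfg.n_fusions):
            score = self.ups[i].forward(score) + self.skips[i].forward(pools[3 - i])
        return self.final_up.forward(score)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        d = self.final_up.backward(dscores)
        dpools = [None] * 5
        for i in reversed(range(self.cfg.n_fusions)):
            dpools[3 - i] = self.skips[i].backward(d)
            d = self.ups[i].backward(d)
        dpools[4] = self.score5.backward(d)
        d = None
        for si in reversed(range(5)):
            grad = dpools[si]
            d = grad if d is None else d + grad if grad is not None else d
            for layer in reversed(self.stages[si]):
                d = layer.backward(d)
        return d


def build_fcn(cfg: FCNConfig, seed: int = 0) -> FCNNet:
    """Construct an untrained network for the given fusion stride."""
    return FCNNet(cfg, seed=seed)


def _to_input_array(imgs, dtype=np.float64) -> np.ndarray:
    """GrayImages / LabelMaps / arrays -> centered (n, 1, h, w) floats."""
    arrs = []
    for im in imgs:
        if isinstance(im, GrayImage):
            arrs.append(im.normalized())
        else:
            a = np.asarray(im, dtype=np.float64)
            if a.max() > 1.0:
                raise ValueError(
                    "raw arrays must be pre-normalized to [0, 1]; pass GrayImage "
                    "instances to let the window's bit depth set the scale"
                )
            arrs.append(a)
    x = np.stack(arrs).astype(dtype)
    return (x - 0.5)[:, None, :, :]


def _to_label_array(labels) -> np.ndarray:
    return np.stack(
        [lm.classes if isinstance(lm, LabelMap) else np.asarray(lm) for lm in labels]
    ).astype(np.int64)


def train(
    model: FCNNet | TrainedModel,
    train_set: Sequence[tuple],
    cfg: TrainConfig,
) -> TrainedModel:
    """Minibatch SGD over (GrayImage, LabelMap) pairs; keeps the last model.

    Shuffling and batching are driven by ``cfg.seed``, so the per-epoch
    mean-loss history is bit-reproducible.  No validation-based selection:
    the model after the final epoch is returned.
    """
    cfg.validate()
    if len(train_set) == 0:
        raise ValueError("train_set is empty")
    net = model.net if isinstance(model, TrainedModel) else model
    x = _to_input_array([p[0] for p in train_set], dtype=net.dtype)
    y = _to_label_array([p[1] for p in train_set])
    if y.min() < 0 or y.max() >= net.cfg.n_classes:
        raise ValueError("label out of range for the configured class count")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x7A]))
    opt = L.SGD(
        net.layers(),
        cfg.learning_rate,
        cfg.momentum,
        cfg.weight_decay,
        max_grad_norm=cfg.max_grad_norm,
    )
    n = x.shape[0]
    history: list[float] = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            scores = net.forward(x[idx])
            loss, dscores = L.softmax_cross_entropy(scores, y[idx], cfg.loss_mode)
            net.backward(dscores.astype(net.dtype))
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
    return TrainedModel(net.cfg, net, history, cfg)


def predict(model: FCNNet | TrainedModel, img) -> LabelMap:
    """Per-pixel argmax segmentation; ties resolve to the lowest class."""
    net = model.net if isinstance(model, TrainedModel) else model
    x = _to_input_array([img], dtype=net.dtype)
    scores = net.forward(x)
    return LabelMap(np.argmax(scores[0], axis=0).astype(np.uint8))


def muscle_mask(labels: LabelMap | np.ndarray, pixel_spacing: float | None = None) -> BinaryMask:
    """Binary mask of the Muscle class (1); Background and Inside drop out."""
    c = labels.classes if isinstance(labels, LabelMap) else np.asarray(labels)
    return BinaryMask(c == 1, pixel_spacing)


class FCNSegmenter(BaseEstimator):
    """Sklearn-style estimator around the FCN family.

    Parameters mirror :class:`FCNConfig` and :class:`TrainConfig`.  ``fit``
    takes ``X`` as an (n, h, w) stack of [0, 1]-normalized gray images (or
    a list of :class:`GrayImage`) and ``y`` as an (n, h, w) integer label
    stack; ``predict`` returns an (n, h, w) label stack.  Fitted state:
    ``model_`` (the trained network) and ``loss_history_``.
    """

    def __init__(
        self,
        fusion_stride: int = 2,
        n_classes: int = 3,
        base_channels: int = 8,
        input_channels: int = 1,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        weight_decay: float = 1e-6,
        batch_size: int = 8,
        epochs: int = 30,
        loss_mode: str = "normalized",
        max_grad_norm: float | None = 1.0,
        random_state: int = 0,
    ):
        self.fusion_stride = fusion_stride
        self.n_classes = n_classes
        self.base_channels = base_channels
        self.input_channels = input_channels
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.loss_mode = loss_mode
        self.max_grad_norm = max_grad_norm
        self.random_state = random_state

    def _configs(self) -> tuple[FCNConfig, TrainConfig]:
        fcn_cfg = FCNConfig(
            fusion_stride=self.fusion_stride,
            n_classes=self.n_classes,
            base_channels=self.base_channels,
            input_channels=self.input_channels,
        )
        train_cfg = TrainConfig(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.random_state,
            loss_mode=self.loss_mode,
            max_grad_norm=self.max_grad_norm,
        )
        fcn_cfg.validate()
        train_cfg.validate()
        return fcn_cfg, train_cfg

    def fit(self, X, y):
        fcn_cfg, train_cfg = self._configs()
        net = build_fcn(fcn_cfg, seed=self.random_state)
        trained = train(net, list(zip(list(X), list(y))), train_cfg)
        self.model_ = trained
        self.loss_history_ = trained.loss_history
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("FCNSegmenter is not fitted")
        return np.stack([predict(self.model_, im).classes for im in X])

    def predict_muscle_masks(self, X) -> np.ndarray:
        """(n, h, w) boolean muscle masks (class 1 of the predictions)."""
        return self.predict(X) == 1
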
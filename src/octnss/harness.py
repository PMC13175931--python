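"""Two-stage fine-tuning harness.

Encodes the transfer-learning schedule used for the OCT classifier: stage 1
trains a fresh dropout + softmax head on top of a frozen backbone (Adam,
lr 1e-3, 10 epochs); stage 2 unfreezes the last 50 backbone layers and
continues at lr 1e-4 for 20 epochs.  Early stopping monitors validation
loss and restores the best weights; a reduce-on-plateau schedule decays the
learning rate down to a floor of 1e-6.  Categorical cross-entropy, batch 32,
224x224x3 inputs, and rotation / zoom / translation / brightness /
horizontal-flip augmentation are the defaults; every field is overridable
for desk-scale runs on phantoms with a small backbone.

The backbone is any object exposing ``layers``, ``freeze_all()``,
``unfreeze_last(n)``, ``feature_dim``, ``forward``/``backward`` and
``params(trainable_only=...)`` — see :class:`octnss.nn.TinyCNNBackbone`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import AffineTransform, resize, warp

from . import nn
from .enhance import EnhanceParams, enhance_image
from .io import DatasetIndex, GrayImage, read_gray
from .metrics import ClassificationReport, classification_report

logger = logging.getLogger(__name__)


@dataclass
class StagePlan:
    optimizer: str = "adam"
    lr: float = 1e-3
    epochs: int = 10
    frozen_base: bool = True
    unfreeze_last_n_layers: int = 0


@dataclass
class AugmentPlan:
    """Augmentation families with fixed default magnitudes."""

    rotation_deg: float = 15.0
    zoom_frac: float = 0.10
    translate_frac: float = 0.10
    brightness_frac: float = 0.10
    horizontal_flip: bool = True


@dataclass
class TrainPlan:
    input_size: tuple[int, int, int] = (224, 224, 3)
    n_classes: int = 8
    batch_size: int = 32
    loss: str = "categorical_crossentropy"
    stage1: StagePlan = field(
        default_factory=lambda: StagePlan(lr=1e-3, epochs=10, frozen_base=True)
    )
    stage2: StagePlan = field(
        default_factory=lambda: StagePlan(
            lr=1e-4, epochs=20, frozen_base=False, unfreeze_last_n_layers=50
        )
    )
    dropout: float = 0.5
    augmentation: AugmentPlan = field(default_factory=AugmentPlan)
    early_stopping_patience: int = 5  # value is an assumption; not pinned upstream
    early_stopping_restore_best: bool = True
    reduce_lr_factor: float = 0.5
    reduce_lr_patience: int = 2
    reduce_lr_min_lr: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage2.lr >= self.stage1.lr:
            raise ValueError("stage 2 learning rate must be below stage 1's")
        if self.stage1.epochs < 1 or self.stage2.epochs < 1:
            raise ValueError("both stages need at least one epoch")
        if self.reduce_lr_min_lr > self.stage2.lr:
            raise ValueError("plateau floor must not exceed the stage-2 lr")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch records for both stages plus early-stopping outcome."""

    stage1: dict[str, list[float]] = field(default_factory=dict)
    stage2: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = 0  # 1-based global epoch index of the best val loss
    stopped_early: bool = False


def build_plan(config: str | Path | dict | None = None) -> TrainPlan:
    """Construct a TrainPlan from an optional YAML/JSON file or dict.

    An empty config yields the default schedule.  Overrides are applied
    field-by-field (nested for ``stage1``/``stage2``/``augmentation``) and
    logged; inconsistent overrides raise at validation.
    """
    data: dict = {}
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        data = yaml.safe_load(text) or {}
    elif isinstance(config, dict):
        data = dict(config)
    elif config is not None:
        raise TypeError(f"config must be a path, dict or None, not {type(config)}")

    plan = TrainPlan()
    for key, value in data.items():
        if not hasattr(plan, key):
            raise ValueError(f"unknown TrainPlan field {key!r}")
        current = getattr(plan, key)
        if isinstance(current, (StagePlan, AugmentPlan)) and isinstance(value, dict):
            for k2, v2 in value.items():
                if not hasattr(current, k2):
                    raise ValueError(f"unknown {key} field {k2!r}")
                setattr(current, k2, v2)
                logger.info("plan override: %s.%s = %r", key, k2, v2)
        else:
            if key == "input_size":
                value = tuple(value)
            setattr(plan, key, value)
            logger.info("plan override: %s = %r", key, value)
    plan.__post_init__()  # re-validate after overrides
    return plan


def plan_to_dict(plan: TrainPlan) -> dict:
    return asdict(plan)


# ---------------------------------------------------------------------------
# Batch preparation


class BatchStream:
    """Deterministic stream of (images, one-hot labels) batches.

    Images are loaded once, optionally enhanced, resized to the plan's input
    size, scaled to [0, 1] and replicated to three channels.  The training
    split is shuffled and augmented with generators derived from the plan
    seed and the epoch number, so two runs with one seed see identical pixel
    streams; val/test streams are un-augmented and bit-identical across
    iterations.
    """

    def __init__(self, index: DatasetIndex, plan: TrainPlan, enhance: bool = False):
        if len(index) == 0:
            raise ValueError("dataset index is empty")
        if len(index.class_names) != plan.n_classes:
            raise ValueError(
                f"index has {len(index.class_names)} classes but the plan "
                f"expects {plan.n_classes}"
            )
        self.index = index
        self.plan = plan
        self.enhance = enhance
        self.augment = index.split == "train"
        self._images: np.ndarray | None = None
        self._labels: np.ndarray | None = None

    @property
    def n_batches(self) -> int:
        return math.ceil(len(self.index) / self.plan.batch_size)

    @property
    def class_names(self) -> list[str]:
        return self.index.class_names

    def _load(self) -> None:
        if self._images is not None:
            return
        h, w, _ = self.plan.input_size
        images = np.empty((len(self.index), h, w), dtype=np.float32)
        labels = np.empty(len(self.index), dtype=np.int64)
        for i, (path, label) in enumerate(self.index.entries):
            img = read_gray(path)
            if self.enhance:
                img = enhance_image(img, EnhanceParams()).enhanced
            images[i] = self._prepare(img, (h, w))
            labels[i] = self.index.label_index(label)
        self._images = images
        self._labels = labels

    @staticmethod
    def _prepare(img: GrayImage, hw: tuple[int, int]) -> np.ndarray:
        scale = 255.0 if img.bit_depth == 8 else 65535.0
        x = np.clip(img.pixels / scale, 0.0, 1.0)
        return resize(x, hw, order=1, anti_aliasing=True, preserve_range=True)

    def batches(self, epoch: int = 0):
        """Yield (X, Y) with X of shape (B, 3, H, W) and one-hot Y."""
        self._load()
        n = len(self.index)
        order = np.arange(n)
        rng = np.random.default_rng([self.plan.seed, epoch, 0xBA])
        if self.augment:
            rng.shuffle(order)
        bs = self.plan.batch_size
        for start in range(0, n, bs):
            sel = order[start : start + bs]
            imgs = self._images[sel].astype(np.float64)
            if self.augment:
                imgs = np.stack([self._augment_one(im, rng) for im in imgs])
            x = np.repeat(imgs[:, None, :, :], 3, axis=1)  # gray -> 3 channels
            y = np.zeros((len(sel), self.plan.n_classes))
            y[np.arange(len(sel)), self._labels[sel]] = 1.0
            yield x, y

    def _augment_one(self, im: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        aug = self.plan.augmentation
        h, w = im.shape
        angle = np.deg2rad(rng.uniform(-aug.rotation_deg, aug.rotation_deg))
        zoom = 1.0 + rng.uniform(-aug.zoom_frac, aug.zoom_frac)
        ty = rng.uniform(-aug.translate_frac, aug.translate_frac) * h
        tx = rng.uniform(-aug.translate_frac, aug.translate_frac) * w
        bright = 1.0 + rng.uniform(-aug.brightness_frac, aug.brightness_frac)
        flip = aug.horizontal_flip and rng.random() < 0.5

        center = np.array([w / 2, h / 2])
        tform = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=angle, scale=(zoom, zoom))
            + AffineTransform(translation=center + np.array([tx, ty]))
        )
        out = warp(im, tform.inverse, order=1, mode="edge", preserve_range=True)
        if flip:
            out = out[:, ::-1]
        return np.clip(out * bright, 0.0, 1.0)

    def all_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Un-augmented (X, y-index) arrays in index order (for evaluation)."""
        self._load()
        x = np.repeat(self._images[:, None, :, :].astype(np.float64), 3, axis=1)
        return x, self._labels.copy()


def prepare_batches(
    index: DatasetIndex, plan: TrainPlan, enhance: bool = False
) -> BatchStream:
    """Build the batch stream for one dataset split (see BatchStream)."""
    return BatchStream(index, plan, enhance=enhance)


# ---------------------------------------------------------------------------
# Callbacks


class EarlyStopping:
    """Stop when val loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch (1-based); returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


class ReduceLROnPlateau:
    """Multiply the lr by ``factor`` after ``patience`` stale epochs."""

    def __init__(self, factor: float = 0.5, patience: int = 2, min_lr: float = 1e-6):
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def update(self, val_loss: float, lr: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.wait = 0
            return lr
        self.wait += 1
        if self.wait >= self.patience:
            self.wait = 0
            return max(lr * self.factor, self.min_lr)
        return lr


# ---------------------------------------------------------------------------
# Training


class TrainedModel:
    """Backbone + dropout/softmax head with a predict_proba interface."""

    def __init__(self, backbone, head: nn.Sequential, class_names: list[str]):
        self.backbone = backbone
        self.head = head
        self.class_names = class_names

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x, train=train), train=train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        probs = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            probs.append(nn.softmax(logits))
        return np.concatenate(probs)

    def all_params(self) -> list[nn.Param]:
        return self.backbone.params() + self.head.params()


def _snapshot(params: list[nn.Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def _restore(params: list[nn.Param], snap: list[np.ndarray]) -> None:
    for p, s in zip(params, snap):
        p.value[...] = s


def train(
    plan: TrainPlan,
    backbone,
    train_stream: BatchStream,
    val_stream: BatchStream,
) -> tuple[TrainedModel, TrainHistory]:
    """Run the two-stage schedule and return the trained model + history."""
    rng = np.random.default_rng([plan.seed, 0x5EED])
    head = nn.Sequential(
        [
            nn.Dropout(plan.dropout, rng=rng),
            nn.Dense(backbone.feature_dim, plan.n_classes, rng=rng),
        ]
    )
    model = TrainedModel(backbone, head, train_stream.class_names)
    history = TrainHistory()

    best_val = np.inf
    best_snap = _snapshot(model.all_params())
    best_epoch_global = 0
    epoch_offset = 0

    for stage_name, stage in (("stage1", plan.stage1), ("stage2", plan.stage2)):
        if stage.frozen_base:
            backbone.freeze_all()
        else:
            backbone.freeze_all()
            backbone.unfreeze_last(stage.unfreeze_last_n_layers)
        trainable = backbone.params(trainable_only=True) + head.params()
        optimizer = nn.Adam(trainable, lr=stage.lr)
        stopper = EarlyStopping(plan.early_stopping_patience)
        plateau = ReduceLROnPlateau(
            plan.reduce_lr_factor, plan.reduce_lr_patience, plan.reduce_lr_min_lr
        )
        record = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}

        backbone_trainable = any(layer.trainable for layer in backbone.layers)
        for epoch in range(1, stage.epochs + 1):
            losses, accs, weights = [], [], []
            for b, (x, y) in enumerate(train_stream.batches(epoch=epoch_offset + epoch)):
                probs = nn.softmax(model.forward(x, train=True))
                loss = nn.cross_entropy(probs, y)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss in {stage_name}, epoch {epoch}, batch {b}"
                    )
                dfeat = head.backward(nn.softmax_xent_grad(probs, y))
                if backbone_trainable:
                    backbone.backward(dfeat)
                optimizer.step()
                losses.append(loss)
                accs.append((probs.argmax(1) == y.argmax(1)).mean())
                weights.append(len(x))
            w = np.asarray(weights, dtype=float)
            record["train_loss"].append(float(np.average(losses, weights=w)))
            record["train_acc"].append(float(np.average(accs, weights=w)))

            val_loss, val_acc = _evaluate_loss(model, val_stream)
            record["val_loss"].append(val_loss)
            record["val_acc"].append(val_acc)

            if val_loss < best_val:
                best_val = val_loss
                best_snap = _snapshot(model.all_params())
                best_epoch_global = epoch_offset + epoch
            optimizer.lr = plateau.update(val_loss, optimizer.lr)
            if stopper.update(epoch, val_loss):
                history.stopped_early = True
                break
        setattr(history, stage_name, record)
        epoch_offset += len(record["val_loss"])
        if plan.early_stopping_restore_best:
            _restore(model.all_params(), best_snap)

    history.best_epoch = best_epoch_global
    return model, history


def _evaluate_loss(model: TrainedModel, stream: BatchStream) -> tuple[float, float]:
    losses, accs, weights = [], [], []
    for x, y in stream.batches():
        probs = nn.softmax(model.forward(x, train=False))
        losses.append(nn.cross_entropy(probs, y))
        accs.append((probs.argmax(1) == y.argmax(1)).mean())
        weights.append(len(x))
    w = np.asarray(weights, dtype=float)
    return float(np.average(losses, weights=w)), float(np.average(accs, weights=w))


def evaluate(model: TrainedModel, test_stream: BatchStream) -> ClassificationReport:
    """Evaluate on a test stream via the multi-class metric bundle."""
    x, y_idx = test_stream.all_arrays()
    if len(x) == 0:
        raise ValueError("test stream is empty")
    probs = model.predict_proba(x)
    names = np.asarray(model.class_names)
    return classification_report(
        names[y_idx], names[probs.argmax(1)], probs, class_names=list(names)
    )


def save_history_csv(history: TrainHistory, path: str | Path) -> None:
    """Flatten the per-epoch records of both stages into one CSV."""
    import pandas as pd

    rows = []
    for stage in ("stage1", "stage2"):
        rec = getattr(history, stage)
        for i in range(len(rec.get("train_loss", []))):
            rows.append(
                {
                    "stage": stage,
                    "epoch": i + 1,
                    **{k: rec[k][i] for k in rec},
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_plan(plan: TrainPlan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=2, default=str))
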
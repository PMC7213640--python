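"""Residual convolutional classifier for 48x48 multi-channel cell images.

Two architecture presets: ``small`` — a compact 8-convolution residual
network that trains well on CPU and is the desk-scale default — and
``resnet50`` — the full bottleneck architecture (50 convolutions, stages
3/4/6/3, 2048-wide pooled embedding).  Both expose the penultimate
global-average-pooled representation for embedding extraction.

Training follows the clinical pipeline's schedule: categorical
cross-entropy, Adam at learning rate 1e-4, batches of 256 with live
augmentation on the training and validation streams, ceil(M/256) steps per
epoch so the whole training set is seen once, validation once per epoch on
the full validation set, learning rate cut 10x after 10 non-improving
epochs, early stop after 25, up to 512 epochs, with the best
validation-loss weights restored at the end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .core import CLASS_LABELS, CellRecord, ValidationError
from .preprocess import ChannelMeans, PreprocessChain, compute_channel_means
from .split import SplitSpec, assert_patient_disjoint

PRESETS = ("small", "resnet50")


@dataclass(frozen=True)
class ArchConfig:
    preset: str = "small"
    side: int = 48
    in_channels: int = 3
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValidationError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.in_channels < 1:
            raise ValidationError("in_channels must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 512
    lr_reduce_factor: float = 0.1
    lr_patience: int = 10
    early_stop_patience: int = 25
    improvement_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "max_epochs", "lr_patience",
                     "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.early_stop_patience <= self.lr_patience:
            raise ValidationError("early_stop_patience must exceed lr_patience")


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
                "lr": self.lr,
            }
        )


#: Zero-centered uint8-scale inputs are divided by this inside the model so
#: first-layer activations are O(1); a fixed architecture constant, not a
#: data statistic.
INPUT_SCALE = 128.0


class CNNModel:
    """Feature trunk + softmax head, with a self-describing manifest."""

    def __init__(
        self,
        arch: ArchConfig,
        trunk: nn.Sequential,
        head: nn.Dense,
        embedding_width: int,
        classes: tuple[str, ...] = CLASS_LABELS,
    ):
        self.arch = arch
        self.trunk = trunk
        self.head = head
        self.embedding_width = embedding_width
        self.classes = classes
        self.channel_roles: Optional[tuple[str, ...]] = None
        self.channel_means: Optional[ChannelMeans] = None

    def params(self) -> list[nn.Param]:
        return self.trunk.params() + self.head.params()

    def buffers(self) -> list[np.ndarray]:
        return self.trunk.buffers() + self.head.buffers()

    def state(self) -> list[np.ndarray]:
        return nn.get_state(self.params(), self.buffers())

    def load_state(self, state: list[np.ndarray]) -> None:
        nn.set_state(self.params(), self.buffers(), state)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32) / INPUT_SCALE
        return self.head.forward(self.trunk.forward(x, train), train)

    def forward_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward_logits(x))

    def forward_embedding(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32) / INPUT_SCALE
        return self.trunk.forward(x)


def _conv_bn_relu(cin: int, cout: int, k: int, rng, stride: int = 1) -> list[nn.Layer]:
    pad = None if k != 1 else 0
    return [
        nn.Conv2D(cin, cout, k, stride=stride, pad=pad, rng=rng),
        nn.BatchNorm2D(cout),
        nn.ReLU(),
    ]


def _basic_block(c: int, rng) -> list[nn.Layer]:
    """Two 3x3 convolutions with identity skip (conv-BN-ReLU-conv-BN)."""
    body = nn.Sequential(
        [
            nn.Conv2D(c, c, 3, rng=rng),
            nn.BatchNorm2D(c),
            nn.ReLU(),
            nn.Conv2D(c, c, 3, rng=rng),
            nn.BatchNorm2D(c),
        ]
    )
    return [nn.Residual(body), nn.ReLU()]


def _bottleneck(cin: int, mid: int, cout: int, stride: int, rng) -> list[nn.Layer]:
    body = nn.Sequential(
        [
            nn.Conv2D(cin, mid, 1, stride=stride, pad=0, rng=rng),
            nn.BatchNorm2D(mid),
            nn.ReLU(),
            nn.Conv2D(mid, mid, 3, rng=rng),
            nn.BatchNorm2D(mid),
            nn.ReLU(),
            nn.Conv2D(mid, cout, 1, pad=0, rng=rng),
            nn.BatchNorm2D(cout),
        ]
    )
    proj = (
        nn.Sequential(
            [
                nn.Conv2D(cin, cout, 1, stride=stride, pad=0, rng=rng),
                nn.BatchNorm2D(cout),
            ]
        )
        if (cin != cout or stride != 1)
        else None
    )
    return [nn.Residual(body, proj), nn.ReLU()]


def build(arch: ArchConfig, seed: int = 0) -> CNNModel:
    """Construct an untrained model; initialization is a pure function of
    the seed.  Output rows are softmax probabilities summing to 1."""
    rng = np.random.default_rng(seed)
    c = arch.in_channels
    if arch.preset == "small":
        layers: list[nn.Layer] = [
            *_conv_bn_relu(c, 12, 3, rng, stride=2),           # conv1, 48 -> 24
            nn.MaxPool2(),                                     # -> 12
            *_conv_bn_relu(12, 16, 3, rng),                    # conv2
            *_basic_block(16, rng),                            # conv3-4
            nn.MaxPool2(),                                     # -> 6
            *_conv_bn_relu(16, 32, 3, rng),                    # conv5
            *_basic_block(32, rng),                            # conv6-7
            *_conv_bn_relu(32, 64, 3, rng),                    # conv8
            nn.GlobalAvgPool(),
        ]
        width = 64
    else:  # resnet50
        layers = [
            nn.Conv2D(c, 64, 7, stride=2, pad=3, rng=rng),     # stem, 48 -> 24
            nn.BatchNorm2D(64), nn.ReLU(),
            nn.MaxPool2(),                                     # -> 12
        ]
        cin = 64
        for mid, cout, blocks, stride in (
            (64, 256, 3, 1),
            (128, 512, 4, 2),
            (256, 1024, 6, 2),
            (512, 2048, 3, 2),
        ):
            for b in range(blocks):
                layers.extend(_bottleneck(cin, mid, cout, stride if b == 0 else 1, rng))
                cin = cout
        layers.append(nn.GlobalAvgPool())
        width = 2048
    trunk = nn.Sequential(layers)
    head = nn.Dense(width, arch.n_classes, rng=rng, std=0.01)
    return CNNModel(arch, trunk, head, width)


# ---------------------------------------------------------------------------
# Training


def _labels_to_int(records: Sequence[CellRecord], classes: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    out = np.empty(len(records), dtype=np.int64)
    for i, r in enumerate(records):
        if r.true_class is None:
            raise ValidationError(f"record {r.cell_id!r} lacks true_class")
        out[i] = idx[r.true_class]
    return out


def train(
    model: CNNModel,
    records: Sequence[CellRecord],
    split: SplitSpec,
    chain: PreprocessChain,
    cfg: TrainConfig,
) -> TrainHistory:
    """Train in place and return the epoch history.

    Patient-disjointness of the split is asserted up front; training-set
    channel means are computed here and stored on the model so inference
    is self-describing.  Augmentation runs live on both the training and
    validation streams; the evaluation path (predict) never augments.
    """
    assert_patient_disjoint(records, split)
    by_id = {r.cell_id: r for r in records}
    train_recs = [by_id[c] for c in split.train_ids if c in by_id]
    val_recs = [by_id[c] for c in split.validation_ids if c in by_id]
    if not train_recs or not val_recs:
        raise ValidationError("train and validation partitions must be non-empty")
    roles = train_recs[0].image.channel_roles
    if model.arch.in_channels != len(roles):
        raise ValidationError(
            f"model expects {model.arch.in_channels} channels, records have {len(roles)}"
        )

    y_train = _labels_to_int(train_recs, model.classes)
    y_val = _labels_to_int(val_recs, model.classes)
    present = set(y_train.tolist())
    if present != set(range(len(model.classes))):
        missing = [model.classes[i] for i in range(len(model.classes)) if i not in present]
        raise ValidationError(f"training data has no cells of class {missing}")

    root = np.random.default_rng(cfg.seed)
    pad_rng, shuffle_rng, aug_rng = root.spawn(3)
    base_train = chain.base_records(train_recs, pad_rng)
    base_val = chain.base_records(val_recs, pad_rng)
    means = compute_channel_means(base_train)
    model.channel_roles = roles
    model.channel_means = means

    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    lr_tracker = nn.PlateauTracker(
        cfg.lr_patience, cfg.improvement_tol, reset_on_trigger=True
    )
    stop_tracker = nn.PlateauTracker(cfg.early_stop_patience, cfg.improvement_tol)
    history = TrainHistory()
    best_loss = np.inf
    best_state = model.state()

    m_train = len(train_recs)
    steps = math.ceil(m_train / cfg.batch_size)
    val_steps = math.ceil(len(val_recs) / cfg.batch_size)

    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(m_train)
        ep_loss, ep_correct, ep_n = 0.0, 0, 0
        for s in range(steps):
            idx = order[s * cfg.batch_size : (s + 1) * cfg.batch_size]
            x = chain.train_batch(base_train[idx], means, aug_rng)
            logits = model.forward_logits(x, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            model.trunk.backward(model.head.backward(grad))
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
            ep_n += len(idx)

        v_loss, v_correct, v_n = 0.0, 0, 0
        for s in range(val_steps):
            sl = slice(s * cfg.batch_size, (s + 1) * cfg.batch_size)
            x = chain.train_batch(base_val[sl], means, aug_rng)
            logits = model.forward_logits(x)
            loss, _ = nn.softmax_cross_entropy(logits, y_val[sl])
            v_loss += loss * logits.shape[0]
            v_correct += int((logits.argmax(axis=1) == y_val[sl]).sum())
            v_n += logits.shape[0]
        v_loss /= v_n

        history.epoch.append(epoch)
        history.train_loss.append(ep_loss / ep_n)
        history.train_acc.append(ep_correct / ep_n)
        history.val_loss.append(v_loss)
        history.val_acc.append(v_correct / v_n)
        history.lr.append(opt.lr)

        if v_loss < best_loss:
            best_loss = v_loss
            best_state = model.state()

        if lr_tracker.update(v_loss):
            opt.lr *= cfg.lr_reduce_factor
        if stop_tracker.update(v_loss):
            history.stopped_epoch = epoch
            history.stop_reason = "early_stopping"
            break
    else:
        history.stopped_epoch = cfg.max_epochs
        history.stop_reason = "max_epochs"

    model.load_state(best_state)
    return history


# ---------------------------------------------------------------------------
# Inference


def _eval_pixels(
    model: CNNModel, records: Sequence[CellRecord], chain: PreprocessChain
) -> np.ndarray:
    if model.channel_means is None or model.channel_roles is None:
        raise ValidationError("model has no stored channel means; train it first")
    roles = records[0].image.channel_roles
    if roles != model.channel_roles:
        raise ValidationError(
            f"channel mismatch: model expects roles {model.channel_roles}, "
            f"records have {roles}"
        )
    base = chain.base_records(records)
    return chain.eval_batch(base, model.channel_means)


def predict(
    model: CNNModel,
    records: Sequence[CellRecord],
    chain: PreprocessChain,
    batch_size: int = 256,
) -> tuple[np.ndarray, list[str]]:
    """Per-cell class probabilities and argmax labels.

    Test-time preprocessing is canvas -> stretch -> center with the
    training-set means; no augmentation.  Argmax ties break toward the
    class earliest in ``model.classes`` (lexicographically first for the
    default leukemic/normal/other ordering).
    """
    x = _eval_pixels(model, records, chain)
    probas = []
    for s in range(0, len(records), batch_size):
        probas.append(model.forward_proba(x[s : s + batch_size]))
    proba = np.concatenate(probas, axis=0)
    labels = [model.classes[i] for i in proba.argmax(axis=1)]
    return proba, labels


def extract_embeddings(
    model: CNNModel,
    records: Sequence[CellRecord],
    chain: PreprocessChain,
    batch_size: int = 256,
) -> np.ndarray:
    """Penultimate pooled representation, one row per record (input order)."""
    x = _eval_pixels(model, records, chain)
    rows = []
    for s in range(0, len(records), batch_size):
        rows.append(model.forward_embedding(x[s : s + batch_size]))
    return np.concatenate(rows, axis=0)


# ---------------------------------------------------------------------------
# Checkpoints


def save_model(model: CNNModel, path: str | Path) -> Path:
    """Self-describing checkpoint: weights + arch/means/roles manifest."""
    path = Path(path)
    manifest = {
        "arch": {
            "preset": model.arch.preset,
            "side": model.arch.side,
            "in_channels": model.arch.in_channels,
            "n_classes": model.arch.n_classes,
        },
        "classes": list(model.classes),
        "channel_roles": list(model.channel_roles) if model.channel_roles else None,
        "channel_means": list(model.channel_means.values)
        if model.channel_means
        else None,
        "embedding_width": model.embedding_width,
    }
    arrays = {f"s{i}": arr for i, arr in enumerate(model.state())}
    np.savez_compressed(path, manifest=json.dumps(manifest), **arrays)
    return path


def load_model(path: str | Path, seed: int = 0) -> CNNModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        state = [data[f"s{i}"] for i in range(len(data.files) - 1)]
    model = build(ArchConfig(**manifest["arch"]), seed=seed)
    model.classes = tuple(manifest["classes"])
    model.load_state(state)
    if manifest["channel_roles"] is not None:
        model.channel_roles = tuple(manifest["channel_roles"])
    if manifest["channel_means"] is not None:
        model.channel_means = ChannelMeans(values=tuple(manifest["channel_means"]))
    return model
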
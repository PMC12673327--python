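"""Training protocol: 8:2 split, batch 16, learning rate 2e-4, Adam.

The split, shuffling, weight initialization and optimizer state are all
driven by explicit seeds, so a (generate -> split -> train -> evaluate)
pipeline is bit-reproducible on one platform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import load_image, preprocess_image
from .network import KROMNet, NetworkSpec, build_kromnet
from .nn import SGD, Adam, softmax_cross_entropy
from .synthgen import DatasetManifest

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "split_dataset",
    "load_inputs",
    "train",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    batch_size: int = 16
    learning_rate: float = 2e-4
    epochs: int = 100
    split_ratio: float = 0.8
    optimizer: str = "adam"
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError(f"split_ratio {self.split_ratio} outside (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    """Per-epoch training curve."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)

    def append(self, epoch: int, loss: float, train_acc: float, test_acc: float) -> None:
        if not math.isfinite(loss):
            raise ValueError(f"non-finite loss {loss} at epoch {epoch}")
        self.epochs.append(epoch)
        self.train_loss.append(loss)
        self.train_acc.append(train_acc)
        self.test_acc.append(test_acc)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "test_acc": self.test_acc,
            }
        ).to_csv(path, index=False)


def split_dataset(
    manifest: DatasetManifest, config: TrainingConfig
) -> tuple[DatasetManifest, DatasetManifest]:
    """Split into disjoint, exhaustive train/test manifests.

    Stratified mode shuffles within each class and takes
    ``floor(split_ratio * n_c)`` per class for training, preserving the
    class composition in the test set; unstratified mode shuffles globally.
    The ``split`` column of the returned manifests records the assignment.
    """
    labels = manifest.labels
    k = len(manifest.class_counts)
    if len(manifest.records) < k:
        raise ValueError(f"need at least {k} records to split, got {len(manifest.records)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x5B117]))
    train_idx: list[int] = []
    test_idx: list[int] = []
    if config.stratified:
        for c in range(k):
            idx = np.flatnonzero(labels == c)
            if len(idx) == 0:
                raise ValueError(f"class {c} has no records; cannot stratify")
            idx = rng.permutation(idx)
            n_tr = int(math.floor(config.split_ratio * len(idx)))
            train_idx.extend(idx[:n_tr].tolist())
            test_idx.extend(idx[n_tr:].tolist())
    else:
        idx = rng.permutation(len(labels))
        n_tr = int(math.floor(config.split_ratio * len(labels)))
        train_idx = idx[:n_tr].tolist()
        test_idx = idx[n_tr:].tolist()
    train_idx.sort()
    test_idx.sort()
    return manifest.subset(train_idx, "train"), manifest.subset(test_idx, "test")


def load_inputs(
    manifest: DatasetManifest, root: str | Path, side: int, maxval: int = 255
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every manifest image into a (N, 1, side, side) batch."""
    root = Path(root)
    xs = np.stack(
        [preprocess_image(load_image(root / r.path), side=side, maxval=maxval)
         for r in manifest.records]
    )
    return xs, manifest.labels


def _accuracy(model: KROMNet, x: np.ndarray, y: np.ndarray) -> float:
    return float((model.predict(x) == y).mean())


def train(
    model: KROMNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainingConfig,
    x_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> tuple[KROMNet, TrainingHistory]:
    """Minimize the cross-entropy objective by seeded mini-batch descent.

    Shuffling is re-seeded per epoch from ``config.seed``; the history
    records the mean batch loss, the training accuracy accumulated from the
    batch forward passes, and (when a test set is given) the end-of-epoch
    test accuracy.
    """
    k = model.spec.num_classes
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    if y_train.min() < 0 or y_train.max() >= k:
        raise ValueError(
            f"label {y_train.min() if y_train.min() < 0 else y_train.max()} "
            f"outside [0, {k - 1}]"
        )
    opt_cls = Adam if config.optimizer == "adam" else SGD
    optimizer = opt_cls(model.params(), lr=config.learning_rate)
    onehot_all = np.zeros((len(y_train), k), dtype=np.float32)
    onehot_all[np.arange(len(y_train)), y_train] = 1.0

    history = TrainingHistory()
    n = len(x_train)
    for epoch in range(1, config.epochs + 1):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, epoch]))
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = x_train[sel]
            yb = onehot_all[sel]
            model.net.zero_grad()
            logits = model.forward_logits(xb)
            loss, dlogits, probs = softmax_cross_entropy(logits, yb)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, batch starting {start}"
                )
            correct += int((probs.argmax(axis=1) == y_train[sel]).sum())
            model.net.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        train_acc = correct / n
        test_acc = (
            _accuracy(model, x_test, np.asarray(y_test, dtype=int))
            if x_test is not None and len(x_test) else float("nan")
        )
        history.append(epoch, train_loss, train_acc, test_acc)
        logger.info(
            "epoch %3d  loss %.6f  train_acc %.4f  test_acc %s",
            epoch, train_loss, train_acc,
            f"{test_acc:.4f}" if math.isfinite(test_acc) else "-",
        )
    return model, history


def save_model(model: KROMNet, path: str | Path) -> None:
    """Serialize weights plus the embedded architecture spec (.npz)."""
    arrays = model.state_arrays()
    arrays["_spec_yaml"] = np.frombuffer(model.spec.to_yaml().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> KROMNet:
    """Rebuild a model from a checkpoint; predictions match the saved one."""
    with np.load(path) as data:
        spec = NetworkSpec.from_yaml(bytes(data["_spec_yaml"]).decode())
        model = build_kromnet(spec, seed=0)
        model.load_state_arrays({k: data[k] for k in data.files if k != "_spec_yaml"})
    return model
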
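"""The knee-ROM classifier architecture and its objective.

The network stacks six convolutional layers (with interleaved 2x2 max
pooling), two dilated convolutional layers that widen the receptive field
without losing spatial resolution, two channel-attention gates that
recalibrate feature channels, and two fully connected layers ending in a
softmax over the K ROM classes (K = 4 or 6).

The functional forms exposed here mirror the building blocks one-to-one:

* ``global_avg_pool``   — per-channel spatial mean M2 of a feature map M1
* ``attention_weights`` — M3 = sigmoid(W2 · relu(W1 · M2)), weights in (0, 1)
* ``recalibrate``       — M4 = M1 gated channel-by-channel by M3
* ``dilated_conv``      — convolution with zeros inserted between kernel
  taps; rate 1 recovers standard convolution exactly
* ``cross_entropy``     — J = −Σ_i Σ_c y_ic log p_ic, reported as the mean
  over the batch so the learning rate is batch-size independent
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import yaml

from .nn import (
    ChannelAttention,
    Conv2d,
    Flatten,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
    softmax,
)

__all__ = [
    "NetworkSpec",
    "PredictionBatch",
    "KROMNet",
    "build_kromnet",
    "global_avg_pool",
    "attention_weights",
    "recalibrate",
    "dilated_conv",
    "cross_entropy",
    "EPS_LOG",
]

#: Probabilities are clipped to at least this value before taking logs.
EPS_LOG = 1e-12

_DEFAULT_CONV_BLOCKS = (
    # (out_channels, kernel, stride, max-pool after?)
    (16, 3, 1, True),
    (32, 3, 1, True),
    (32, 3, 1, False),
    (64, 3, 1, True),
    (64, 3, 1, False),
    (128, 3, 1, True),
)
_DEFAULT_DILATED_BLOCKS = (
    # (out_channels, kernel, dilation rate)
    (128, 3, 2),
    (128, 3, 4),
)


@dataclass
class NetworkSpec:
    """Layer-by-layer configuration of the classifier.

    The architecture is fixed in shape — exactly six conv blocks, two
    dilated blocks, two attention gates, two FC layers — with widths,
    kernels, pooling positions, dilation rates and the attention reduction
    ratio all overridable.
    """

    num_classes: int = 4
    input_side: int = 128
    conv_blocks: tuple = _DEFAULT_CONV_BLOCKS
    dilated_blocks: tuple = _DEFAULT_DILATED_BLOCKS
    attention_positions: tuple = (0, 1)  # after which dilated blocks
    reduction_ratio: int = 16
    fc_hidden: int = 256

    def __post_init__(self) -> None:
        self.conv_blocks = tuple(tuple(b) for b in self.conv_blocks)
        self.dilated_blocks = tuple(tuple(b) for b in self.dilated_blocks)
        self.attention_positions = tuple(self.attention_positions)
        if len(self.conv_blocks) != 6:
            raise ValueError(f"expected exactly 6 conv blocks, got {len(self.conv_blocks)}")
        if len(self.dilated_blocks) != 2:
            raise ValueError(f"expected exactly 2 dilated blocks, got {len(self.dilated_blocks)}")
        if len(self.attention_positions) != 2:
            raise ValueError("expected exactly 2 attention positions")
        if self.num_classes not in (4, 6):
            raise ValueError(f"num_classes must be 4 or 6, got {self.num_classes}")
        for _, _, rate in self.dilated_blocks:
            if rate < 1:
                raise ValueError(f"dilation rate must be >= 1, got {rate}")
        for pos in self.attention_positions:
            ch = self.dilated_blocks[pos][0]
            if ch % self.reduction_ratio != 0:
                raise ValueError(
                    f"reduction ratio {self.reduction_ratio} does not divide "
                    f"attended channel count {ch}"
                )
        if self.input_side % 8 != 0 or self.input_side <= 0:
            raise ValueError(f"input_side must be a positive multiple of 8, got {self.input_side}")

    @property
    def pool_count(self) -> int:
        return sum(1 for b in self.conv_blocks if b[3])

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        return cls(**yaml.safe_load(text))


@dataclass
class PredictionBatch:
    """Class-probability rows paired with one-hot true labels."""

    probs: np.ndarray   # (N, K), rows sum to 1
    onehot: np.ndarray  # (N, K), exactly one 1 per row
    ids: tuple = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        onehot = np.asarray(self.onehot)
        if probs.shape != onehot.shape:
            raise ValueError(f"probs {probs.shape} vs onehot {onehot.shape} shape mismatch")
        if probs.min() < 0 or probs.max() > 1 + 1e-9:
            raise ValueError("probabilities outside [0, 1]")
        rowsums = probs.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > 1e-6:
            raise ValueError("probability rows must sum to 1 within 1e-6")
        if not np.all(onehot.sum(axis=1) == 1) or not np.all(np.isin(onehot, (0, 1))):
            raise ValueError("onehot rows must contain exactly one 1")
        self.probs = probs
        self.onehot = onehot.astype(np.float64)

    @classmethod
    def from_labels(cls, probs: np.ndarray, labels: Sequence[int], ids: tuple = ()) -> "PredictionBatch":
        probs = np.asarray(probs, dtype=np.float64)
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(probs)), np.asarray(labels, dtype=int)] = 1.0
        return cls(probs=probs, onehot=onehot, ids=ids)


def global_avg_pool(m1: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean: (C, H, W) -> (C,)."""
    m1 = np.asarray(m1)
    if m1.ndim != 3 or m1.shape[1] < 1 or m1.shape[2] < 1:
        raise ValueError(f"expected a C x H x W map with H, W >= 1, got shape {m1.shape}")
    return m1.mean(axis=(1, 2))


def attention_weights(
    m2: np.ndarray,
    w1: np.ndarray,
    w2: np.ndarray,
    b1: np.ndarray | None = None,
    b2: np.ndarray | None = None,
) -> np.ndarray:
    """Channel gates sigmoid(W2 · relu(W1 · M2)); outputs strictly in (0, 1)."""
    m2 = np.asarray(m2, dtype=np.float64)
    w1 = np.asarray(w1, dtype=np.float64)
    w2 = np.asarray(w2, dtype=np.float64)
    c = m2.shape[0]
    if w1.shape[1] != c or w2.shape[0] != c or w2.shape[1] != w1.shape[0]:
        raise ValueError(
            f"bottleneck shapes W1 {w1.shape}, W2 {w2.shape} incompatible with C={c}"
        )
    z = w1 @ m2 + (0.0 if b1 is None else np.asarray(b1, dtype=np.float64))
    a = np.maximum(z, 0.0)
    s = w2 @ a + (0.0 if b2 is None else np.asarray(b2, dtype=np.float64))
    return 1.0 / (1.0 + np.exp(-s))


def recalibrate(m1: np.ndarray, m3: np.ndarray) -> np.ndarray:
    """Channel-by-channel product M4[c] = M3[c] * M1[c]."""
    m1 = np.asarray(m1)
    m3 = np.asarray(m3)
    if m1.shape[0] != m3.shape[0]:
        raise ValueError(f"channel mismatch: map has {m1.shape[0]}, weights {m3.shape[0]}")
    return m1 * m3[:, None, None]


def dilated_conv(x: np.ndarray, kernel: np.ndarray, rate: int) -> np.ndarray:
    """Dilated convolution of a feature map, spatial size preserved.

    ``x`` is (C_in, H, W) or (N, C_in, H, W); ``kernel`` is
    (C_out, C_in, k, k) with k odd.  Zero padding of ``rate * (k - 1) / 2``
    per side keeps output spatial dims equal to the input's; the effective
    kernel extent is ``k + (k - 1)(rate - 1)``.
    """
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    x = np.asarray(x)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    kernel = np.asarray(kernel)
    conv = Conv2d(
        kernel.shape[1], kernel.shape[0], kernel.shape[2],
        dilation=rate, padding="same", dtype=x.dtype,
    )
    conv.w.value = kernel.astype(x.dtype)
    conv.b.value = np.zeros(kernel.shape[0], dtype=x.dtype)
    out = conv.forward(x)
    return out[0] if squeeze else out


def cross_entropy(batch: PredictionBatch) -> float:
    """Mean cross-entropy −(1/N) Σ_i Σ_c y_ic log p_ic.

    Probabilities are clipped to ``EPS_LOG`` before the log; the loss is
    nonnegative and zero iff every sample puts probability 1 on its true
    class.
    """
    p = np.clip(batch.probs, EPS_LOG, 1.0)
    n = p.shape[0]
    return float(-(batch.onehot * np.log(p)).sum() / n)


class KROMNet:
    """The assembled classifier: callable on (N, 1, S, S) inputs.

    ``forward_logits`` exposes pre-softmax scores for training;
    ``predict_proba`` applies the softmax head.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x6E7]))
        layers: list[Layer] = []
        in_ch = 1
        side = spec.input_side
        for out_ch, k, stride, pool in spec.conv_blocks:
            layers.append(Conv2d(in_ch, out_ch, k, stride=stride, rng=rng))
            layers.append(ReLU())
            if pool:
                layers.append(MaxPool2d(2))
                side //= 2
            in_ch = out_ch
        self.attention_layers: list[ChannelAttention] = []
        for idx, (out_ch, k, rate) in enumerate(spec.dilated_blocks):
            layers.append(Conv2d(in_ch, out_ch, k, dilation=rate, rng=rng))
            layers.append(ReLU())
            if idx in spec.attention_positions:
                att = ChannelAttention(out_ch, spec.reduction_ratio, rng=rng)
                layers.append(att)
                self.attention_layers.append(att)
            in_ch = out_ch
        layers.append(Flatten())
        flat = in_ch * side * side
        layers.append(Linear(flat, spec.fc_hidden, rng=rng))
        layers.append(ReLU())
        layers.append(Linear(spec.fc_hidden, spec.num_classes, rng=rng))
        self.net = Sequential(layers)
        self.final_side = side

    def params(self) -> list[Param]:
        return self.net.params()

    @property
    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=np.float32))

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [
            softmax(self.forward_logits(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i:03d}": p.value for i, p in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            arr = arrays[f"p{i:03d}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"parameter {i} shape {arr.shape} != {p.value.shape}")
            p.value = arr.astype(p.value.dtype)


def build_kromnet(spec: NetworkSpec, seed: int = 0) -> KROMNet:
    """Construct the classifier with seeded, reproducible initialization."""
    return KROMNet(spec, seed=seed)
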
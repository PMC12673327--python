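"""Evaluation: confusion matrices, precision/recall/F1/accuracy, attention maps.

Per-class metrics follow the standard one-vs-rest definitions —
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean —
reported macro-averaged (equal class weight); accuracy is the micro form
trace/total x 100%.  Micro and support-weighted averages are emitted
alongside for comparison.  A class never predicted (or absent from the
truth) contributes 0 to the affected macro term, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .network import KROMNet

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "export_attention_maps",
    "write_report",
    "save_confusion_heatmap",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.counts,
            index=[f"true_{i}" for i in range(self.k)],
            columns=[f"pred_{i}" for i in range(self.k)],
        ).to_csv(path)


@dataclass
class MetricsReport:
    """Macro precision/recall/F1 (fractions) and micro accuracy (percent)."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    per_class: pd.DataFrame
    micro_precision: float = float("nan")
    weighted_f1: float = float("nan")


def confusion(pred_labels, true_labels, k: int) -> ConfusionMatrix:
    """Tally counts[i, j] = #{true == i and predicted == j}."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(true)} truths")
    for name, arr in (("predicted", pred), ("true", true)):
        if arr.size and (arr.min() < 0 or arr.max() >= k):
            raise ValueError(f"{name} label outside [0, {k - 1}]")
    counts = _sk_confusion(true, pred, labels=np.arange(k))
    return ConfusionMatrix(counts)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and macro precision/recall/F1 plus micro accuracy."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    tp, fp, fn = cm.tp.astype(float), cm.fp.astype(float), cm.fn.astype(float)
    support = cm.counts.sum(axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)

    if (tp + fp == 0).any():
        logger.warning(
            "classes %s were never predicted; their precision is recorded as 0",
            np.flatnonzero(tp + fp == 0).tolist(),
        )
    if (support == 0).any():
        logger.warning(
            "classes %s have no true instances; their recall is recorded as 0",
            np.flatnonzero(support == 0).tolist(),
        )

    per_class = pd.DataFrame(
        {
            "class": np.arange(cm.k),
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support.astype(int),
        }
    )
    micro_tp = tp.sum()
    micro_precision = float(micro_tp / (micro_tp + fp.sum())) if micro_tp + fp.sum() > 0 else 0.0
    weighted_f1 = float((f1 * support).sum() / support.sum()) if support.sum() > 0 else 0.0
    return MetricsReport(
        precision=float(precision.mean()),
        recall=float(recall.mean()),
        f1=float(f1.mean()),
        accuracy=float(np.trace(cm.counts) / cm.total * 100.0),
        per_class=per_class,
        micro_precision=micro_precision,
        weighted_f1=weighted_f1,
    )


def export_attention_maps(model: KROMNet, x: np.ndarray) -> list[dict]:
    """Channel-attention gates and spatial overlays for one prepared input.

    Runs a forward pass and, for each attention layer, returns its gate
    vector M3 (values in (0, 1)), the pooled channel descriptor M2, and a
    weight-scaled channel-mean map min-max normalized to [0, 1] and
    upsampled (nearest-neighbor) to the network input resolution.
    """
    if not model.attention_layers:
        raise ValueError("model has no channel-attention layers")
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    # Forward through the stack, capturing each attention layer's input map.
    feats: list[np.ndarray] = []
    h = x
    for layer in model.net.layers:
        inp = h
        h = layer.forward(h)
        if layer in model.attention_layers:
            feats.append((inp, h))

    side = model.spec.input_side
    out = []
    for (m1, m4), att in zip(feats, model.attention_layers):
        weights = att.last_weights[0]
        mean_map = m4[0].mean(axis=0)
        lo, hi = float(mean_map.min()), float(mean_map.max())
        norm = (mean_map - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_map)
        reps = side // norm.shape[0]
        overlay = np.kron(norm, np.ones((reps, reps), dtype=norm.dtype))
        out.append(
            {
                "weights": weights.astype(np.float64),
                "pooled": att.last_pooled[0].astype(np.float64),
                "overlay": overlay,
            }
        )
    return out


def save_attention_heatmaps(maps: list[dict], out_dir: str | Path, prefix: str = "attention") -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(maps):
        p = out_dir / f"{prefix}_layer{i}.png"
        plt.imsave(p, m["overlay"], cmap="jet", vmin=0.0, vmax=1.0)
        paths.append(p)
    return paths


def save_confusion_heatmap(cm: ConfusionMatrix, path: str | Path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4 + 0.3 * cm.k, 4 + 0.3 * cm.k))
    im = ax.imshow(cm.counts, cmap="Blues")
    for i in range(cm.k):
        for j in range(cm.k):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="white" if cm.counts[i, j] > cm.counts.max() / 2 else "black")
    ax.set_xlabel("Predicted label")
    ax.set_ylabel("True label")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(report: MetricsReport, cm: ConfusionMatrix, out: str | Path) -> dict[str, Path]:
    """Write the metrics CSV, confusion CSV and confusion heatmap PNG.

    The metrics CSV carries one row per class plus a macro row, fractions
    to 4 decimals and the accuracy percentage to 2 decimals.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    metrics_path = out / "metrics.csv"
    rows = []
    for row in report.per_class.itertuples(index=False):
        rows.append(
            f"{int(row._0)},{row.precision:.4f},{row.recall:.4f},{row.f1:.4f},{int(row.support)}"
        )
    lines = ["class,precision,recall,f1,support"]
    lines.extend(rows)
    lines.append(f"macro,{report.precision:.4f},{report.recall:.4f},{report.f1:.4f},{cm.total}")
    lines.append(f"accuracy_percent,{report.accuracy:.2f},,,")
    metrics_path.write_text("\n".join(lines) + "\n")

    cm_path = out / "confusion_matrix.csv"
    cm.to_csv(cm_path)
    fig_path = out / "confusion_matrix.png"
    save_confusion_heatmap(cm, fig_path)
    return {"metrics": metrics_path, "confusion_csv": cm_path, "confusion_png": fig_path}
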
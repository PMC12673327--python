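"""End-to-end orchestration: generate -> preprocess -> train -> evaluate.

A run directory is self-describing: it holds the resolved configuration,
the seed, per-epoch history, metrics and confusion matrices, attention
maps for one test image per class, and a ``run.log``.  Re-running with the
same configuration and seed reproduces the metrics byte-for-byte.
"""

from __future__ import annotations

import copy
import json
import logging
import platform
import sys
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import (
    compute_metrics,
    confusion,
    export_attention_maps,
    save_attention_heatmaps,
    write_report,
)
from .network import NetworkSpec, build_kromnet
from .synthgen import (
    PUBLISHED_FOUR_CLASS_COUNTS,
    PUBLISHED_SIX_CLASS_COUNTS,
    DatasetManifest,
    generate_dataset,
)
from .training import TrainingConfig, load_inputs, save_model, split_dataset, train

__all__ = ["DEFAULT_CONFIG", "PipelineConfig", "run_end_to_end", "make_fixtures"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "global_seed": 0,
    "output_root": "runs",
    "dataset": {
        "schemes": ["four_class"],
        "four_class_counts": list(PUBLISHED_FOUR_CLASS_COUNTS),
        "six_class_counts": list(PUBLISHED_SIX_CLASS_COUNTS),
        "canvas": 240,
    },
    "imaging": {"input_side": 128, "maxval": 255},
    "network": {
        "reduction_ratio": 16,
        "fc_hidden": 256,
    },
    "training": {
        "batch_size": 16,
        "learning_rate": 0.0002,
        "epochs": 100,
        "split_ratio": 0.8,
        "optimizer": "adam",
        "stratified": True,
    },
    "evaluation": {"attention_examples": 1},
}


class PipelineConfig:
    """Validated nested configuration; unknown keys are rejected by name."""

    def __init__(self, overrides: dict | None = None):
        self.data = copy.deepcopy(DEFAULT_CONFIG)
        if overrides:
            self._merge(self.data, overrides, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls(overrides)

    def _merge(self, base: dict, overrides: dict, path: str) -> None:
        for key, value in overrides.items():
            where = f"{path}.{key}" if path else key
            if key not in base:
                raise ValueError(f"unknown configuration key: {where!r}")
            if isinstance(base[key], dict):
                if not isinstance(value, dict):
                    raise ValueError(f"configuration key {where!r} must be a mapping")
                self._merge(base[key], value, where)
            else:
                base[key] = value

    def __getitem__(self, key: str):
        return self.data[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=False)


def _setup_run_logging(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("kromnet").addHandler(handler)
    logging.getLogger("kromnet").setLevel(logging.INFO)
    return handler


def run_end_to_end(config: PipelineConfig, run_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline for every requested label scheme."""
    seed = int(config["global_seed"])
    run_dir = Path(run_dir) if run_dir is not None else (
        Path(config["output_root"]) / f"run_seed{seed}"
    )
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(run_dir)
    try:
        (run_dir / "config.yaml").write_text(config.to_yaml())
        (run_dir / "environment.json").write_text(
            json.dumps(
                {
                    "kromnet": __version__,
                    "python": sys.version.split()[0],
                    "numpy": np.__version__,
                    "platform": platform.platform(),
                    "seed": seed,
                },
                indent=2,
            )
        )
        for scheme in config["dataset"]["schemes"]:
            _run_scheme(config, scheme, run_dir, seed)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logging.getLogger("kromnet").removeHandler(handler)
        handler.close()
    return run_dir


def _run_scheme(config: PipelineConfig, scheme: str, run_dir: Path, seed: int) -> dict:
    if scheme not in ("four_class", "six_class"):
        raise ValueError(f"stage generate: unknown scheme {scheme!r}")
    k = 4 if scheme == "four_class" else 6
    counts = config["dataset"][f"{'four' if k == 4 else 'six'}_class_counts"]
    canvas = int(config["dataset"]["canvas"])
    side = int(config["imaging"]["input_side"])
    scheme_dir = run_dir / scheme

    t0 = time.time()
    logger.info("[%s] generating %d images (canvas %d)", scheme, sum(counts), canvas)
    manifest = generate_dataset(scheme, counts, canvas, scheme_dir / "dataset", seed)
    logger.info("[%s] generation took %.1fs", scheme, time.time() - t0)

    tcfg = TrainingConfig(
        batch_size=int(config["training"]["batch_size"]),
        learning_rate=float(config["training"]["learning_rate"]),
        epochs=int(config["training"]["epochs"]),
        split_ratio=float(config["training"]["split_ratio"]),
        optimizer=str(config["training"]["optimizer"]),
        seed=seed,
        stratified=bool(config["training"]["stratified"]),
    )
    train_manifest, test_manifest = split_dataset(manifest, tcfg)
    merged = DatasetManifest(
        records=train_manifest.records + test_manifest.records,
        scheme=scheme,
        class_counts=manifest.class_counts,
        global_seed=manifest.global_seed,
    )
    merged.to_csv(scheme_dir / "dataset" / "manifest.csv")

    t0 = time.time()
    logger.info("[%s] preprocessing at input side %d", scheme, side)
    x_train, y_train = load_inputs(train_manifest, scheme_dir / "dataset", side,
                                   int(config["imaging"]["maxval"]))
    x_test, y_test = load_inputs(test_manifest, scheme_dir / "dataset", side,
                                 int(config["imaging"]["maxval"]))
    logger.info("[%s] preprocessing took %.1fs", scheme, time.time() - t0)

    spec = NetworkSpec(
        num_classes=k,
        input_side=side,
        reduction_ratio=int(config["network"]["reduction_ratio"]),
        fc_hidden=int(config["network"]["fc_hidden"]),
    )
    model = build_kromnet(spec, seed=seed)
    logger.info("[%s] model has %d parameters", scheme, model.num_parameters)

    t0 = time.time()
    model, history = train(model, x_train, y_train, tcfg, x_test, y_test)
    logger.info("[%s] training took %.1fs", scheme, time.time() - t0)
    history.to_csv(scheme_dir / "history.csv")
    save_model(model, scheme_dir / "model.npz")

    pred = model.predict(x_test)
    cm = confusion(pred, y_test, k)
    report = compute_metrics(cm)
    write_report(report, cm, scheme_dir)
    logger.info(
        "[%s] test accuracy %.2f%%  macro P/R/F1 %.4f/%.4f/%.4f",
        scheme, report.accuracy, report.precision, report.recall, report.f1,
    )

    n_examples = int(config["evaluation"]["attention_examples"])
    if n_examples > 0:
        for c in range(k):
            idx = np.flatnonzero(y_test == c)[:n_examples]
            for j, i in enumerate(idx):
                maps = export_attention_maps(model, x_test[i])
                save_attention_heatmaps(
                    maps, scheme_dir / "attention", prefix=f"class{c}_example{j}"
                )
    return {"accuracy": report.accuracy, "report": report, "cm": cm}


def make_fixtures(out: str | Path, canvas: int = 96) -> dict[str, Path]:
    """Write the deterministic fixture datasets used by the test suite.

    * ``overfit16``: 16 images, 4 per four-class label (memorization check)
    * ``noiseless64``: 64 images, 16 per four-class label, rendered clean
    * ``paper_scale.yaml``: a request spec for the full-size four-class
      composition (300/243/272/288) without rendering it
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    fixtures: dict[str, Path] = {}

    d = out / "overfit16"
    generate_dataset("four_class", (4, 4, 4, 4), canvas, d, global_seed=16)
    fixtures["overfit16"] = d

    d = out / "noiseless64"
    manifest = generate_dataset("four_class", (16, 16, 16, 16), canvas, d,
                                global_seed=64, write_images=False)
    from PIL import Image

    from .synthgen import noiseless, record_seed, render_limb, sample_pose

    (d / "images").mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(manifest.records):
        pose = noiseless(sample_pose("four_class", rec.label4, record_seed(64, i), canvas=canvas))
        Image.fromarray(render_limb(pose, canvas, canvas), mode="L").save(d / rec.path)
    fixtures["noiseless64"] = d

    spec_path = out / "paper_scale.yaml"
    spec_path.write_text(
        yaml.safe_dump(
            {
                "scheme": "four_class",
                "class_counts": list(PUBLISHED_FOUR_CLASS_COUNTS),
                "canvas": 240,
                "global_seed": 1103,
            },
            sort_keys=False,
        )
    )
    fixtures["paper_scale"] = spec_path
    return fixtures
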
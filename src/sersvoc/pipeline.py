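"""End-to-end orchestration: simulate -> featurize -> train -> evaluate.

A single root seed is fanned out to the stochastic stages by hashing
the stage name (CRC-32), so changing one stage's draws never perturbs
another's, and a rerun with the same config reproduces the report
bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify, evaluate, featurize, synthetic_data
from .spectra_io import ALDEHYDE_CLASSES, save_dataset

logger = logging.getLogger("sersvoc")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    preset: str = "easy"
    n_per_class: int = 108
    concentration: float = 1e-7
    train_size: int = 540
    epochs: int = 5000
    learning_rate: float = 0.5
    hidden_activation: str = "sigmoid"
    band_edges: tuple[float, ...] = featurize.DEFAULT_BAND_EDGES
    out_dir: str | None = None
    seed: int = 0
    write_spectra: bool = False

    def __post_init__(self) -> None:
        if self.preset not in synthetic_data.PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key=value config file (comments with '#')."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            typ = cls.__dataclass_fields__[key].type
            if key == "band_edges":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            elif typ == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig) -> evaluate.EvalReport:
    """Run simulate -> featurize -> split -> train -> evaluate.

    Writes manifest (optional), features, model and report under
    ``config.out_dir`` when one is given.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("stage %s (seed %d)", name, stage_seed(config.seed, name))
        return time.perf_counter()

    t0 = _stage("simulate")
    gen_cfg = synthetic_data.PRESETS[config.preset]()
    dataset = synthetic_data.generate_dataset(
        n_per_class=config.n_per_class,
        concentration=config.concentration,
        config=gen_cfg,
        seed=stage_seed(config.seed, "simulate"),
    )
    if out and config.write_spectra:
        save_dataset(dataset, out / "spectra")
    logger.info("simulate: %d spectra in %.2fs", len(dataset), time.perf_counter() - t0)

    t0 = _stage("featurize")
    scheme = featurize.BandScheme(tuple(config.band_edges))
    table = featurize.featurize_dataset(dataset, scheme, normalize=True)
    if out:
        table.to_csv(out / "features.csv", index=False)

    t0 = _stage("split")
    if config.train_size >= len(table):
        raise ValueError(
            f"split stage: train_size {config.train_size} >= dataset size {len(table)}"
        )
    train_df, test_df = classify.split_dataset(
        table, config.train_size, stage_seed(config.seed, "split")
    )

    t0 = _stage("train")
    feat_cols = [c for c in table.columns if c != "label"]
    clf = classify.ShallowSoftmaxClassifier(
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        activation=config.hidden_activation,
        random_state=stage_seed(config.seed, "train"),
        classes=ALDEHYDE_CLASSES,
    )
    clf.fit(train_df[feat_cols].to_numpy(), train_df["label"].to_numpy())
    if out:
        save_model(clf, out / "model.json")
    logger.info("train: final loss %.4f in %.2fs", clf.loss_history_[-1],
                time.perf_counter() - t0)

    _stage("evaluate")
    report = evaluate.evaluate_model(
        clf, test_df[feat_cols].to_numpy(), test_df["label"].to_numpy(),
        class_order=ALDEHYDE_CLASSES,
    )
    if out:
        write_report(report, out / "report.json")
    return report


def save_model(clf: classify.ShallowSoftmaxClassifier, path: str | Path) -> None:
    payload = {
        "classes": [str(c) for c in clf.classes_],
        "activation": clf.activation,
        "W1": clf.params_.W1.tolist(),
        "b1": clf.params_.b1.tolist(),
        "W2": clf.params_.W2.tolist(),
        "b2": clf.params_.b2.tolist(),
        "config": {
            "learning_rate": clf.learning_rate,
            "epochs": clf.epochs,
            "random_state": clf.random_state,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> classify.ShallowSoftmaxClassifier:
    payload = json.loads(Path(path).read_text())
    clf = classify.ShallowSoftmaxClassifier(
        activation=payload["activation"], classes=payload["classes"],
        **{k: payload["config"][k] for k in ("learning_rate", "epochs", "random_state")},
    )
    clf.classes_ = np.asarray(payload["classes"])
    clf.params_ = classify.NetworkParams(
        payload["W1"], payload["b1"], payload["W2"], payload["b2"]
    )
    clf.n_features_in_ = clf.params_.W1.shape[0]
    return clf


def write_report(report: evaluate.EvalReport, path: str | Path) -> None:
    payload = {
        "accuracy": report.accuracy,
        "confusion_counts": report.confusion.counts.tolist(),
        "confusion_normalized": report.confusion.normalized.tolist(),
        "class_order": list(report.confusion.class_order),
        "per_class_auc": report.per_class_auc,
        "macro_auc": report.macro_auc,
        "micro_auc": report.micro_auc,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
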
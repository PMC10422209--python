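"""End-to-end orchestration: generate -> train -> score -> evaluate.

One global seed is fanned out into named substreams (phantom, encoder,
train, panel) so stages are independently re-runnable yet the full
pipeline is reproducible: two invocations with the same config and seed
produce identical artifacts, including byte-identical report JSON.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from ._seeds import child_seed
from .encoder import Encoder, EncoderConfig, build_encoder
from .evalstats import EvaluationReport, evaluate_scores
from .phantom import PhantomConfig, generate_phantom_dataset, load_dataset, save_dataset
from .scoring import (
    BaselinePanel,
    build_baseline_panel,
    frame_to_scores,
    score_dataset,
    scores_to_frame,
)
from .supcon import TrainConfig, TrainResult, train

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "phantom": {
        "n_subjects_per_stage": 40,
        "images_per_subject": 3,
        "image_size": 64,
        "noise_sd": 0.03,
        "subject_effect_sd": 0.02,
    },
    "encoder": {
        "backbone_depth": "small",
        "feature_dim": 1024,
        "projection_dim": 128,
        "projection_layers": 1,
    },
    "training": {
        "batch_size": 32,
        "temperature_tau": 0.07,
        "epochs": 10,
        "learning_rate": 3e-4,
        "augmentation": "none",
    },
    "evaluation": {"equal_var": False, "n_bins": 10},
}


def merge_config(overrides: Mapping[str, Any] | None) -> dict:
    """Defaults overlaid with a (possibly partial) override mapping."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (overrides or {}).items():
        if section not in config:
            raise KeyError(f"unknown config section {section!r}")
        config[section].update(values)
    return config


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config file and merge it over the defaults."""
    if path is None:
        return merge_config(None)
    import yaml

    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def config_hash(config: Mapping[str, Any], seed: int) -> str:
    blob = json.dumps({"config": config, "seed": seed}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    """Everything the full pipeline computes, in memory."""

    images: list
    encoder: Encoder
    history: pd.DataFrame
    panel: BaselinePanel
    records: list
    report: EvaluationReport


def run_pipeline(config: Mapping[str, Any] | None = None, seed: int = 0) -> PipelineResult:
    """Run the whole pipeline in memory and return all intermediates."""
    config = merge_config(config)
    images = generate_phantom_dataset(
        PhantomConfig(**config["phantom"], seed=child_seed(seed, "phantom"))
    )
    encoder = build_encoder(
        EncoderConfig(**config["encoder"], seed=child_seed(seed, "encoder"))
    )
    train_images = [im for im in images if im.split == "train"]
    test_images = [im for im in images if im.split == "test"]
    result: TrainResult = train(
        encoder, train_images,
        TrainConfig(**config["training"], seed=child_seed(seed, "train")),
    )
    panel = build_baseline_panel(train_images, encoder, child_seed(seed, "panel"))
    records = score_dataset(test_images, encoder, panel)
    report = evaluate_scores(records, **config["evaluation"])
    return PipelineResult(
        images=images, encoder=encoder, history=result.history,
        panel=panel, records=records, report=report,
    )


# ---------------------------------------------------------------------------
# on-disk stage commands (the CLI wraps these)
# ---------------------------------------------------------------------------

def cmd_generate(config: Mapping[str, Any], seed: int, out_dir: str | Path,
                 force: bool = False) -> Path:
    """Write a phantom dataset, metadata CSV and a run manifest."""
    config = merge_config(config)
    out_dir = Path(out_dir) / "dataset"
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass force=True to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    images = generate_phantom_dataset(
        PhantomConfig(**config["phantom"], seed=child_seed(seed, "phantom"))
    )
    meta_path = save_dataset(images, out_dir)
    manifest = {
        "seed": int(seed),
        "config": config["phantom"],
        "config_hash": config_hash(config["phantom"], seed),
        "n_images": len(images),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return meta_path


def cmd_train(config: Mapping[str, Any], seed: int, out_dir: str | Path) -> Path:
    """Train on the train split; write checkpoint and loss-history CSV."""
    config = merge_config(config)
    out_dir = Path(out_dir)
    meta_path = out_dir / "dataset" / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no dataset at {meta_path}; run generate first")
    images = load_dataset(meta_path)
    train_images = [im for im in images if im.split == "train"]
    encoder = build_encoder(
        EncoderConfig(**config["encoder"], seed=child_seed(seed, "encoder"))
    )
    result = train(
        encoder, train_images,
        TrainConfig(**config["training"], seed=child_seed(seed, "train")),
    )
    ckpt = out_dir / "encoder.npz"
    encoder.save(ckpt)
    result.history.to_csv(out_dir / "loss_history.csv", index=False)
    return ckpt


def cmd_score(config: Mapping[str, Any], seed: int, out_dir: str | Path) -> Path:
    """Score the test split against a seeded baseline panel; write CSV."""
    merge_config(config)  # validate sections
    out_dir = Path(out_dir)
    ckpt = out_dir / "encoder.npz"
    if not ckpt.exists():
        raise FileNotFoundError(f"no checkpoint at {ckpt}; run train first")
    meta_path = out_dir / "dataset" / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no dataset at {meta_path}; run generate first")
    encoder = Encoder.load(ckpt)
    images = load_dataset(meta_path)
    train_images = [im for im in images if im.split == "train"]
    test_images = [im for im in images if im.split == "test"]
    panel = build_baseline_panel(train_images, encoder, child_seed(seed, "panel"))
    records = score_dataset(test_images, encoder, panel)
    scores_path = out_dir / "scores.csv"
    scores_to_frame(records).to_csv(scores_path, index=False)
    panel.save_manifest(out_dir / "panel_manifest.json")
    return scores_path


def cmd_evaluate(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Evaluate a scores CSV; write report JSON and flat CSV tables."""
    config = merge_config(config)
    out_dir = Path(out_dir)
    scores_path = out_dir / "scores.csv"
    if not scores_path.exists():
        raise FileNotFoundError(f"no scores at {scores_path}; run score first")
    frame = pd.read_csv(scores_path)
    if "stage" not in frame.columns or frame["stage"].isna().any():
        raise ValueError("scores CSV must carry a complete 'stage' column")
    records = frame_to_scores(frame)
    report = evaluate_scores(records, **config["evaluation"])
    report_path = out_dir / "report.json"
    report.save(report_path)
    report.write_tables(out_dir / "tables")
    return report_path


def cmd_run_all(config: Mapping[str, Any], seed: int, out_dir: str | Path,
                force: bool = False) -> Path:
    cmd_generate(config, seed, out_dir, force=force)
    cmd_train(config, seed, out_dir)
    cmd_score(config, seed, out_dir)
    return cmd_evaluate(config, out_dir)
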
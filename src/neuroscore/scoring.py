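"""Neurological-function scoring against a healthy baseline panel.

The score of a test image is 100x the cosine similarity between its
embedding and the embedding of a healthy (NC) baseline image, averaged
over a panel of five baseline individuals drawn from the training split.
Averaging across five healthy subjects cancels the subtle neurological
differences between individual healthy brains. With unit-hypersphere
embeddings the cosine is simply the dot product, so each per-baseline
score lies in [-100, 100]; no clamping is applied — a negative score is
informative, not an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoder import Encoder, embed_batch
from .phantom import LabeledImage

PANEL_SIZE = 5


@dataclass
class BaselinePanel:
    """Five healthy (NC) training-split individuals and their embeddings."""

    baseline_images: list[LabeledImage]
    baseline_embeddings: np.ndarray
    subject_ids: list[str]
    selection_seed: int
    encoder_fingerprint: str | None = None

    def __post_init__(self):
        if len(self.baseline_images) != PANEL_SIZE:
            raise ValueError(f"a baseline panel holds exactly {PANEL_SIZE} images")
        if len(set(self.subject_ids)) != PANEL_SIZE:
            raise ValueError("panel subjects must be pairwise distinct")
        for im in self.baseline_images:
            if im.stage != "NC":
                raise ValueError("panel members must be stage NC")
            if im.split != "train":
                raise ValueError("panel members must come from the training split")

    def manifest(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "selection_seed": int(self.selection_seed),
            "encoder_fingerprint": self.encoder_fingerprint,
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2, sort_keys=True))


@dataclass
class ScoreRecord:
    """Per-image severity score with its five per-baseline components."""

    subject_id: str
    image_index: int
    stage: str | None
    per_baseline_scores: np.ndarray = field(repr=False)
    score: float = 0.0

    def __post_init__(self):
        self.per_baseline_scores = np.asarray(self.per_baseline_scores, dtype=float)
        if self.per_baseline_scores.shape != (PANEL_SIZE,):
            raise ValueError(f"expected {PANEL_SIZE} per-baseline scores")
        self.score = float(self.per_baseline_scores.mean())


def build_baseline_panel(
    train_images: Sequence[LabeledImage], encoder: Encoder, seed: int
) -> BaselinePanel:
    """Randomly select five distinct healthy training subjects and embed them.

    One image is sampled per selected subject ("baseline individuals" are
    people, not images). Deterministic for a fixed seed.
    """
    by_subject: dict[str, list[LabeledImage]] = {}
    for im in train_images:
        if im.stage == "NC" and im.split == "train":
            by_subject.setdefault(im.subject_id, []).append(im)
    subjects = sorted(by_subject)
    if len(subjects) < PANEL_SIZE:
        raise ValueError(
            f"need at least {PANEL_SIZE} distinct NC training subjects, "
            f"found {len(subjects)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
    chosen = [subjects[i] for i in rng.choice(len(subjects), PANEL_SIZE, replace=False)]
    picked = [by_subject[sid][int(rng.integers(len(by_subject[sid])))] for sid in chosen]
    embeddings = embed_batch(encoder, picked)
    return BaselinePanel(
        baseline_images=picked,
        baseline_embeddings=embeddings,
        subject_ids=chosen,
        selection_seed=int(seed),
        encoder_fingerprint=encoder.fingerprint(),
    )


def cosine_score(z_test: np.ndarray, z_base: np.ndarray) -> float:
    """100x the cosine similarity of two embeddings; in [-100, 100]."""
    z_test = np.asarray(z_test, dtype=float)
    z_base = np.asarray(z_base, dtype=float)
    nt, nb = np.linalg.norm(z_test), np.linalg.norm(z_base)
    if nt == 0.0 or nb == 0.0:
        raise ValueError("cannot score a zero-norm embedding")
    return float(100.0 * (z_test @ z_base) / (nt * nb))


def _check_panel(encoder: Encoder, panel: BaselinePanel) -> None:
    if (
        panel.encoder_fingerprint is not None
        and panel.encoder_fingerprint != encoder.fingerprint()
    ):
        raise ValueError(
            "baseline panel was built with a different encoder checkpoint"
        )


def score_image(
    image: LabeledImage, encoder: Encoder, panel: BaselinePanel,
    image_index: int = 0,
) -> ScoreRecord:
    """Score one image: mean of its five per-baseline cosine scores."""
    _check_panel(encoder, panel)
    z = embed_batch(encoder, [image])[0]
    per = np.array([cosine_score(z, zb) for zb in panel.baseline_embeddings])
    return ScoreRecord(
        subject_id=image.subject_id, image_index=image_index, stage=image.stage,
        per_baseline_scores=per,
    )


def score_dataset(
    images: Sequence[LabeledImage], encoder: Encoder, panel: BaselinePanel
) -> list[ScoreRecord]:
    """Score every image; one record per image, order preserved."""
    images = list(images)
    if not images:
        raise ValueError("cannot score an empty image collection")
    _check_panel(encoder, panel)
    z = embed_batch(encoder, images)
    per_all = 100.0 * (z @ panel.baseline_embeddings.T)  # (n, 5)
    return [
        ScoreRecord(
            subject_id=im.subject_id, image_index=i, stage=im.stage,
            per_baseline_scores=per_all[i],
        )
        for i, im in enumerate(images)
    ]


def scores_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Tabulate records (CSV-ready; round-trips via :func:`frame_to_scores`)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "image_index": [r.image_index for r in records],
            "stage": [r.stage for r in records],
            "score": [r.score for r in records],
            **{
                f"per_baseline_{k + 1}": [r.per_baseline_scores[k] for r in records]
                for k in range(PANEL_SIZE)
            },
        }
    )


def frame_to_scores(frame: pd.DataFrame) -> list[ScoreRecord]:
    cols = [f"per_baseline_{k + 1}" for k in range(PANEL_SIZE)]
    return [
        ScoreRecord(
            subject_id=str(row.subject_id), image_index=int(row.image_index),
            stage=None if pd.isna(row.stage) else str(row.stage),
            per_baseline_scores=np.array([getattr(row, c) for c in cols]),
        )
        for row in frame.itertuples(index=False)
    ]


def aggregate_by_subject(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Mean score per subject (optional aggregation; scoring is per image)."""
    frame = scores_to_frame(records)
    return (
        frame.groupby("subject_id")
        .agg(stage=("stage", "first"), score=("score", "mean"),
             n_images=("score", "size"))
        .reset_index()
    )
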
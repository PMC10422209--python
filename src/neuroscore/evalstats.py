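"""Evaluation battery relating severity scores to ordinal disease stages.

Covers correlation with stage (Pearson and Spearman, signed plus
percentage-of-absolute-value display), pairwise two-sample t-tests,
threshold-based two-class and three-class sensitivity/specificity/accuracy,
dispersion statistics of the min-max-normalized score, and Pareto bins.

Stages are coded NC=0, MCI=1, AD=2 (Spearman is invariant to any monotone
recoding). Because the score is a similarity to healthy baselines, a
correctly trained model yields scores that decrease with severity, hence a
negative Pearson correlation with the stage code; magnitudes are rendered
as percentages for tabular display.

Thresholding continuous scores into classes uses accuracy-maximizing
cut-points found by exhaustive scan over midpoints of sorted unique
scores, with the class-to-interval mapping fixed by the group mean order.
By default the cut-points are selected on the same set being evaluated; a
separate selection set may be supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoreRecord

STAGE_CODING: Mapping[str, int] = {"NC": 0, "MCI": 1, "AD": 2}

#: Rounding precision (decimals) used to discretize normalized scores
#: before computing the modal frequency for the variation ratio.
VARIATION_RATIO_DECIMALS = 2


class UndefinedStatisticError(ValueError):
    """Raised when a requested statistic is undefined for the input."""


def _as_arrays(scores, stages):
    scores = np.asarray(scores, dtype=float)
    stages = np.asarray(stages)
    if scores.shape != stages.shape:
        raise ValueError("scores and stages must have equal length")
    return scores, stages


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    pearson: float
    spearman: float

    @property
    def pearson_abs_pct(self) -> float:
        return abs(self.pearson) * 100.0

    @property
    def spearman_abs_pct(self) -> float:
        return abs(self.spearman) * 100.0


def correlation_with_stage(
    scores, stages, coding: Mapping[str, int] | None = None
) -> CorrelationResult:
    """Pearson and Spearman correlation between score and ordinal stage."""
    scores, stages = _as_arrays(scores, stages)
    coding = dict(coding or STAGE_CODING)
    if scores.size < 3:
        raise UndefinedStatisticError("need at least 3 observations")
    codes = np.array([coding[s] for s in stages], dtype=float)
    if np.unique(codes).size < 2:
        raise UndefinedStatisticError("need at least 2 distinct stages")
    if np.ptp(scores) == 0:
        raise UndefinedStatisticError("correlation undefined for constant scores")
    pearson = stats.pearsonr(scores, codes).statistic
    spearman = stats.spearmanr(scores, codes).statistic
    return CorrelationResult(pearson=float(pearson), spearman=float(spearman))


# ---------------------------------------------------------------------------
# pairwise t-tests
# ---------------------------------------------------------------------------

STAGE_PAIRS = (("NC", "MCI"), ("MCI", "AD"), ("NC", "AD"))


def pairwise_ttests(scores, stages, equal_var: bool = False) -> dict[str, dict]:
    """Two-sided two-sample t-tests for NC/MCI, MCI/AD and NC/AD.

    ``equal_var=False`` (default) is the unequal-variance Welch test;
    ``equal_var=True`` gives the pooled-variance variant.
    """
    scores, stages = _as_arrays(scores, stages)
    out = {}
    for a, b in STAGE_PAIRS:
        ga, gb = scores[stages == a], scores[stages == b]
        for name, g in ((a, ga), (b, gb)):
            if g.size < 2:
                raise ValueError(
                    f"group {name} has {g.size} member(s); need at least 2"
                )
        res = stats.ttest_ind(ga, gb, equal_var=equal_var)
        out[f"{a}/{b}"] = {"t": float(res.statistic), "p": float(res.pvalue)}
    return out


# ---------------------------------------------------------------------------
# threshold classification
# ---------------------------------------------------------------------------

def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between sorted unique values plus all/none sentinels."""
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    positive_stage: str
    low_score_is_positive: bool
    confusion: dict = field(default_factory=dict)  # tp / fn / tn / fp


def _binary_counts(scores, is_pos, thr, low_is_pos):
    pred_pos = scores <= thr if low_is_pos else scores >= thr
    tp = int(np.sum(pred_pos & is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    return tp, fn, tn, fp


def binary_threshold_metrics(
    scores, stages, task: tuple[str, str],
    selection_scores=None, selection_stages=None,
) -> BinaryMetrics:
    """Two-class metrics with an accuracy-maximizing score cut-point.

    ``task`` is an ordered stage pair; the later (more severe) stage is the
    positive class. Whether a low score votes positive is inferred from the
    group means on the selection set. Ties in accuracy break toward higher
    sensitivity, then toward the smaller threshold.
    """
    scores, stages = _as_arrays(scores, stages)
    neg_stage, pos_stage = task
    if STAGE_CODING[pos_stage] < STAGE_CODING[neg_stage]:
        raise ValueError("task must be ordered (less severe, more severe)")
    mask = (stages == neg_stage) | (stages == pos_stage)
    scores, stages = scores[mask], stages[mask]
    for st in task:
        if not np.any(stages == st):
            raise ValueError(f"stage {st} absent from the evaluation data")

    if selection_scores is None:
        sel_scores, sel_stages = scores, stages
    else:
        sel_scores, sel_stages = _as_arrays(selection_scores, selection_stages)
        sel_mask = (sel_stages == neg_stage) | (sel_stages == pos_stage)
        sel_scores, sel_stages = sel_scores[sel_mask], sel_stages[sel_mask]
    sel_pos = sel_stages == pos_stage
    low_is_pos = sel_scores[sel_pos].mean() < sel_scores[~sel_pos].mean()

    best = None
    for thr in _candidate_thresholds(sel_scores):
        tp, fn, tn, fp = _binary_counts(sel_scores, sel_pos, thr, low_is_pos)
        acc = (tp + tn) / sel_scores.size
        sens = tp / (tp + fn)
        key = (acc, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr)
    thr = float(best[1])

    is_pos = stages == pos_stage
    tp, fn, tn, fp = _binary_counts(scores, is_pos, thr, low_is_pos)
    return BinaryMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / scores.size,
        threshold=thr,
        positive_stage=pos_stage,
        low_score_is_positive=bool(low_is_pos),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    )


@dataclass(frozen=True)
class ThreeClassMetrics:
    per_stage: dict            # stage -> {sensitivity, specificity, accuracy}
    overall_accuracy: float
    cutpoints: tuple[float, float]
    stage_order_low_to_high: tuple[str, str, str]
    confusion: dict            # true stage -> {predicted stage -> count}


def _predict_threeclass(scores, cut1, cut2, order):
    pred = np.empty(scores.shape, dtype=object)
    pred[scores <= cut1] = order[0]
    pred[(scores > cut1) & (scores <= cut2)] = order[1]
    pred[scores > cut2] = order[2]
    return pred


def threeclass_threshold_metrics(
    scores, stages, selection_scores=None, selection_stages=None
) -> ThreeClassMetrics:
    """Three-class metrics from two accuracy-maximizing cut-points.

    The score axis is cut into three intervals assigned to the stages in
    order of their group mean scores (for a similarity-to-healthy score:
    AD lowest, NC highest). The cut-point pair is found by exhaustive scan
    over midpoints of the sorted unique selection scores; per-stage
    one-vs-rest sensitivity/specificity/accuracy are reported along with
    the full confusion matrix.
    """
    scores, stages = _as_arrays(scores, stages)
    present = set(np.unique(stages))
    if not {"NC", "MCI", "AD"} <= present:
        raise ValueError(f"need all three stages, found {sorted(present)}")
    if selection_scores is None:
        sel_scores, sel_stages = scores, stages
    else:
        sel_scores, sel_stages = _as_arrays(selection_scores, selection_stages)

    means = {st: sel_scores[sel_stages == st].mean() for st in ("NC", "MCI", "AD")}
    order = tuple(sorted(means, key=means.get))  # low interval -> low-mean stage

    cands = _candidate_thresholds(sel_scores)
    best = None
    for i, c1 in enumerate(cands):
        for c2 in cands[i + 1 :]:
            pred = _predict_threeclass(sel_scores, c1, c2, order)
            acc = float(np.mean(pred == sel_stages))
            if best is None or acc > best[0]:
                best = (acc, c1, c2)
    _, cut1, cut2 = best

    pred = _predict_threeclass(scores, cut1, cut2, order)
    n = scores.size
    confusion = {
        true: {p: int(np.sum((stages == true) & (pred == p)))
               for p in ("NC", "MCI", "AD")}
        for true in ("NC", "MCI", "AD")
    }
    per_stage = {}
    for st in ("NC", "MCI", "AD"):
        tp = confusion[st][st]
        fn = sum(confusion[st][p] for p in ("NC", "MCI", "AD")) - tp
        fp = sum(confusion[t][st] for t in ("NC", "MCI", "AD")) - tp
        tn = n - tp - fn - fp
        per_stage[st] = {
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
            "accuracy": (tp + tn) / n,
        }
    return ThreeClassMetrics(
        per_stage=per_stage,
        overall_accuracy=float(np.mean(pred == stages)),
        cutpoints=(float(cut1), float(cut2)),
        stage_order_low_to_high=order,
        confusion=confusion,
    )


# ---------------------------------------------------------------------------
# dispersion and Pareto
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionResult:
    variance: float
    std: float
    quartile_deviation: float
    variation_ratio: float


def dispersion_table(scores) -> DispersionResult:
    """Dispersion of the min-max-normalized score distribution.

    Variance and standard deviation are the population forms; quartile
    deviation is (Q3 - Q1)/2 with linear-interpolation quantiles; the
    variation ratio is 1 - modal frequency / n after rounding normalized
    values to 2 decimals (continuous scores need a discretization to have
    a mode). Constant input yields zeros throughout.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise UndefinedStatisticError("need at least 2 observations")
    rng_ = np.ptp(scores)
    if rng_ == 0:
        return DispersionResult(0.0, 0.0, 0.0, 0.0)
    norm = (scores - scores.min()) / rng_
    q1, q3 = np.quantile(norm, [0.25, 0.75])  # linear interpolation rule
    rounded = np.round(norm, VARIATION_RATIO_DECIMALS)
    _, counts = np.unique(rounded, return_counts=True)
    return DispersionResult(
        variance=float(np.var(norm)),
        std=float(np.std(norm)),
        quartile_deviation=float((q3 - q1) / 2.0),
        variation_ratio=float(1.0 - counts.max() / norm.size),
    )


@dataclass(frozen=True)
class ParetoResult:
    bin_edges: np.ndarray
    frequencies: np.ndarray
    cumulative_percent: np.ndarray


def pareto_bins(scores, n_bins: int = 10) -> ParetoResult:
    """Equal-width bins over [min, max] with a cumulative-percentage curve.

    Frequencies sum to n; the cumulative curve is nondecreasing and ends
    at exactly 100%.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 1:
        raise UndefinedStatisticError("need at least 1 observation")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    freq, edges = np.histogram(scores, bins=n_bins)
    cum = np.cumsum(freq) / scores.size * 100.0
    cum[-1] = 100.0
    return ParetoResult(bin_edges=edges, frequencies=freq, cumulative_percent=cum)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """All evaluation outputs in one serializable object."""

    n: int
    correlation: CorrelationResult
    ttests: dict
    binary: dict                      # "NC/MCI" etc. -> BinaryMetrics
    threeclass: ThreeClassMetrics
    dispersion: DispersionResult
    pareto: ParetoResult

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "correlation": {
                "pearson": self.correlation.pearson,
                "spearman": self.correlation.spearman,
                "pearson_abs_pct": self.correlation.pearson_abs_pct,
                "spearman_abs_pct": self.correlation.spearman_abs_pct,
            },
            "ttests": self.ttests,
            "binary": {k: asdict(v) for k, v in self.binary.items()},
            "threeclass": {
                "per_stage": self.threeclass.per_stage,
                "overall_accuracy": self.threeclass.overall_accuracy,
                "cutpoints": list(self.threeclass.cutpoints),
                "stage_order_low_to_high": list(
                    self.threeclass.stage_order_low_to_high
                ),
                "confusion": self.threeclass.confusion,
            },
            "dispersion": asdict(self.dispersion),
            "pareto": {
                "bin_edges": [float(x) for x in self.pareto.bin_edges],
                "frequencies": [int(x) for x in self.pareto.frequencies],
                "cumulative_percent": [
                    float(x) for x in self.pareto.cumulative_percent
                ],
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def write_tables(self, out_dir: str | Path) -> None:
        """Flat CSV mirrors of the report sections, for diffability."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        d = self.to_dict()
        pd.DataFrame([d["correlation"]]).to_csv(out_dir / "correlation.csv",
                                                index=False)
        pd.DataFrame(
            [{"pair": k, **v} for k, v in d["ttests"].items()]
        ).to_csv(out_dir / "ttests.csv", index=False)
        pd.DataFrame(
            [{"task": k, **{kk: vv for kk, vv in v.items() if kk != "confusion"},
              **v["confusion"]} for k, v in d["binary"].items()]
        ).to_csv(out_dir / "binary_metrics.csv", index=False)
        pd.DataFrame(
            [{"stage": st, **m} for st, m in d["threeclass"]["per_stage"].items()]
        ).to_csv(out_dir / "threeclass_metrics.csv", index=False)
        pd.DataFrame([d["dispersion"]]).to_csv(out_dir / "dispersion.csv",
                                               index=False)
        pd.DataFrame(
            {
                "bin_left": d["pareto"]["bin_edges"][:-1],
                "bin_right": d["pareto"]["bin_edges"][1:],
                "frequency": d["pareto"]["frequencies"],
                "cumulative_percent": d["pareto"]["cumulative_percent"],
            }
        ).to_csv(out_dir / "pareto.csv", index=False)


def evaluate_scores(
    records: Sequence[ScoreRecord] | None = None,
    scores=None, stages=None,
    equal_var: bool = False, n_bins: int = 10,
) -> EvaluationReport:
    """Run the full battery on score records (or bare scores + stages)."""
    if records is not None:
        scores = [r.score for r in records]
        stages = [r.stage for r in records]
    scores, stages = _as_arrays(scores, stages)
    if any(s is None for s in stages):
        raise ValueError("stage labels are required for evaluation")
    return EvaluationReport(
        n=int(scores.size),
        correlation=correlation_with_stage(scores, stages),
        ttests=pairwise_ttests(scores, stages, equal_var=equal_var),
        binary={
            f"{a}/{b}": binary_threshold_metrics(scores, stages, (a, b))
            for a, b in STAGE_PAIRS
        },
        threeclass=threeclass_threshold_metrics(scores, stages),
        dispersion=dispersion_table(scores),
        pareto=pareto_bins(scores, n_bins=n_bins),
    )
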
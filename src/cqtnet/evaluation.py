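"""K-fold cross-validation and metric reporting.

Splitting supports two units: ``question_set`` (the 9:1 split over all
segments) and ``series`` (all nine question sets of a series share a fold,
preventing within-participant leakage — the default). Folds are stratified
by label with a seeded shuffle, and overall fold sizes differ by at most
one. Per-fold recall / precision / F1 (positive class = deceptive) are
aggregated as mean +/- SD (n-1 denominator), and the held-out question-set
probabilities are pooled into per-series scores for the three-way decision
table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .nn.model import (
    ArchitectureConfig,
    CnnLstmClassifier,
    TrainConfig,
    build_model,
    predict_proba,
    train,
)
from .preprocess import QuestionSetSegment
from .scoring import ScoringConfig, decide_dataset
from .session_io import SeriesManifest

__all__ = [
    "CVReport",
    "kfold_split",
    "classification_metrics",
    "chance_f1",
    "cross_validate",
]

METRICS = ("recall", "precision", "f1")


@dataclass
class CVReport:
    k: int
    unit: str
    seed: int
    per_fold: list[dict]
    mean_sd: dict[str, tuple[float, float]]
    decision_table: dict

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "unit": self.unit,
            "seed": self.seed,
            "per_fold": self.per_fold,
            "mean_sd": {m: list(v) for m, v in self.mean_sd.items()},
            "decision_table": self.decision_table,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1, **kwargs)


def kfold_split(
    items: Sequence, k: int, labels: Sequence[str] | None = None, seed: int = 0
) -> list[list]:
    """Partition ``items`` into ``k`` folds whose sizes differ by <= 1.

    When ``labels`` are given the assignment is stratified: each class is
    shuffled (seeded) and dealt to consecutive folds round-robin, the deal
    position carrying over between classes so overall sizes stay balanced.
    """
    items = list(items)
    if len(items) < k:
        raise ValueError(f"cannot split {len(items)} items into {k} folds")
    rng = np.random.default_rng(seed)
    if labels is None:
        order = list(rng.permutation(len(items)))
    else:
        if len(labels) != len(items):
            raise ValueError("labels must match items")
        order = []
        for cls in sorted(set(labels)):
            idx = [i for i, lab in enumerate(labels) if lab == cls]
            order.extend(np.asarray(idx)[rng.permutation(len(idx))])
    folds: list[list] = [[] for _ in range(k)]
    for pos, i in enumerate(order):
        folds[pos % k].append(items[i])
    return folds


def classification_metrics(
    predicted: Sequence[str], true: Sequence[str], positive: str = "deceptive"
) -> tuple[float, float, float]:
    """(recall, precision, f1) with the deceptive class positive; 0/0 -> 0."""
    if len(predicted) != len(true):
        raise ValueError("predicted and true label lists differ in length")
    y_true = np.array([t == positive for t in true])
    y_pred = np.array([p == positive for p in predicted])
    if not y_true.any() or not y_pred.any():
        warnings.warn("degenerate fold: no positives in truth or prediction")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", zero_division=0
        )
    return float(recall), float(precision), float(f1)


def chance_f1(true_positive_rate: float, predicted_positive_rate: float) -> float:
    """Expected F1 of a classifier whose predictions are independent of the
    truth: with truth-positive rate p and predicted-positive rate q,
    precision -> p, recall -> q, so F1 -> 2pq/(p+q). The no-signal
    reference for F1 (0 when either rate is 0)."""
    p, q = true_positive_rate, predicted_positive_rate
    return 2 * p * q / (p + q) if p + q > 0 else 0.0


def _fold_seed(seed: int, fold: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, fold, stream]).generate_state(1)[0] % 2**31)


def cross_validate(
    segments: list[QuestionSetSegment],
    manifests: list[SeriesManifest],
    arch_config: ArchitectureConfig | None = None,
    train_config: TrainConfig | None = None,
    scoring_config: ScoringConfig | None = None,
    k: int = 10,
    unit: str = "series",
    seed: int = 0,
) -> CVReport:
    """Full k-fold evaluation: train on k-1 folds, score the held-out fold.

    Pools each segment's single held-out probability into per-series scores
    for the decision table. Fully seeded (fold assignment, per-fold weight
    init and training).
    """
    if unit not in ("series", "question_set"):
        raise ValueError("unit must be 'series' or 'question_set'")
    arch_config = arch_config or ArchitectureConfig()
    train_config = train_config or TrainConfig()
    scoring_config = scoring_config or ScoringConfig()

    truth_by_series = {m.series_id: m.ground_truth for m in manifests}
    indices = list(range(len(segments)))
    if unit == "series":
        series_ids = sorted({s.series_id for s in segments})
        folds_series = kfold_split(
            series_ids, k,
            labels=[truth_by_series[s] for s in series_ids], seed=seed,
        )
        fold_indices = [
            [i for i in indices if segments[i].series_id in set(fold)]
            for fold in folds_series
        ]
    else:
        fold_indices = kfold_split(
            indices, k, labels=[segments[i].label for i in indices], seed=seed
        )

    per_fold: list[dict] = []
    probs_by_segment: dict[int, float] = {}
    for fold_id, test_idx in enumerate(fold_indices):
        test_set = set(test_idx)
        train_segs = [segments[i] for i in indices if i not in test_set]
        test_segs = [segments[i] for i in test_idx]
        model = build_model(arch_config, seed=_fold_seed(seed, fold_id, 0))
        cfg = TrainConfig(**{**train_config.__dict__,
                             "seed": _fold_seed(seed, fold_id, 1)})
        try:
            fitted = train(model, train_segs, cfg)
        except Exception as err:
            raise RuntimeError(f"training failed in fold {fold_id}") from err
        probs = predict_proba(fitted, test_segs)
        for i, p in zip(test_idx, probs):
            probs_by_segment[i] = float(p)
        predicted = ["deceptive" if p > 0.5 else "truthful" for p in probs]
        true = [s.label for s in test_segs]
        recall, precision, f1 = classification_metrics(predicted, true)
        per_fold.append(
            {"fold": fold_id, "n_test": len(test_segs), "recall": recall,
             "precision": precision, "f1": f1,
             "n_true_deceptive": int(sum(t == "deceptive" for t in true)),
             "n_pred_deceptive": int(sum(p == "deceptive" for p in predicted))}
        )

    assert sorted(probs_by_segment) == indices, "folds must partition the data"
    mean_sd = {
        m: (
            float(np.mean([f[m] for f in per_fold])),
            float(np.std([f[m] for f in per_fold], ddof=1)),
        )
        for m in METRICS
    }

    series_probs: dict[str, list[float]] = {}
    for i in indices:
        series_probs.setdefault(segments[i].series_id, []).append(probs_by_segment[i])
    table = decide_dataset(series_probs, manifests, scoring_config)
    decision_table = {
        "counts": table["counts"],
        "series": [
            {"series_id": s.series_id, "score": s.score, "decision": s.decision}
            for s in table["series"]
        ],
    }
    return CVReport(
        k=k, unit=unit, seed=seed, per_fold=per_fold,
        mean_sd=mean_sd, decision_table=decision_table,
    )
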
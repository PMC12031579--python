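"""Series scoring with the Utah-mapped inconclusive band.

A series contributes nine question-set deception probabilities (3 charts x
3 pairs). Their sum is the series score in [0, 9]. The decision thresholds
come from mapping the Utah numerical-scoring cut-offs (+/-6 on the
-18..+18 total-score scale) affinely onto the score range:

    threshold = (cutoff - utah_min) / (utah_max - utah_min)
                * (score_max - score_min) + score_min

which gives threshold 1 = 6 (deception cut) and threshold 2 = 3 (truth
cut) with the defaults. Scores strictly above threshold 1 mean deception,
strictly below threshold 2 mean non-deception, anything in between —
boundaries included — is inconclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .session_io import SeriesManifest

__all__ = [
    "ScoringConfig",
    "SeriesScore",
    "compute_thresholds",
    "score_series",
    "decide_dataset",
]

#: manifest ground truth -> matching decision
_TRUTH_TO_DECISION = {"deceptive": "deception", "truthful": "non_deception"}


@dataclass(frozen=True)
class ScoringConfig:
    utah_cutoff_deception: float = 6.0
    utah_cutoff_truth: float = -6.0
    utah_min: float = -18.0
    utah_max: float = 18.0
    score_min: float = 0.0
    score_max: float = 9.0
    n_question_sets: int = 9

    def __post_init__(self) -> None:
        if self.utah_min >= self.utah_max:
            raise ValueError("degenerate Utah range")
        if self.score_min >= self.score_max:
            raise ValueError("degenerate score range")
        for cutoff in (self.utah_cutoff_deception, self.utah_cutoff_truth):
            if not self.utah_min <= cutoff <= self.utah_max:
                raise ValueError(f"cutoff {cutoff} outside the Utah range")


@dataclass(frozen=True)
class SeriesScore:
    series_id: str
    probabilities: tuple[float, ...]
    score: float
    threshold_1: float
    threshold_2: float
    decision: str


def compute_thresholds(config: ScoringConfig | None = None) -> tuple[float, float]:
    """Map the Utah cut-offs onto the series-score range (affine).

    Returns ``(threshold_1, threshold_2)``; with the default configuration
    these are exactly (6.0, 3.0).
    """
    cfg = config or ScoringConfig()

    def _map(cutoff: float) -> float:
        frac = (cutoff - cfg.utah_min) / (cfg.utah_max - cfg.utah_min)
        return frac * (cfg.score_max - cfg.score_min) + cfg.score_min

    t1, t2 = _map(cfg.utah_cutoff_deception), _map(cfg.utah_cutoff_truth)
    if t1 < t2:
        raise ValueError("deception threshold below truth threshold")
    return t1, t2


def score_series(
    probabilities: Sequence[float],
    config: ScoringConfig | None = None,
    series_id: str = "",
) -> SeriesScore:
    """Sum the nine question-set probabilities and issue the 3-way decision."""
    cfg = config or ScoringConfig()
    probs = [float(p) for p in probabilities]
    if len(probs) != cfg.n_question_sets:
        raise ValueError(
            f"expected {cfg.n_question_sets} probabilities, got {len(probs)}"
        )
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    score = float(sum(probs))
    t1, t2 = compute_thresholds(cfg)
    if score > t1:
        decision = "deception"
    elif score < t2:
        decision = "non_deception"
    else:
        decision = "inconclusive"
    return SeriesScore(
        series_id=series_id,
        probabilities=tuple(probs),
        score=score,
        threshold_1=t1,
        threshold_2=t2,
        decision=decision,
    )


def decide_dataset(
    series_probabilities: Mapping[str, Sequence[float]],
    manifests: Iterable[SeriesManifest],
    config: ScoringConfig | None = None,
) -> dict:
    """Score every series and tabulate correct/incorrect/inconclusive counts
    per ground-truth group (the reporting shape of a confusion table with an
    explicit inconclusive column).

    Series with unknown ground truth are scored and listed but excluded from
    the counts, with a warning.
    """
    cfg = config or ScoringConfig()
    counts = {
        "deceptive": {"correct": 0, "incorrect": 0, "inconclusive": 0},
        "truthful": {"correct": 0, "incorrect": 0, "inconclusive": 0},
    }
    scores: list[SeriesScore] = []
    for manifest in manifests:
        if manifest.series_id not in series_probabilities:
            raise KeyError(f"no probabilities for series {manifest.series_id}")
        result = score_series(
            series_probabilities[manifest.series_id], cfg, series_id=manifest.series_id
        )
        scores.append(result)
        truth = manifest.ground_truth
        if truth not in _TRUTH_TO_DECISION:
            warnings.warn(
                f"series {manifest.series_id} has no ground truth; excluded from counts"
            )
            continue
        if result.decision == "inconclusive":
            counts[truth]["inconclusive"] += 1
        elif result.decision == _TRUTH_TO_DECISION[truth]:
            counts[truth]["correct"] += 1
        else:
            counts[truth]["incorrect"] += 1
    return {"counts": counts, "series": scores}
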
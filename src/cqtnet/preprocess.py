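"""Turn annotated charts into fixed-length 5-channel classifier inputs.

For each (comparison, relevant) question pair, a 22.4 s window (896 samples
at 40 Hz) is cut at each question onset, the two windows are concatenated
with the *offset-join* — the second window is shifted by a constant so its
first sample equals the last sample of the first window, removing the
boundary discontinuity — and each channel is z-scored per segment. The
result is a 5 x 1792 array, one question set, the atomic classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .session_io import (
    CHANNELS,
    QUESTION_WINDOW_S,
    WINDOW_SAMPLES,
    SeriesManifest,
    SessionRecording,
    onset_index,
)

__all__ = [
    "SEGMENT_SAMPLES",
    "QuestionSetSegment",
    "extract_window",
    "offset_join",
    "standardize",
    "build_question_set",
    "build_dataset",
    "save_segments",
    "load_segments",
]

#: Samples per joined (comparison, relevant) segment: 2 x 896.
SEGMENT_SAMPLES = 2 * WINDOW_SAMPLES

LABELS = ("truthful", "deceptive")  # index 1 == deceptive throughout


@dataclass
class QuestionSetSegment:
    """One preprocessed question set: ``x`` is 5 x 1792, canonical channel order."""

    series_id: str
    chart_id: str
    pair_id: int
    x: np.ndarray
    label: str = "unknown"

    def validate(self) -> "QuestionSetSegment":
        if self.x.shape != (len(CHANNELS), SEGMENT_SAMPLES):
            raise ValueError(
                f"segment shape {self.x.shape} != {(len(CHANNELS), SEGMENT_SAMPLES)}"
            )
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite value in segment")
        return self


def extract_window(trace: np.ndarray, onset_s: float, window_s: float = QUESTION_WINDOW_S) -> np.ndarray:
    """Slice ``floor(window_s*40)`` samples starting at ``floor(onset_s*40)``."""
    trace = np.asarray(trace)
    start = onset_index(onset_s)
    n = int(window_s * 40)
    if start < 0 or start + n > len(trace):
        raise IndexError(
            f"window [{start}, {start + n}) exceeds trace of {len(trace)} samples"
        )
    return trace[start : start + n]


def offset_join(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Concatenate two segments, shifting the second so the join is continuous.

    ``out = first ++ (second + delta)`` with ``delta = first[-1] - second[0]``,
    hence ``out[len(first)] == out[len(first)-1]`` exactly.
    """
    first = np.asarray(first, dtype=np.float64)
    second = np.asarray(second, dtype=np.float64)
    if first.size == 0 or second.size == 0:
        raise ValueError("offset_join requires non-empty segments")
    # evaluated as (second - second[0]) + first[-1] so the junction sample
    # equals first[-1] exactly in floating point
    return np.concatenate([first, (second - second[0]) + first[-1]])


def standardize(x: np.ndarray) -> np.ndarray:
    """Per-row z-score; constant rows map to all zeros."""
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mean, sd, out=out, where=sd > 0)
    return out


def build_question_set(
    recording: SessionRecording,
    pair_id: int,
    label: str = "unknown",
    series_id: str | None = None,
) -> QuestionSetSegment:
    """Build the 5 x 1792 input for one question pair of a chart.

    Comparison window first, relevant second; offset-join then per-channel
    z-scoring.
    """
    pairs = recording.pairs()
    if pair_id not in pairs or set(pairs[pair_id]) != {"comparison", "relevant"}:
        raise KeyError(f"pair {pair_id} not found in chart {recording.chart_id}")
    comp, rel = pairs[pair_id]["comparison"], pairs[pair_id]["relevant"]
    rows = []
    for name in CHANNELS:
        trace = recording.channels[name]
        joined = offset_join(
            extract_window(trace, comp.onset_s), extract_window(trace, rel.onset_s)
        )
        rows.append(joined)
    x = standardize(np.stack(rows))
    return QuestionSetSegment(
        series_id=series_id or recording.series_id or "",
        chart_id=recording.chart_id,
        pair_id=pair_id,
        x=x,
        label=label,
    ).validate()


def build_dataset(
    recordings: list[SessionRecording], manifests: list[SeriesManifest]
) -> list[QuestionSetSegment]:
    """Preprocess every question set of every chart listed in the manifests.

    Question-set labels inherit the series ground truth.
    """
    by_id = {rec.chart_id: rec for rec in recordings}
    segments: list[QuestionSetSegment] = []
    for manifest in manifests:
        for chart_id in manifest.charts:
            if chart_id not in by_id:
                raise KeyError(f"chart {chart_id} of series {manifest.series_id} missing")
            rec = by_id[chart_id]
            for pair_id in sorted(rec.pairs()):
                segments.append(
                    build_question_set(
                        rec, pair_id, label=manifest.ground_truth,
                        series_id=manifest.series_id,
                    )
                )
    return segments


def save_segments(segments: list[QuestionSetSegment], path: str | Path) -> Path:
    """Write segments + labels + identifiers to one ``.npz`` container."""
    path = Path(path)
    np.savez_compressed(
        path,
        x=np.stack([s.x for s in segments]).astype(np.float32),
        label=np.array([s.label for s in segments]),
        series_id=np.array([s.series_id for s in segments]),
        chart_id=np.array([s.chart_id for s in segments]),
        pair_id=np.array([s.pair_id for s in segments]),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_segments(path: str | Path) -> list[QuestionSetSegment]:
    with np.load(path, allow_pickle=False) as data:
        return [
            QuestionSetSegment(
                series_id=str(data["series_id"][i]),
                chart_id=str(data["chart_id"][i]),
                pair_id=int(data["pair_id"][i]),
                x=data["x"][i].astype(np.float64),
                label=str(data["label"][i]),
            ).validate()
            for i in range(len(data["x"]))
        ]
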
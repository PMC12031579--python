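"""Session recordings, annotations, and on-disk formats.

A *chart* is one continuous recording pass of the five polygraph channels
(photoplethysmogram, blood pressure, thoracic and abdominal respiration,
skin conductance) sampled at 40 Hz, annotated with question-onset events.
Three charts form a *series*, the unit that ultimately receives a
deception / non-deception / inconclusive decision.

On disk a chart is a pair of human-inspectable text files:

``<chart_id>.csv``
    one row per sample; column 1 is the sample index, columns 2-6 the five
    channels in canonical order.
``<chart_id>.json``
    sidecar with the sampling rate, the question events, and optional
    series / participant linkage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLING_RATE_HZ",
    "CHANNELS",
    "QUESTION_WINDOW_S",
    "WINDOW_SAMPLES",
    "QuestionEvent",
    "SessionRecording",
    "SeriesManifest",
    "SessionFormatError",
    "read_session",
    "write_session",
    "read_manifests",
    "write_manifests",
]

#: Fixed acquisition rate of the polygraph device (Hz). Other rates are
#: rejected; resampling is out of scope.
SAMPLING_RATE_HZ = 40

#: Canonical channel order used everywhere: files, tensors, model branches.
CHANNELS = (
    "ppg",
    "blood_pressure",
    "resp_thoracic",
    "resp_abdominal",
    "skin_conductance",
)

#: Length of the per-question scoring window in seconds. 22.4 s at 40 Hz is
#: 896 samples, so a joined (comparison, relevant) pair is 1792 samples —
#: the input length for which the convolutional stack emits exactly 89 time
#: steps.
QUESTION_WINDOW_S = 22.4

#: ``floor(QUESTION_WINDOW_S * SAMPLING_RATE_HZ)`` samples per question window.
WINDOW_SAMPLES = int(QUESTION_WINDOW_S * SAMPLING_RATE_HZ)

EVENT_KINDS = ("comparison", "relevant", "irrelevant")
GROUND_TRUTHS = ("deceptive", "truthful", "unknown")


class SessionFormatError(ValueError):
    """A session file or in-memory recording violates the format contract."""


def onset_index(onset_s: float, rate_hz: float = SAMPLING_RATE_HZ) -> int:
    """0-based sample index of a question onset: ``floor(onset_s * rate)``."""
    return int(math.floor(onset_s * rate_hz))


@dataclass(frozen=True)
class QuestionEvent:
    """One question onset.

    ``pair_id`` (1..3) links a comparison question to its relevant question
    within a chart; irrelevant questions carry ``pair_id=None`` and are
    ignored by scoring.
    """

    onset_s: float
    kind: str
    pair_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise SessionFormatError(f"unknown event kind {self.kind!r}")
        if self.kind in ("comparison", "relevant"):
            if self.pair_id is None or not 1 <= int(self.pair_id) <= 3:
                raise SessionFormatError(
                    f"{self.kind} event requires pair_id in 1..3, got {self.pair_id!r}"
                )
        if not math.isfinite(self.onset_s) or self.onset_s < 0:
            raise SessionFormatError(f"invalid onset_s {self.onset_s!r}")


@dataclass
class SessionRecording:
    """Five synchronized 40 Hz channel traces plus events for one chart."""

    chart_id: str
    channels: dict[str, np.ndarray]
    events: list[QuestionEvent] = field(default_factory=list)
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    series_id: str | None = None
    participant_id: str | None = None

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def pairs(self) -> dict[int, dict[str, QuestionEvent]]:
        """Map pair_id -> {'comparison': event, 'relevant': event}."""
        out: dict[int, dict[str, QuestionEvent]] = {}
        for ev in self.events:
            if ev.kind in ("comparison", "relevant"):
                out.setdefault(int(ev.pair_id), {})[ev.kind] = ev
        return out

    def validate(self, require_pairs: bool = False) -> "SessionRecording":
        """Check all invariants; raise :class:`SessionFormatError` on violation."""
        if self.sampling_rate_hz != SAMPLING_RATE_HZ:
            raise SessionFormatError(
                f"sampling_rate_hz must be {SAMPLING_RATE_HZ}, got {self.sampling_rate_hz}"
            )
        for name in CHANNELS:
            if name not in self.channels:
                raise SessionFormatError(f"channel {name} absent")
        lengths = {name: len(self.channels[name]) for name in CHANNELS}
        if len(set(lengths.values())) != 1:
            raise SessionFormatError(f"channel length mismatch: {lengths}")
        n = self.n_samples
        for name in CHANNELS:
            if not np.all(np.isfinite(self.channels[name])):
                raise SessionFormatError(f"non-finite sample in channel {name}")
        last = -math.inf
        for ev in self.events:
            if ev.onset_s <= last:
                raise SessionFormatError(
                    f"events not strictly increasing at onset {ev.onset_s}"
                )
            last = ev.onset_s
            if onset_index(ev.onset_s, self.sampling_rate_hz) + WINDOW_SAMPLES > n:
                raise SessionFormatError(
                    f"event at {ev.onset_s}s plus {QUESTION_WINDOW_S}s window "
                    f"exceeds trace of {n} samples"
                )
        if require_pairs:
            pairs = self.pairs()
            if sorted(pairs) != [1, 2, 3] or any(
                set(p) != {"comparison", "relevant"} for p in pairs.values()
            ):
                raise SessionFormatError(
                    f"chart {self.chart_id}: expected 3 complete "
                    f"(comparison, relevant) pairs, found {sorted(pairs)}"
                )
        return self


@dataclass(frozen=True)
class SeriesManifest:
    """One examination series: exactly three charts and a ground truth."""

    series_id: str
    participant_id: str
    charts: tuple[str, str, str]
    ground_truth: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.charts) != 3:
            raise SessionFormatError(
                f"series {self.series_id}: expected exactly 3 charts, got {len(self.charts)}"
            )
        if self.ground_truth not in GROUND_TRUTHS:
            raise SessionFormatError(f"unknown ground_truth {self.ground_truth!r}")


# ---------------------------------------------------------------------------
# file I/O


def write_session(recording: SessionRecording, path: str | Path) -> Path:
    """Write one chart as ``<path>.csv`` + ``<path>.json``.

    ``path`` may be the CSV path or a stem; returns the CSV path. Samples
    are written with 17 significant digits so the read/write round trip is
    bit-exact for finite float64 values.
    """
    recording.validate()
    path = Path(path)
    if path.suffix == ".csv":
        stem = path.with_suffix("")
    else:
        stem = path
    csv_path = stem.with_suffix(".csv")
    df = pd.DataFrame(
        {name: np.asarray(recording.channels[name], dtype=np.float64) for name in CHANNELS}
    )
    df.insert(0, "sample", np.arange(len(df)))
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "chart_id": recording.chart_id,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "series_id": recording.series_id,
        "participant_id": recording.participant_id,
        "events": [
            {"onset_s": ev.onset_s, "kind": ev.kind, "pair_id": ev.pair_id}
            for ev in recording.events
        ],
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path


def read_session(path: str | Path) -> SessionRecording:
    """Read a chart written by :func:`write_session`."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in (".csv", ".json") else path
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    if not csv_path.exists():
        raise SessionFormatError(f"missing data file {csv_path}")
    if not json_path.exists():
        raise SessionFormatError(f"missing sidecar file {json_path}")
    sidecar = json.loads(json_path.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    channels = {}
    for name in CHANNELS:
        if name not in df.columns:
            raise SessionFormatError(f"channel {name} absent")
        channels[name] = df[name].to_numpy(dtype=np.float64)
    events = [
        QuestionEvent(
            onset_s=float(ev["onset_s"]),
            kind=str(ev["kind"]),
            pair_id=None if ev.get("pair_id") is None else int(ev["pair_id"]),
        )
        for ev in sidecar.get("events", [])
    ]
    rec = SessionRecording(
        chart_id=str(sidecar["chart_id"]),
        channels=channels,
        events=events,
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        series_id=sidecar.get("series_id"),
        participant_id=sidecar.get("participant_id"),
    )
    return rec.validate()


def write_manifests(manifests: Iterable[SeriesManifest], path: str | Path) -> Path:
    """Write the series manifest table as CSV."""
    path = Path(path)
    rows = [
        {
            "series_id": m.series_id,
            "participant_id": m.participant_id,
            "chart_1": m.charts[0],
            "chart_2": m.charts[1],
            "chart_3": m.charts[2],
            "ground_truth": m.ground_truth,
        }
        for m in manifests
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifests(path: str | Path) -> list[SeriesManifest]:
    df = pd.read_csv(path)
    return [
        SeriesManifest(
            series_id=str(r.series_id),
            participant_id=str(r.participant_id),
            charts=(str(r.chart_1), str(r.chart_2), str(r.chart_3)),
            ground_truth=str(r.ground_truth),
        )
        for r in df.itertuples()
    ]
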
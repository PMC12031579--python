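"""Synthetic comparison-question-test (CQT) polygraph sessions.

Emulates the structure of a real examination — one series = three charts,
each chart carrying three (comparison, relevant) question pairs — together
with a sympathetic-arousal response whose amplitude encodes the CQT
premise: under deception the response to a relevant question is larger
than to its comparison question; under truthfulness it is smaller or equal.

Waveform models (standard phenomenology, per channel):

* skin conductance — tonic level plus event-locked bi-exponential phasic
  transients whose amplitude grows with arousal;
* photoplethysmogram — pulse train at the heart rate whose envelope drops
  by an arousal-proportional fraction after a question (vasoconstriction);
* blood pressure — baseline plus a slow arousal-proportional rise;
* thoracic / abdominal respiration — sinusoids at the breathing rate
  (abdomen phase-lagged) whose amplitude is suppressed with arousal.

Every response starts ``response_latency_s`` after question onset; white
noise and a random-walk drift are added to all channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .session_io import (
    CHANNELS,
    QUESTION_WINDOW_S,
    SAMPLING_RATE_HZ,
    QuestionEvent,
    SeriesManifest,
    SessionRecording,
    onset_index,
)

__all__ = ["SimParams", "response_kernel", "simulate_chart", "simulate_dataset", "scr_contrast"]

#: Per-channel (baseline, carrier amplitude, response gain, noise scale).
#: Units are the device's arbitrary units; the preprocessing z-scores every
#: segment so only shapes and relative amplitudes matter. ``noise scale``
#: makes ``noise_sd`` roughly "noise sd per unit response amplitude".
_CHANNEL_SCALES = {
    "ppg": (0.0, 1.0, 0.25, 1.0),
    "blood_pressure": (90.0, 0.0, 4.0, 4.0),
    "resp_thoracic": (0.0, 1.0, 0.20, 1.0),
    "resp_abdominal": (0.0, 0.8, 0.20, 0.8),
    "skin_conductance": (8.0, 0.0, 0.6, 0.6),
}

#: Phase lag of abdominal relative to thoracic respiration (radians).
_ABDOMINAL_LAG_RAD = 0.3


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults define the study conditions.

    ``effect_size`` multiplies the relevant-question response under the
    deceptive condition: expected relevant amplitude is
    ``(1 + effect_size)`` times the comparison amplitude. Under the
    truthful condition the ratio is ``truthful_ratio`` (≤ 1).
    """

    effect_size: float = 1.0
    noise_sd: float = 0.3
    drift_sd: float = 0.1
    heart_rate_hz: float = 1.2
    resp_rate_hz: float = 0.25
    scr_rise_s: float = 0.75
    scr_decay_s: float = 4.0
    response_latency_s: float = 1.5
    chart_duration_s: float = 240.0
    inter_question_gap_s: float = 25.0
    first_onset_s: float = 10.0
    truthful_ratio: float = 0.8
    amplitude_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "heart_rate_hz",
            "resp_rate_hz",
            "scr_rise_s",
            "scr_decay_s",
            "response_latency_s",
            "chart_duration_s",
            "inter_question_gap_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0 or self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("effect_size, noise_sd and drift_sd must be nonnegative")
        if not 0 < self.truthful_ratio <= 1:
            raise ValueError("truthful_ratio must be in (0, 1]")
        last_onset = self.event_onsets()[-1][0]
        if last_onset + QUESTION_WINDOW_S + self.response_latency_s > self.chart_duration_s:
            raise ValueError(
                "chart_duration_s too short for 3 question pairs plus windows"
            )

    def event_onsets(self) -> list[tuple[float, str, int | None]]:
        """Fixed chart schedule: one irrelevant opener, then C1 R1 C2 R2 C3 R3."""
        t = self.first_onset_s
        sched: list[tuple[float, str, int | None]] = [(t, "irrelevant", None)]
        for pair in (1, 2, 3):
            t += self.inter_question_gap_s
            sched.append((t, "comparison", pair))
            t += self.inter_question_gap_s
            sched.append((t, "relevant", pair))
        return sched


def response_kernel(
    t: np.ndarray, rise_s: float, decay_s: float
) -> np.ndarray:
    """Unit-peak bi-exponential phasic response, r(t ≤ 0) = 0.

    r(t) = (exp(-t/decay) - exp(-t/rise)) / peak, peaking at
    t* = ln(decay/rise) * rise*decay / (decay - rise).
    """
    if rise_s <= 0 or decay_s <= 0:
        raise ValueError("kernel time constants must be positive")
    if rise_s >= decay_s:
        raise ValueError("rise_s must be smaller than decay_s")
    t = np.asarray(t, dtype=np.float64)
    t_peak = math.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    r = np.where(t > 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    return r / peak


def _event_amplitudes(
    condition: str, params: SimParams, rng: np.random.Generator
) -> list[float]:
    """Arousal amplitude per scheduled event (lognormal trial jitter)."""
    amps = []
    for _, kind, _ in params.event_onsets():
        if kind == "irrelevant":
            base = 0.3
        elif kind == "comparison":
            base = 1.0
        elif condition == "deceptive":
            base = 1.0 + params.effect_size
        else:
            base = params.truthful_ratio
        jitter = math.exp(rng.normal(0.0, params.amplitude_jitter)) if params.amplitude_jitter else 1.0
        amps.append(base * jitter)
    return amps


def simulate_chart(
    condition: str, params: SimParams, seed: int, chart_id: str = "chart"
) -> SessionRecording:
    """Generate one annotated chart under the given condition.

    Deterministic: identical ``(condition, params, seed)`` give bit-identical
    recordings.
    """
    if condition not in ("deceptive", "truthful"):
        raise ValueError(f"condition must be deceptive|truthful, got {condition!r}")
    rng = np.random.default_rng(seed)
    fs = SAMPLING_RATE_HZ
    n = int(round(params.chart_duration_s * fs))
    t = np.arange(n) / fs

    schedule = params.event_onsets()
    amps = _event_amplitudes(condition, params, rng)

    # Shared arousal time courses. The fast course drives skin conductance;
    # the slow course drives the cardiovascular / respiratory modulations.
    fast = np.zeros(n)
    slow = np.zeros(n)
    for (onset, _, _), a in zip(schedule, amps):
        tau = t - onset - params.response_latency_s
        fast += a * response_kernel(tau, params.scr_rise_s, params.scr_decay_s)
        slow += a * response_kernel(tau, 2.0, 12.0)

    channels: dict[str, np.ndarray] = {}
    # carrier phases are randomized per chart (drawn in fixed order)
    phase_ppg = rng.uniform(0, 2 * math.pi)
    phase_resp = rng.uniform(0, 2 * math.pi)
    for name in CHANNELS:
        baseline, carrier_amp, gain, noise_scale = _CHANNEL_SCALES[name]
        if name == "skin_conductance":
            signal = baseline + gain * fast
        elif name == "ppg":
            pulse = np.sin(2 * math.pi * params.heart_rate_hz * t + phase_ppg)
            pulse += 0.3 * np.sin(4 * math.pi * params.heart_rate_hz * t + 2 * phase_ppg)
            envelope = np.clip(1.0 - gain * slow, 0.05, None)
            signal = carrier_amp * envelope * pulse
        elif name == "blood_pressure":
            signal = baseline + gain * slow
        else:  # respiration channels
            lag = _ABDOMINAL_LAG_RAD if name == "resp_abdominal" else 0.0
            breath = np.sin(2 * math.pi * params.resp_rate_hz * t + phase_resp - lag)
            envelope = np.clip(1.0 - gain * slow, 0.05, None)
            signal = carrier_amp * envelope * breath
        if params.noise_sd:
            signal = signal + rng.normal(0.0, params.noise_sd * noise_scale, n)
        if params.drift_sd:
            steps = rng.normal(0.0, params.drift_sd * noise_scale / math.sqrt(fs), n)
            signal = signal + np.cumsum(steps)
        channels[name] = signal

    events = [
        QuestionEvent(onset_s=onset, kind=kind, pair_id=pair)
        for onset, kind, pair in schedule
    ]
    return SessionRecording(
        chart_id=chart_id, channels=channels, events=events
    ).validate(require_pairs=True)


def _chart_seed(master_seed: int, series_idx: int, chart_idx: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), series_idx, chart_idx])
    return int(ss.generate_state(1)[0])


def simulate_dataset(
    n_deceptive_series: int,
    n_truthful_series: int,
    params: SimParams,
    seed: int,
) -> tuple[list[SessionRecording], list[SeriesManifest]]:
    """Generate a full dataset of annotated series.

    Every question set in a deceptive series is deception-labelled and every
    set in a truthful series truth-labelled, so ``(42, 36)`` reproduces the
    reference data arithmetic: 78 series, 234 charts, 702 question sets of
    which 378 deceptive and 324 truthful.
    """
    if n_deceptive_series < 0 or n_truthful_series < 0:
        raise ValueError("series counts must be nonnegative")
    recordings: list[SessionRecording] = []
    manifests: list[SeriesManifest] = []
    conditions = ["deceptive"] * n_deceptive_series + ["truthful"] * n_truthful_series
    for s_idx, condition in enumerate(conditions):
        series_id = f"S{s_idx + 1:03d}"
        participant_id = f"P{s_idx + 1:03d}"
        chart_ids = []
        for c_idx in range(3):
            chart_id = f"{series_id}C{c_idx + 1}"
            rec = simulate_chart(
                condition, params, _chart_seed(seed, s_idx, c_idx), chart_id=chart_id
            )
            rec.series_id = series_id
            rec.participant_id = participant_id
            recordings.append(rec)
            chart_ids.append(chart_id)
        manifests.append(
            SeriesManifest(
                series_id=series_id,
                participant_id=participant_id,
                charts=tuple(chart_ids),
                ground_truth=condition,
            )
        )
    return recordings, manifests


def scr_contrast(recording: SessionRecording, window_s: float = QUESTION_WINDOW_S) -> float:
    """Oracle statistic: mean skin-conductance elevation in relevant windows
    minus comparison windows, baseline-corrected at each question onset.

    Model-free check of the CQT premise in simulated data: expected to be
    positive for deceptive charts, nonpositive for truthful ones, and zero
    at ``effect_size == 0``.
    """
    sc = recording.channels["skin_conductance"]
    n_win = int(window_s * recording.sampling_rate_hz)
    means = {"comparison": [], "relevant": []}
    for ev in recording.events:
        if ev.kind not in means:
            continue
        i = onset_index(ev.onset_s, recording.sampling_rate_hz)
        seg = sc[i : i + n_win]
        means[ev.kind].append(float(np.mean(seg) - sc[i]))
    return float(np.mean(means["relevant"]) - np.mean(means["comparison"]))
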
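"""Postsynaptic-current detection and passive-property estimation.

The detector is an automated, parameterized stand-in for rig-side custom
detection plus manual curation: boxcar smoothing (default 9 points), a
robust noise scale from the median absolute deviation (MAD) of the smoothed
first difference, threshold crossing on that derivative, peak localization
at the subsequent extremum, and a median pre-event baseline.  Two
plausibility filters replace manual confirmation: the amplitude must exceed
the noise-scaled threshold, and the trace must decay back toward baseline
after the peak (unless another event intervenes).

Passive properties come from averaged membrane-test steps (5 mV, 20 ms in
the emulated protocol): series resistance from the peak capacitive
transient, input resistance from the steady-state deflection, capacitance
from the transient charge divided by the step voltage, and holding current
from the pre-step baseline.  Hyperpolarizing steps give negative
deflections; magnitudes are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "DetectionConfig",
    "DetectedEvent",
    "PassiveProperties",
    "detect_events",
    "compute_passive_properties",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
]

MAD_TO_SD = 1.4826  # normal-consistency factor


class InvalidInputError(ValueError):
    pass


class EstimationError(RuntimeError):
    """The membrane-test step could not be resolved above the noise."""


@dataclass(frozen=True)
class Trace:
    """A sampled current record from one voltage-clamped cell."""

    samples_pa: np.ndarray
    sample_rate_hz: float
    holding_mv: float = -65.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples_pa, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("trace needs at least one sample")
        if self.sample_rate_hz <= 0:
            raise InvalidInputError("sample_rate_hz must be > 0")
        object.__setattr__(self, "samples_pa", arr)

    @property
    def duration_s(self) -> float:
        return self.samples_pa.size / self.sample_rate_hz


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the event detector.

    ``smooth_window_points`` is the boxcar width (odd); ``threshold_mads``
    scales both the derivative-crossing threshold and the amplitude
    plausibility filter; ``baseline_window_ms`` is the pre-event window
    whose median is the event baseline; peaks closer than
    ``min_peak_separation_ms`` are merged (larger peak wins).  ``polarity``
    is +1 for upward events (the synthetic convention) or -1 for downward.
    """

    smooth_window_points: int = 9
    threshold_mads: float = 4.0
    baseline_window_ms: float = 10.0
    min_peak_separation_ms: float = 5.0
    polarity: int = 1
    peak_window_ms: float = 10.0
    decay_check_ms: float = 100.0
    decay_fraction: float = 0.5

    def validate(self) -> None:
        if self.smooth_window_points < 1 or self.smooth_window_points % 2 == 0:
            raise InvalidInputError("smooth_window_points must be odd and >= 1")
        if self.threshold_mads <= 0:
            raise InvalidInputError("threshold_mads must be > 0")
        if self.baseline_window_ms <= 0 or self.min_peak_separation_ms <= 0:
            raise InvalidInputError("window parameters must be > 0")
        if self.polarity not in (-1, 1):
            raise InvalidInputError("polarity must be +1 or -1")


@dataclass(frozen=True)
class DetectedEvent:
    """One detected PSC: peak time/value, local baseline, amplitude.

    ``amplitude_pa`` is the absolute difference between peak and baseline.
    """

    peak_time_s: float
    baseline_pa: float
    peak_pa: float
    amplitude_pa: float


@dataclass(frozen=True)
class PassiveProperties:
    capacitance_pf: float
    input_resistance_gohm: float
    series_resistance_mohm: float
    holding_current_pa: float


def _boxcar(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    c = np.cumsum(np.insert(xp, 0, 0.0))
    return (c[w:] - c[:-w]) / w


def _mad_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return MAD_TO_SD * float(np.median(np.abs(x - med)))


def detect_events(trace: Trace, config: DetectionConfig | None = None) -> list[DetectedEvent]:
    """Detect PSC events, ordered by peak time.

    Guarantees: no two peaks closer than ``min_peak_separation_ms``; every
    event carries its pre-event median baseline and the absolute
    peak-baseline amplitude.
    """
    config = config or DetectionConfig()
    config.validate()
    x = trace.samples_pa
    if x.size <= config.smooth_window_points:
        raise InvalidInputError("trace shorter than smoothing window")

    fs = trace.sample_rate_hz
    y = config.polarity * _boxcar(x, config.smooth_window_points)
    d = np.diff(y)
    sigma_d = _mad_sd(d)
    # noise SD of the (unsmoothed) trace, from first differences
    sigma_x = _mad_sd(np.diff(config.polarity * x)) / np.sqrt(2.0)
    if sigma_d == 0.0:
        # Noiseless trace: fall back to any strictly positive derivative of
        # meaningful size relative to the dynamic range.
        scale = np.ptp(y)
        if scale == 0.0:
            return []
        thr = 1e-6 * scale
    else:
        thr = config.threshold_mads * sigma_d

    above = d > thr
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if onsets.size == 0:
        return []

    peak_w = max(1, int(round(config.peak_window_ms / 1000.0 * fs)))
    bl_w = max(1, int(round(config.baseline_window_ms / 1000.0 * fs)))
    min_sep = max(1, int(round(config.min_peak_separation_ms / 1000.0 * fs)))

    # localize peaks
    peaks: list[int] = []
    for i0 in onsets:
        seg_end = min(i0 + peak_w + 1, y.size)
        p = i0 + int(np.argmax(y[i0:seg_end]))
        peaks.append(p)

    # merge peaks closer than the minimum separation, keeping the taller one
    peaks = sorted(set(peaks))
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < min_sep:
            if y[p] > y[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)

    amp_floor = config.threshold_mads * sigma_x
    decay_w = max(1, int(round(config.decay_check_ms / 1000.0 * fs)))
    events: list[DetectedEvent] = []
    for idx, p in enumerate(merged):
        lo = max(0, p - bl_w)
        baseline_y = float(np.median(y[lo:p])) if p > lo else float(y[p])
        amp = float(y[p] - baseline_y)
        if amp < max(amp_floor, 0.0) or amp <= 0:
            continue
        # decay plausibility: trace must come back toward baseline after the
        # peak unless another candidate event interrupts the window
        w_end = min(p + decay_w, y.size)
        nxt = merged[idx + 1] if idx + 1 < len(merged) else None
        if nxt is None or nxt >= w_end:
            if w_end > p + 1:
                post_min = float(np.min(y[p + 1 : w_end]))
                if w_end < y.size and post_min - baseline_y > config.decay_fraction * amp:
                    continue
        events.append(
            DetectedEvent(
                peak_time_s=p / fs,
                baseline_pa=float(config.polarity * baseline_y),
                peak_pa=float(config.polarity * y[p]),
                amplitude_pa=amp,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Passive properties


def compute_passive_properties(
    step_responses: Sequence[Trace] | Sequence[np.ndarray],
    step_mv: float,
    sample_rate_hz: float | None = None,
    step_start_s: float = 0.005,
    step_duration_s: float = 0.020,
) -> PassiveProperties:
    """Estimate passive properties from averaged membrane-test steps.

    Each segment must contain a pre-step baseline and the full step.  The
    segments are averaged before estimation.  ``step_mv`` is the magnitude
    of the voltage step (e.g. 5 for the emulated 5 mV hyperpolarizing step).
    """
    if len(step_responses) == 0:
        raise InvalidInputError("need at least one step segment")
    first = step_responses[0]
    if isinstance(first, Trace):
        fs = first.sample_rate_hz
        arrs = [np.asarray(t.samples_pa, dtype=float) for t in step_responses]
    else:
        if sample_rate_hz is None:
            raise InvalidInputError("sample_rate_hz required for raw arrays")
        fs = sample_rate_hz
        arrs = [np.asarray(a, dtype=float) for a in step_responses]
    n = min(a.size for a in arrs)
    avg = np.mean([a[:n] for a in arrs], axis=0)

    i_start = int(round(step_start_s * fs))
    i_end = int(round((step_start_s + step_duration_s) * fs))
    if i_start < 2 or i_end > n:
        raise InvalidInputError("segment does not contain baseline and full step")

    holding = float(np.mean(avg[:i_start]))
    step = avg[i_start:i_end] - holding
    noise_sd = float(np.std(avg[:i_start], ddof=1)) if i_start > 1 else 0.0

    # steady state from the last quarter of the step
    q = max(1, (i_end - i_start) // 4)
    ss = float(np.mean(step[-q:]))
    if abs(ss) <= max(3.0 * noise_sd, 1e-12):
        raise EstimationError("step deflection not discernible above noise")
    peak = float(np.max(np.abs(step)))
    if peak <= 3.0 * noise_sd:
        raise EstimationError("capacitive transient not discernible above noise")

    # magnitudes; units: mV / pA = GOhm
    input_resistance_gohm = step_mv / abs(ss)
    series_resistance_mohm = 1000.0 * step_mv / peak
    transient = np.abs(step) - abs(ss)
    charge_pa_s = float(np.sum(np.clip(transient, 0.0, None)) / fs)
    capacitance_pf = 1000.0 * charge_pa_s / step_mv
    return PassiveProperties(
        capacitance_pf=capacitance_pf,
        input_resistance_gohm=input_resistance_gohm,
        series_resistance_mohm=series_resistance_mohm,
        holding_current_pa=holding,
    )


# ---------------------------------------------------------------------------
# I/O


def events_to_frame(events: Sequence[DetectedEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.peak_time_s, e.baseline_pa, e.peak_pa, e.amplitude_pa) for e in events],
        columns=["peak_time_s", "baseline_pa", "peak_pa", "amplitude_pa"],
    )


def write_events_csv(path: str | Path, events: Sequence[DetectedEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[DetectedEvent]:
    df = pd.read_csv(path)
    return [
        DetectedEvent(r.peak_time_s, r.baseline_pa, r.peak_pa, r.amplitude_pa)
        for r in df.itertuples()
    ]


def passive_properties_to_json(path: str | Path, props: PassiveProperties) -> None:
    with open(path, "w") as fh:
        json.dump(props.__dict__, fh, indent=2)
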
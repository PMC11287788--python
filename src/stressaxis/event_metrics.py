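"""Per-cell PSC summaries and distributions.

Conventions used throughout (deliberately asymmetric, matching standard
practice for these recordings):

* interevent interval = backward interval from an event's peak to the
  previous event's peak; the first event has no defined interval,
* amplitude eligibility: non-first events with backward interval >= 200 ms
  (inclusive); a first event qualifies when preceded by > 200 ms of
  recording time (strict),
* isolated events: > 200 ms (strict) to the adjacent event peak in BOTH
  directions; at the edges the recording start/end stands in for the
  missing neighbour,
* decay time = time between the first post-peak crossings of 80% and 20%
  of the peak, linearly interpolated between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .psc_detection import DetectedEvent, Trace

__all__ = [
    "MetricConfig",
    "CellEventSummary",
    "psc_frequency",
    "interevent_intervals",
    "eligible_amplitudes",
    "isolated_event_average",
    "decay_time_80_20",
    "cumulative_distribution",
    "summarize_cell",
]


class MetricError(ValueError):
    pass


class UndefinedDecayError(RuntimeError):
    """The waveform never falls to 20% of its peak."""


@dataclass(frozen=True)
class MetricConfig:
    amplitude_min_backward_interval_s: float = 0.200  # inclusive
    isolated_min_interval_s: float = 0.200  # exclusive, both directions
    snippet_pre_ms: float = 20.0
    snippet_post_ms: float = 100.0

    def validate(self) -> None:
        if self.amplitude_min_backward_interval_s <= 0 or self.isolated_min_interval_s <= 0:
            raise MetricError("interval thresholds must be > 0")


@dataclass
class CellEventSummary:
    """Per-cell event statistics plus the normalized average waveform."""

    frequency_hz: float
    intervals_s: np.ndarray
    eligible_amplitudes_pa: np.ndarray
    mean_interval_s: float
    mean_amplitude_pa: float
    average_event_waveform: np.ndarray | None
    waveform_sample_rate_hz: float | None
    decay_time_80_20_ms: float | None
    n_events: int


def _peak_times(events: Sequence[DetectedEvent]) -> np.ndarray:
    t = np.asarray([e.peak_time_s for e in events], dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise MetricError("events must be ordered by peak time")
    return t


def psc_frequency(events: Sequence[DetectedEvent], duration_s: float) -> float:
    """Event count divided by recording duration (Hz); zero events -> 0."""
    if duration_s <= 0:
        raise MetricError("duration_s must be > 0")
    return len(events) / duration_s


def interevent_intervals(events: Sequence[DetectedEvent]) -> np.ndarray:
    """Backward peak-to-peak intervals; the first event contributes none."""
    t = _peak_times(events)
    return np.diff(t) if t.size > 1 else np.zeros(0)


def eligible_amplitudes(
    events: Sequence[DetectedEvent],
    recording_start_s: float = 0.0,
    config: MetricConfig | None = None,
) -> np.ndarray:
    """Amplitudes of events clean enough for amplitude measurement.

    Non-first events are kept iff their backward interval is at least the
    threshold (inclusive); the first event is kept iff strictly more than
    the threshold of recording elapsed before its peak.
    """
    config = config or MetricConfig()
    config.validate()
    t = _peak_times(events)
    if t.size == 0:
        return np.zeros(0)
    amps = np.asarray([e.amplitude_pa for e in events], dtype=float)
    thr = config.amplitude_min_backward_interval_s
    keep = np.zeros(t.size, dtype=bool)
    keep[0] = (t[0] - recording_start_s) > thr
    if t.size > 1:
        keep[1:] = np.diff(t) >= thr
    return amps[keep]


def _isolated_mask(t: np.ndarray, duration_s: float, thr: float) -> np.ndarray:
    if t.size == 0:
        return np.zeros(0, dtype=bool)
    back = np.empty(t.size)
    back[0] = t[0]  # recording start stands in for the previous peak
    back[1:] = np.diff(t)
    fwd = np.empty(t.size)
    fwd[:-1] = np.diff(t)
    fwd[-1] = duration_s - t[-1]  # recording end stands in for the next peak
    return (back > thr) & (fwd > thr)


def isolated_event_average(
    events: Sequence[DetectedEvent],
    trace: Trace,
    config: MetricConfig | None = None,
) -> np.ndarray | None:
    """Average the isolated events of one cell, peak-normalized.

    Snippets are aligned at the peak sample, baseline-subtracted using the
    event's recorded baseline, averaged, and rescaled so the average's peak
    magnitude is 1.  Returns ``None`` when the cell has no isolated event
    fully contained in the trace.
    """
    config = config or MetricConfig()
    config.validate()
    t = _peak_times(events)
    mask = _isolated_mask(t, trace.duration_s, config.isolated_min_interval_s)
    fs = trace.sample_rate_hz
    pre = int(round(config.snippet_pre_ms / 1000.0 * fs))
    post = int(round(config.snippet_post_ms / 1000.0 * fs))
    snippets = []
    for e, keep in zip(events, mask):
        if not keep:
            continue
        p = int(round(e.peak_time_s * fs))
        if p - pre < 0 or p + post >= trace.samples_pa.size:
            continue
        snip = trace.samples_pa[p - pre : p + post + 1] - e.baseline_pa
        snippets.append(snip)
    if not snippets:
        return None
    avg = np.mean(snippets, axis=0)
    peak = avg[pre]
    if peak == 0:
        return None
    return avg / abs(peak)


def decay_time_80_20(waveform: np.ndarray, sample_rate_hz: float) -> float:
    """Decay time (ms) from 80% to 20% of the peak, post-peak.

    Crossing times are linearly interpolated between adjacent samples so the
    measure is resolution independent.  Raises :class:`UndefinedDecayError`
    if the waveform never falls to 20% of its peak.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 2:
        raise MetricError("waveform too short")
    sign = 1.0 if abs(w.max()) >= abs(w.min()) else -1.0
    w = sign * w
    ip = int(np.argmax(w))
    peak = w[ip]
    if peak <= 0:
        raise MetricError("waveform has no positive peak")

    def first_crossing(level: float, start: int) -> float:
        post = w[start:]
        below = np.flatnonzero(post <= level)
        if below.size == 0:
            raise UndefinedDecayError(f"waveform never decays to {level / peak:.0%} of peak")
        j = int(below[0])
        if j == 0:
            return float(start)
        y0, y1 = post[j - 1], post[j]
        frac = (y0 - level) / (y0 - y1)
        return float(start + j - 1 + frac)

    t80 = first_crossing(0.8 * peak, ip)
    t20 = first_crossing(0.2 * peak, ip)
    return (t20 - t80) / sample_rate_hz * 1000.0


def cumulative_distribution(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF as (sorted unique values, cum. prob.)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise MetricError("empty input")
    uniq, counts = np.unique(v, return_counts=True)
    return uniq, np.cumsum(counts) / v.size


def summarize_cell(
    events: Sequence[DetectedEvent],
    trace: Trace,
    config: MetricConfig | None = None,
) -> CellEventSummary:
    """All per-cell metrics in one pass.

    Cells with zero events still report frequency 0 but carry empty interval
    and amplitude lists and no waveform (they stay out of interval
    statistics downstream).
    """
    config = config or MetricConfig()
    intervals = interevent_intervals(events)
    amps = eligible_amplitudes(events, 0.0, config)
    waveform = isolated_event_average(events, trace, config)
    decay = None
    if waveform is not None:
        try:
            decay = decay_time_80_20(waveform, trace.sample_rate_hz)
        except UndefinedDecayError:
            decay = None
    return CellEventSummary(
        frequency_hz=psc_frequency(events, trace.duration_s),
        intervals_s=intervals,
        eligible_amplitudes_pa=amps,
        mean_interval_s=float(np.mean(intervals)) if intervals.size else float("nan"),
        mean_amplitude_pa=float(np.mean(amps)) if amps.size else float("nan"),
        average_event_waveform=waveform,
        waveform_sample_rate_hz=trace.sample_rate_hz if waveform is not None else None,
        decay_time_80_20_ms=decay,
        n_events=len(events),
    )
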
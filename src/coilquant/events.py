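"""Coiling-episode segmentation and per-embryo endpoint extraction.

A coiling episode (event) opens when the trace rises by at least
``start_threshold`` grey levels from one frame to the next, and closes at
the first subsequent frame whose value falls to or below the end level —
by default the median of the whole recording, which tracks the noise floor
of each trace automatically. The four endpoints reported per embryo are:

* tc_frequency — maxima count per minute of recording (peak-derived);
* mean_intensity — mean height of the maxima (peak-derived);
* mean_duration_s — mean event length (event-derived);
* mean_interval_s — mean gap between consecutive events (event-derived).

Recordings with 0 or 1 events have no defined interval; those summary cells
stay empty rather than becoming zero, so downstream statistics are not
biased by incalculable entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .activity import IntensityTrace
from .peaks import PeakSet

__all__ = [
    "MEDIAN",
    "EventParams",
    "CoilEvent",
    "EmbryoSummary",
    "extract_events",
    "intervals",
    "reprocess",
    "summarize",
]

#: Sentinel selecting the trace median as the event end level.
MEDIAN = "median"


@dataclass(frozen=True)
class EventParams:
    """start_threshold: frame-to-frame rise (grey levels) that opens an event;
    end_threshold: literal level, or :data:`MEDIAN` for the trace median;
    min_duration_s: drop events shorter than this (0 disables the filter —
    a guard against the many-false-short-durations failure mode of a too-low
    start threshold)."""

    start_threshold: float = 3.0
    end_threshold: Union[float, str] = MEDIAN
    min_duration_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.start_threshold > 0:
            raise ValueError("start_threshold must be > 0")
        if isinstance(self.end_threshold, str) and self.end_threshold != MEDIAN:
            raise ValueError(
                f"end_threshold must be a number or {MEDIAN!r}, got {self.end_threshold!r}"
            )
        if self.min_duration_s < 0:
            raise ValueError("min_duration_s must be >= 0")


@dataclass(frozen=True)
class CoilEvent:
    start_frame: int
    end_frame: int
    duration_s: float
    peak_intensity: float


@dataclass(frozen=True)
class EmbryoSummary:
    """Per-embryo endpoints; None marks an incalculable (empty) cell."""

    roi_id: str
    tc_frequency: float
    mean_intensity: float | None
    mean_duration_s: float | None
    mean_interval_s: float | None


def resolve_end_level(trace: IntensityTrace, params: EventParams) -> float:
    """The literal end level, or the median of the whole trace (zeros included)."""
    if params.end_threshold == MEDIAN:
        return float(np.median(trace.values))
    return float(params.end_threshold)


def extract_events(trace: IntensityTrace, params: EventParams) -> list[CoilEvent]:
    """Scan the trace for threshold-crossing coiling episodes.

    Outside an event, frame t opens one when value[t] - value[t-1] >=
    start_threshold; the event closes at the first later frame at or below
    the end level (that frame is included in the duration). An event still
    open at the last frame closes there.
    """
    v = np.asarray(trace.values, dtype=np.float64)
    if len(v) == 0:
        raise ValueError("extract_events: empty trace")
    end_level = resolve_end_level(trace, params)

    events: list[CoilEvent] = []
    start: int | None = None
    for t in range(1, len(v)):
        if start is None:
            if v[t] - v[t - 1] >= params.start_threshold:
                start = t
        elif v[t] <= end_level:
            events.append(_make_event(v, start, t, trace.fps))
            start = None
    if start is not None:
        events.append(_make_event(v, start, len(v) - 1, trace.fps))

    if params.min_duration_s > 0:
        events = [e for e in events if e.duration_s >= params.min_duration_s]
    return events


def _make_event(v: np.ndarray, start: int, end: int, fps: float) -> CoilEvent:
    return CoilEvent(
        start_frame=start,
        end_frame=end,
        duration_s=(end - start + 1) / fps,
        peak_intensity=float(v[start : end + 1].max()),
    )


def intervals(events: Sequence[CoilEvent], fps: float) -> list[float]:
    """Gaps between consecutive events in seconds; empty for 0 or 1 events.

    A single (or no) coil has no defined inter-coil interval, so nothing is
    reported rather than a misleading zero or infinity.
    """
    if len(events) < 2:
        return []
    return [
        (nxt.start_frame - prev.end_frame) / fps
        for prev, nxt in zip(events, events[1:])
    ]


def reprocess(trace: IntensityTrace, new_params: EventParams) -> list[CoilEvent]:
    """Re-segment with fresh thresholds; replaces (never merges with) prior
    results. This is the cheap rethresholding loop used to fix runaway or
    missed durations after visual inspection."""
    return extract_events(trace, new_params)


def summarize(
    roi_id: str,
    peakset: PeakSet,
    events: Sequence[CoilEvent],
    trace: IntensityTrace,
) -> EmbryoSummary:
    """Combine peak-derived and event-derived endpoints for one embryo."""
    freq = len(peakset.maxima) / trace.duration_min
    mean_intensity = (
        float(np.mean([h for _, h in peakset.maxima])) if peakset.maxima else None
    )
    mean_duration = (
        float(np.mean([e.duration_s for e in events])) if events else None
    )
    gaps = intervals(events, trace.fps)
    mean_interval = float(np.mean(gaps)) if gaps else None
    return EmbryoSummary(
        roi_id=roi_id,
        tc_frequency=freq,
        mean_intensity=mean_intensity,
        mean_duration_s=mean_duration,
        mean_interval_s=mean_interval,
    )
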
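"""Tail-coiling peak extraction from an intensity trace.

Two thresholds separate genuine coils from noise:

* minimal amplitude — how far a maximum must rise above the retained minima
  flanking it. Amplitude is prominence-style (relative, not absolute
  height), so baseline drift cannot promote noise into peaks.
* minimal peak distance — the rest time, in frames, below which two maxima
  are counted as one coil; the higher of the pair survives.

The amplitude stage is the classic alternating-extrema scan: walking the
trace, a running maximum is confirmed once the signal has dropped by at
least ``min_amplitude`` below it, after which a running minimum accumulates
and is confirmed once the signal has risen by at least ``min_amplitude``
above it, and so on. Plateaus resolve to their first frame. The distance
stage then suppresses confirmed maxima greedily in descending height order
(ties kept at the earlier frame), and minima are recomputed as the lowest
point between consecutive surviving maxima.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import IntensityTrace

__all__ = ["PeakParams", "PeakSet", "find_peaks", "peak_count", "write_peaks"]


@dataclass(frozen=True)
class PeakParams:
    """min_amplitude in trace intensity units; min_distance in frames."""

    min_amplitude: float = 0.7
    min_distance: int = 30

    def __post_init__(self) -> None:
        if self.min_amplitude < 0:
            raise ValueError("min_amplitude must be >= 0")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")


@dataclass
class PeakSet:
    """Alternating maxima/minima as (frame, intensity) pairs."""

    maxima: list[tuple[int, float]]
    minima: list[tuple[int, float]]
    params: PeakParams

    def __len__(self) -> int:
        return len(self.maxima)


def _strict_local_maxima(v: np.ndarray) -> list[int]:
    """Strict local maxima; plateaus collapse to their first frame."""
    out = []
    n = len(v)
    i = 1
    while i < n:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[j]:
                j += 1
            if j + 1 < n and v[j + 1] < v[j]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def _alternating_extrema(
    v: np.ndarray, delta: float
) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Confirmed maxima/minima of the alternating scan with amplitude delta."""
    maxima: list[tuple[int, float]] = []
    minima: list[tuple[int, float]] = []
    mx, mn = -np.inf, np.inf
    mxpos = mnpos = 0
    look_for_max = True
    for i, val in enumerate(v):
        if val > mx:
            mx, mxpos = val, i
        if val < mn:
            mn, mnpos = val, i
        if look_for_max:
            if mx - val >= delta:
                maxima.append((mxpos, float(mx)))
                mn, mnpos = val, i
                look_for_max = False
        else:
            if val - mn >= delta:
                minima.append((mnpos, float(mn)))
                mx, mxpos = val, i
                look_for_max = True
    return maxima, minima


def _suppress_close(
    maxima: list[tuple[int, float]], min_distance: int
) -> list[tuple[int, float]]:
    """Greedy distance suppression: tallest first, ties at the earlier frame."""
    if min_distance <= 0:
        return sorted(maxima)
    accepted: list[tuple[int, float]] = []
    for frame, height in sorted(maxima, key=lambda m: (-m[1], m[0])):
        if all(abs(frame - f) >= min_distance for f, _ in accepted):
            accepted.append((frame, height))
    return sorted(accepted)


def find_peaks(trace: IntensityTrace, params: PeakParams) -> PeakSet:
    """Extract coiling maxima/minima under amplitude and distance constraints."""
    v = np.asarray(trace.values, dtype=np.float64)
    if len(v) == 0:
        raise ValueError("find_peaks: empty trace")

    if params.min_amplitude == 0:
        maxima = [(i, float(v[i])) for i in _strict_local_maxima(v)]
    else:
        maxima, _ = _alternating_extrema(v, params.min_amplitude)
    maxima = _suppress_close(maxima, params.min_distance)

    minima: list[tuple[int, float]] = []
    for (f0, _), (f1, _) in zip(maxima, maxima[1:]):
        seg = v[f0 + 1 : f1]
        k = int(np.argmin(seg))  # first occurrence on ties
        minima.append((f0 + 1 + k, float(seg[k])))
    return PeakSet(maxima=maxima, minima=minima, params=params)


def peak_count(peakset: PeakSet) -> int:
    """Number of maxima = number of tail-coiling occurrences."""
    return len(peakset.maxima)


def write_peaks(
    peaksets: Sequence[PeakSet], fps: float, path: str | os.PathLike
) -> None:
    """Long CSV: roi_id, frame, time_s, intensity, kind in {max, min}."""
    rows = []
    for i, ps in enumerate(peaksets):
        for kind, pts in (("max", ps.maxima), ("min", ps.minima)):
            for frame, intensity in pts:
                rows.append(
                    {"roi_id": f"roi_{i}", "frame": frame,
                     "time_s": frame / fps, "intensity": intensity,
                     "kind": kind}
                )
    pd.DataFrame(
        rows, columns=["roi_id", "frame", "time_s", "intensity", "kind"]
    ).to_csv(Path(path), index=False)
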
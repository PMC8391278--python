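"""From enhanced stack to per-ROI motion traces.

Motion registers as per-pixel absolute difference between consecutive frames
(the stack-difference step); averaging that difference over each chorion's
circular footprint yields one intensity-of-change trace per embryo — the
1-D signal every downstream stage consumes. A coiling embryo produces a
brief burst of positive trace values; a resting embryo produces values near
zero (pure noise floor).

Conventions fixed here: the difference stack keeps the source frame count by
zero-padding frame 0 (so trace index == frame index and frame 0 can never
host a peak), and circle membership is strict interior (pixel center inside
the circle), which makes every value reproducible by a naive pixel loop.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enhance import EnhanceConfig, enhance_stack
from .errors import EmptyInputError
from .roi_detect import CircleROI
from .stack_io import ImageStack

__all__ = [
    "IntensityTrace",
    "stack_difference",
    "roi_trace",
    "trace_all",
    "write_traces",
    "read_traces",
]


@dataclass
class IntensityTrace:
    """Per-frame mean change intensity inside one ROI."""

    values: np.ndarray
    fps: float
    roi: CircleROI | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return int(self.values.shape[0])

    @property
    def duration_min(self) -> float:
        """Trace length in minutes (for per-minute frequencies)."""
        return len(self) / self.fps / 60.0


def stack_difference(stack: ImageStack) -> ImageStack:
    """Absolute difference between consecutive frames, zero-padded at frame 0."""
    if stack.n_frames < 2:
        raise EmptyInputError("stack_difference requires at least 2 frames")
    frames = np.asarray(stack.frames, dtype=np.float32)
    out = np.zeros_like(frames)
    out[1:] = np.abs(frames[1:] - frames[:-1])
    return ImageStack(frames=out, fps=stack.fps, source_path=stack.source_path)


def _circle_pixels(
    shape: tuple[int, int], roi: CircleROI
) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of in-frame pixels strictly inside the circle."""
    h, w = shape
    y0 = max(0, int(np.floor(roi.cy - roi.r)))
    y1 = min(h, int(np.ceil(roi.cy + roi.r)) + 1)
    x0 = max(0, int(np.floor(roi.cx - roi.r)))
    x1 = min(w, int(np.ceil(roi.cx + roi.r)) + 1)
    if y0 >= y1 or x0 >= x1:
        raise ValueError(f"ROI {roi} lies entirely outside a {h}x{w} frame")
    ys, xs = np.mgrid[y0:y1, x0:x1]
    inside = (xs - roi.cx) ** 2 + (ys - roi.cy) ** 2 < roi.r**2
    if not inside.any():
        raise ValueError(f"ROI {roi} covers no pixel centers in a {h}x{w} frame")
    return ys[inside], xs[inside]


def roi_trace(diff: ImageStack, roi: CircleROI) -> IntensityTrace:
    """Mean of each difference frame over the circle's interior pixels.

    Pixels outside the frame are excluded from the mean (border ROIs simply
    average over fewer pixels).
    """
    ys, xs = _circle_pixels((diff.height, diff.width), roi)
    values = diff.frames[:, ys, xs].mean(axis=1)
    return IntensityTrace(values=values, fps=diff.fps, roi=roi)


def trace_all(
    stack: ImageStack,
    rois: Sequence[CircleROI],
    enhance_cfg: EnhanceConfig | None = None,
) -> list[IntensityTrace]:
    """enhance -> difference -> one trace per ROI (order preserved)."""
    if not rois:
        raise EmptyInputError("trace_all requires at least one ROI")
    if enhance_cfg is None:
        enhance_cfg = EnhanceConfig()
    diff = stack_difference(enhance_stack(stack, enhance_cfg))
    return [roi_trace(diff, roi) for roi in rois]


def write_traces(traces: Sequence[IntensityTrace], path: str | os.PathLike) -> None:
    """Wide CSV: frame, time_s, then one column per ROI (roi_0, roi_1, ...)."""
    if not traces:
        raise EmptyInputError("no traces to write")
    n = len(traces[0])
    fps = traces[0].fps
    data = {"frame": np.arange(n), "time_s": np.arange(n) / fps}
    for i, tr in enumerate(traces):
        if len(tr) != n or tr.fps != fps:
            raise ValueError("all traces must share length and fps")
        data[f"roi_{i}"] = tr.values
    pd.DataFrame(data).to_csv(Path(path), index=False)


def read_traces(path: str | os.PathLike) -> list[IntensityTrace]:
    """Read traces written by :func:`write_traces` (fps recovered from time_s)."""
    df = pd.read_csv(Path(path))
    if len(df) < 2:
        raise EmptyInputError(f"trace table {path} holds fewer than 2 frames")
    fps = round(1.0 / (df["time_s"].iloc[1] - df["time_s"].iloc[0]), 6)
    cols = [c for c in df.columns if c.startswith("roi_")]
    return [IntensityTrace(values=df[c].to_numpy(), fps=fps) for c in cols]
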
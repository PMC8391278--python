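"""Diagnostic plotting of traces, detected peaks, and event spans."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

from .activity import IntensityTrace
from .events import CoilEvent
from .peaks import PeakSet


def plot_trace(
    trace: IntensityTrace,
    peakset: PeakSet | None = None,
    events: Sequence[CoilEvent] | None = None,
    path: str | os.PathLike = "trace.png",
    title: str = "",
) -> None:
    """Activity plot: intensity over frames, maxima in red, minima in blue,
    event spans shaded. Written to ``path``; no interactive backend needed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(trace.values, lw=0.8, color="0.3")
    if peakset is not None:
        if peakset.maxima:
            fr, val = zip(*peakset.maxima)
            ax.plot(fr, val, "o", ms=4, color="red", label="maxima")
        if peakset.minima:
            fr, val = zip(*peakset.minima)
            ax.plot(fr, val, "o", ms=4, color="blue", label="minima")
    if events:
        for e in events:
            ax.axvspan(e.start_frame, e.end_frame, color="orange", alpha=0.25)
    ax.set_xlabel("frame")
    ax.set_ylabel("mean change intensity")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
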
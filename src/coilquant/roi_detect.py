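"""Automatic chorion detection: Gaussian blur -> IsoData threshold -> circle
Hough transform with score thresholding.

A zebrafish chorion images as an (approximately) circular shell. Detection
runs on a single reference frame: the frame is blurred to thicken the chorion
annulus, binarized with the iterative-intermeans (IsoData) threshold, and
circles are scored by the fraction of their rasterized perimeter supported by
foreground within a one-pixel tolerance band. The number of eggs is never
supplied by the caller; every candidate above the score threshold survives a
greedy spatial suppression, so the data alone decides how many circles exist.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import circle_perimeter

from .errors import ConfigurationError
from .stack_io import ImageStack

__all__ = [
    "CircleROI",
    "HoughConfig",
    "isodata_threshold",
    "hough_circles",
    "detect_rois",
    "save_rois",
    "load_rois",
]


@dataclass(frozen=True)
class CircleROI:
    """A detected chorion: center (cx, cy), radius r (pixels), Hough score."""

    cx: float
    cy: float
    r: float
    score: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"radius must be positive, got {self.r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class HoughConfig:
    """Search parameters for the circle Hough stage.

    ``min_center_spacing`` defaults to ``r_min`` (chorions cannot
    interpenetrate by more than a margin). ``blur_sigma`` is the Gaussian
    pre-blur applied to the reference frame before thresholding; the default
    of 4 px suits 720p recordings and should be scaled with image size.
    """

    r_min: int
    r_max: int
    r_step: int = 1
    score_threshold: float = 0.7
    min_center_spacing: float | None = None
    blur_sigma: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= self.r_max:
            raise ConfigurationError(
                f"need 0 < r_min <= r_max, got ({self.r_min}, {self.r_max})"
            )
        if self.r_step < 1:
            raise ConfigurationError(f"r_step must be >= 1, got {self.r_step}")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ConfigurationError(
                f"score_threshold must lie in [0, 1], got {self.score_threshold}"
            )
        if self.min_center_spacing is None:
            self.min_center_spacing = float(self.r_min)
        if self.min_center_spacing < 0:
            raise ConfigurationError("min_center_spacing must be >= 0")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")

    @property
    def radii(self) -> np.ndarray:
        return np.arange(self.r_min, self.r_max + 1, self.r_step, dtype=int)


def isodata_threshold(image: np.ndarray) -> tuple[int, np.ndarray]:
    """Iterative-intermeans (IsoData) binarization.

    Pixel values are rounded to integers; starting from the mid-range, the
    threshold t is replaced by round((mean of pixels <= t + mean of pixels
    > t) / 2) until it is a fixed point. Foreground is pixels strictly above
    t. A perfectly uniform image yields its single value as the threshold, an
    all-background mask, and a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("isodata_threshold: empty image")
    vals = np.rint(image).astype(np.int64)
    lo, hi = int(vals.min()), int(vals.max())
    if lo == hi:
        warnings.warn(
            f"isodata_threshold: uniform image (value {lo}); no foreground",
            UserWarning,
            stacklevel=2,
        )
        return lo, np.zeros(image.shape, dtype=bool)

    # histogram-based means: O(range) per iteration
    hist = np.bincount((vals - lo).ravel(), minlength=hi - lo + 1)
    levels = np.arange(lo, hi + 1, dtype=np.float64)
    csum_n = np.cumsum(hist)
    csum_v = np.cumsum(hist * levels)
    total_n, total_v = csum_n[-1], csum_v[-1]

    def next_t(t: int) -> int:
        i = t - lo
        below = csum_v[i] / csum_n[i]
        above = (total_v - csum_v[i]) / (total_n - csum_n[i])
        return int(round((below + above) / 2.0))

    t = int(round((lo + hi) / 2.0))
    t = min(max(t, lo), hi - 1)
    seen = set()
    while t not in seen:
        seen.add(t)
        t_new = min(max(next_t(t), lo), hi - 1)
        if t_new == t:
            break
        t = t_new
    return t, vals > t


def _perimeter_offsets(r: int) -> np.ndarray:
    """Midpoint-rasterized circle perimeter as (dy, dx) offsets."""
    rr, cc = circle_perimeter(0, 0, int(r))
    return np.stack([rr, cc], axis=1)


def _score_map(support: np.ndarray, r: int) -> tuple[np.ndarray, int]:
    """Integer perimeter-support counts for every candidate center.

    ``support`` is the 1-px-dilated foreground; perimeter positions falling
    outside the frame count in the denominator but can never be supported.
    """
    h, w = support.shape
    offsets = _perimeter_offsets(r)
    padded = np.pad(support.astype(np.int32), r)
    acc = np.zeros((h, w), dtype=np.int32)
    for dy, dx in offsets:
        acc += padded[r + dy : r + dy + h, r + dx : r + dx + w]
    return acc, len(offsets)


def hough_circles(mask: np.ndarray, config: HoughConfig) -> list[CircleROI]:
    """Detect circles in a binary mask by perimeter-support voting.

    The score of a candidate (cx, cy, r) is the fraction of its rasterized
    perimeter positions that land on foreground within a 1-pixel tolerance
    band (foreground dilated by a 3x3 element). All candidates with score >=
    ``score_threshold`` are sorted by descending score (ties broken by
    smaller (cy, cx), then smaller r) and accepted greedily subject to
    centers being >= ``min_center_spacing`` apart.

    A thick foreground annulus supports a whole plateau of equally perfect
    candidates, so an accepted detection is reported as the centroid (mean
    cx, cy, r) of all same-score candidates within ``min_center_spacing`` of
    the seed candidate; this recovers sub-pixel-symmetric centers instead of
    the plateau's lexicographic corner.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("hough_circles: empty mask")
    h, w = mask.shape
    if config.r_min > float(np.hypot(h, w)) / 2.0:
        raise ConfigurationError(
            f"r_min={config.r_min} exceeds the image half-diagonal"
        )
    if not mask.any():
        return []

    support = ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))
    candidates: list[tuple[float, int, int, int]] = []  # (score, cy, cx, r)
    thr = config.score_threshold
    for r in config.radii:
        acc, n_perim = _score_map(support, int(r))
        min_count = int(np.ceil(thr * n_perim - 1e-9))
        ys, xs = np.nonzero(acc >= min_count)
        for cy, cx in zip(ys.tolist(), xs.tolist()):
            candidates.append((acc[cy, cx] / n_perim, cy, cx, int(r)))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    return _greedy_plateau_select(candidates, config.min_center_spacing)


def _greedy_plateau_select(
    candidates: list[tuple[float, int, int, int]], spacing: float
) -> list[CircleROI]:
    """Greedy spatial suppression over (score, cy, cx, r) candidates sorted
    by descending score; each acceptance reports its equal-score plateau
    centroid. Shared verbatim by the brute-force oracle."""
    accepted: list[CircleROI] = []
    spacing2 = spacing**2
    for score, cy, cx, r in candidates:
        if any((cx - a.cx) ** 2 + (cy - a.cy) ** 2 < spacing2 for a in accepted):
            continue
        plateau = [
            (pcy, pcx, pr)
            for pscore, pcy, pcx, pr in candidates
            if pscore == score
            and (pcx - cx) ** 2 + (pcy - cy) ** 2 <= max(spacing2, 0.0)
        ] or [(cy, cx, r)]
        mcy = float(np.mean([p[0] for p in plateau]))
        mcx = float(np.mean([p[1] for p in plateau]))
        mr = float(np.mean([p[2] for p in plateau]))
        if any((mcx - a.cx) ** 2 + (mcy - a.cy) ** 2 < spacing2 for a in accepted):
            continue
        accepted.append(CircleROI(cx=mcx, cy=mcy, r=mr, score=float(score)))
    return accepted


def detect_rois(
    stack: ImageStack, config: HoughConfig, reference_frame: int = 0
) -> list[CircleROI]:
    """Locate every chorion on one reference frame of the stack.

    Pipeline: Gaussian blur (``config.blur_sigma``) -> IsoData threshold ->
    circle Hough voting. IsoData marks pixels above the threshold; since the
    chorions are the sparse class under either darkfield (bright-on-dark) or
    brightfield (dark-on-bright) illumination, the mask polarity is flipped
    when foreground would cover more than half the frame. Output is sorted by
    (cy, cx) for stable downstream column ordering.
    """
    if not 0 <= reference_frame < stack.n_frames:
        raise IndexError(
            f"reference_frame {reference_frame} outside stack of {stack.n_frames} frames"
        )
    frame = stack.frames[reference_frame].astype(np.float64)
    if config.blur_sigma > 0:
        frame = ndimage.gaussian_filter(frame, config.blur_sigma, mode="reflect")
    _, mask = isodata_threshold(frame)
    if mask.mean() > 0.5:
        mask = ~mask
    circles = hough_circles(mask, config)
    return sorted(circles, key=lambda c: (c.cy, c.cx))


def save_rois(rois: list[CircleROI], path: str | os.PathLike) -> None:
    """Serialize an ROI set to JSON ({cx, cy, r, score} records)."""
    payload = [
        {"cx": c.cx, "cy": c.cy, "r": c.r, "score": c.score} for c in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_rois(path: str | os.PathLike) -> list[CircleROI]:
    payload = json.loads(Path(path).read_text())
    return [CircleROI(**rec) for rec in payload]
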
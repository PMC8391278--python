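"""Naive reference implementations used to cross-check the package.

Everything here favours directness over speed: explicit loops, exhaustive
scans, no shared code with the implementation paths under test beyond
standard library primitives (the circle rasterizer and binary dilation,
which are inputs to the definition being checked, not part of it).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.draw import circle_perimeter


def isodata_scan(image: np.ndarray) -> list[int]:
    """All intermeans fixed points found by scanning every candidate level."""
    vals = np.rint(np.asarray(image)).astype(np.int64).ravel()
    lo, hi = int(vals.min()), int(vals.max())
    fixed = []
    for t in range(lo, hi):
        below = vals[vals <= t]
        above = vals[vals > t]
        if len(below) == 0 or len(above) == 0:
            continue
        if int(round((below.mean() + above.mean()) / 2.0)) == t:
            fixed.append(t)
    return fixed


def hough_accumulator(
    mask: np.ndarray, radii: list[int]
) -> list[tuple[float, int, int, int]]:
    """Brute-force perimeter-support scores for every (cy, cx, r) candidate.

    Returns (score, cy, cx, r) tuples sorted the way the implementation
    sorts its candidate list (descending score, then cy, cx, r).
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    support = ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))
    out = []
    for r in radii:
        rr, cc = circle_perimeter(0, 0, int(r))
        n = len(rr)
        for cy in range(h):
            for cx in range(w):
                count = 0
                for dy, dx in zip(rr, cc):
                    y, x = cy + dy, cx + dx
                    if 0 <= y < h and 0 <= x < w and support[y, x]:
                        count += 1
                out.append((count / n, cy, cx, int(r)))
    out.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    return out


def circle_mean_loop(frame: np.ndarray, cx: float, cy: float, r: float) -> float:
    """Mean over pixels whose center lies strictly inside the circle."""
    h, w = frame.shape
    total, n = 0.0, 0
    for y in range(h):
        for x in range(w):
            if (x - cx) ** 2 + (y - cy) ** 2 < r**2:
                total += float(frame[y, x])
                n += 1
    if n == 0:
        raise ValueError("circle covers no pixels")
    return total / n


def alternating_extrema_naive(v: np.ndarray, delta: float) -> list[tuple[int, float]]:
    """Amplitude-filtered maxima by a plain state-machine walk of the trace."""
    v = np.asarray(v, dtype=float)
    maxima = []
    state = "search_max"
    best_val, best_pos = -np.inf, 0
    for i in range(len(v)):
        if state == "search_max":
            if v[i] > best_val:
                best_val, best_pos = v[i], i
            elif best_val - v[i] >= delta:
                maxima.append((best_pos, float(best_val)))
                state = "search_min"
                best_val, best_pos = v[i], i
        else:
            if v[i] < best_val:
                best_val, best_pos = v[i], i
            elif v[i] - best_val >= delta:
                state = "search_max"
                best_val, best_pos = v[i], i
    return maxima


def greedy_distance_select(
    maxima: list[tuple[int, float]], min_distance: int
) -> list[tuple[int, float]]:
    """Repeatedly take the tallest unchosen candidate (earlier frame on ties)
    compatible with everything chosen so far; verify the result is maximal."""
    remaining = list(maxima)
    chosen: list[tuple[int, float]] = []
    while remaining:
        best = max(remaining, key=lambda m: (m[1], -m[0]))
        remaining.remove(best)
        if all(abs(best[0] - f) >= min_distance for f, _ in chosen):
            chosen.append(best)
    for cand in maxima:  # maximality: nothing compatible was left out
        if cand not in chosen:
            assert any(abs(cand[0] - f) < min_distance for f, _ in chosen) or any(
                c == cand for c in chosen
            )
    return sorted(chosen)


def find_peaks_naive(v: np.ndarray, min_amplitude: float, min_distance: int):
    """Composition of the two naive stages above."""
    maxima = alternating_extrema_naive(v, min_amplitude)
    return greedy_distance_select(maxima, min_distance)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur_loop(image: np.ndarray, sigma: float) -> np.ndarray:
    """Direct double-loop separable convolution with reflect padding."""
    if sigma == 0:
        return np.asarray(image, dtype=float).copy()
    k = gaussian_kernel_1d(sigma)
    radius = (len(k) - 1) // 2
    img = np.asarray(image, dtype=float)
    padded = np.pad(img, radius, mode="symmetric")  # scipy's "reflect"
    h, w = img.shape
    tmp = np.zeros((h, w + 2 * radius))
    for y in range(h):
        for x in range(w + 2 * radius):
            tmp[y, x] = float(np.dot(k, padded[y : y + 2 * radius + 1, x]))
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            out[y, x] = float(np.dot(k, tmp[y, x : x + 2 * radius + 1]))
    return out
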
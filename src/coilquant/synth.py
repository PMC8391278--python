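"""Synthetic traces and dish videos with exact ground truth.

Every pipeline stage is testable without any recorded data: this module
draws a dish of non-overlapping chorions (bright annuli in darkfield, dark
in brightfield) each holding an elongated embryo blob, and rotates the blob
inside its chorion during scheduled coiling bursts. Rotation produces
localized inter-frame pixel change — the same signature a real coil leaves
in a difference stack — so the schedule is the ground truth for every
downstream count, duration, and interval.

Signal model choices (and what they deliberately simplify):

* A coil onset is fast relative to the frame interval, so the blob rotates
  at constant angular speed for the whole burst; the difference trace is
  then an approximately rectangular pulse with a one-frame rise, matching
  the sharp onsets real coils produce (a slow smooth onset would never
  trip a frame-to-frame start threshold, and real ones do).
* Blob/interior contrast is fixed so that, through the default enhancement
  chain, trace pulses peak near 10 grey levels — the scale of reported
  coil intensities for untreated embryos.
* No chorion translucency, no embryo drift between coils, no illumination
  flicker: recovery results on this generator bound what the pipeline can
  do on clean recordings, not on pathological ones.

Trace-level simulation (``simulate_trace``) bypasses the optics entirely
and writes bursts straight into a 1-D signal: smooth raised-cosine bumps by
default (the morphology of real activity plots), rectangular pulses for
oracle tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np

from .activity import IntensityTrace
from .errors import ConfigurationError, PlacementError
from .roi_detect import CircleROI
from .stack_io import ImageStack

__all__ = [
    "Burst",
    "CoilSchedule",
    "DishSpec",
    "simulate_trace",
    "simulate_video",
    "make_schedule",
]

# darkfield grey levels (brightfield is the 255-complement)
_BG = 15.0
_INTERIOR = 25.0
_RING = 200.0
_BLOB = 230.0
_RING_HALF_WIDTH = 1.5


@dataclass(frozen=True)
class Burst:
    """One scheduled coil: [start_frame, start_frame + duration_frames)."""

    start_frame: int
    duration_frames: int
    amplitude: float = 10.0

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.duration_frames


#: Per-embryo burst lists; index = embryo index.
CoilSchedule = Sequence[Sequence[Burst]]


def _check_bursts(bursts: Sequence[Burst], n_frames: int) -> list[Burst]:
    bursts = sorted(bursts, key=lambda b: b.start_frame)
    for b in bursts:
        if b.start_frame < 0 or b.end_frame > n_frames:
            raise ConfigurationError(f"burst {b} outside [0, {n_frames})")
        if b.duration_frames < 2:
            raise ConfigurationError(f"burst {b} shorter than 2 frames")
    for a, b in zip(bursts, bursts[1:]):
        if b.start_frame < a.end_frame:
            raise ConfigurationError(f"bursts {a} and {b} overlap")
    return bursts


def _bump(duration: int, amplitude: float, shape: str) -> np.ndarray:
    if shape == "rect":
        return np.full(duration, amplitude)
    if shape == "cosine":
        profile = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(duration) / (duration - 1)))
        return amplitude * profile / profile.max()
    raise ConfigurationError(f"unknown burst shape {shape!r}")


def simulate_trace(
    length: int,
    bursts: Sequence[Burst],
    noise_sigma: float = 0.0,
    seed: int = 0,
    fps: float = 30.0,
    shape: Literal["cosine", "rect"] = "cosine",
) -> tuple[IntensityTrace, list[Burst]]:
    """Zero-baseline trace with one bump per burst plus clipped Gaussian noise.

    The bump peak equals the burst amplitude exactly. Frame 0 is forced to
    zero, mirroring the zero-padded first difference frame. Returns the
    trace and the (sorted) ground-truth schedule.
    """
    bursts = _check_bursts(bursts, length)
    values = np.zeros(length, dtype=np.float64)
    for b in bursts:
        values[b.start_frame : b.end_frame] = _bump(b.duration_frames, b.amplitude, shape)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sigma, length), 0.0, None)
    values[0] = 0.0
    return IntensityTrace(values=values, fps=fps), list(bursts)


@dataclass
class DishSpec:
    """Recording geometry and conditions for a synthetic dish video."""

    n_eggs: int = 12
    frame_shape: tuple[int, int] = (240, 320)  # (height, width)
    r_min: float = 18.0
    r_max: float = 24.0
    layout: Literal["grid", "random"] = "grid"
    noise_sigma: float = 0.0
    fps: float = 30.0
    duration_s: float = 60.0
    seed: int = 0
    mode: Literal["darkfield", "brightfield"] = "darkfield"

    def __post_init__(self) -> None:
        if self.n_eggs < 1:
            raise ConfigurationError("n_eggs must be >= 1")
        if not 0 < self.r_min <= self.r_max:
            raise ConfigurationError("need 0 < r_min <= r_max")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fps and duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


def _place_grid(spec: DishSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    h, w = spec.frame_shape
    cols = int(np.ceil(np.sqrt(spec.n_eggs * w / h)))
    rows = int(np.ceil(spec.n_eggs / cols))
    cell_h, cell_w = h / rows, w / cols
    if min(cell_h, cell_w) / 2.0 < spec.r_max + 3:
        raise PlacementError(
            f"{spec.n_eggs} eggs of radius <= {spec.r_max} do not fit a "
            f"{h}x{w} frame without overlap"
        )
    centers = []
    for i in range(spec.n_eggs):
        r_i, c_i = divmod(i, cols)
        jy, jx = rng.uniform(-2.0, 2.0, size=2)
        centers.append(((r_i + 0.5) * cell_h + jy, (c_i + 0.5) * cell_w + jx))
    return centers


def _place_random(
    spec: DishSpec, radii: np.ndarray, rng: np.random.Generator
) -> list[tuple[float, float]]:
    h, w = spec.frame_shape
    centers: list[tuple[float, float]] = []
    for i in range(spec.n_eggs):
        r = radii[i] + 3
        for _ in range(2000):
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
            if all(
                np.hypot(cy - y, cx - x) >= radii[i] + radii[j] + 4
                for j, (y, x) in enumerate(centers)
            ):
                centers.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place egg {i} of {spec.n_eggs} without overlap"
            )
    return centers


def _blob_angles(
    bursts: Sequence[Burst], n_frames: int, theta0: float
) -> np.ndarray:
    """Blob orientation per frame: static except during bursts, where it
    advances at constant speed by pi * min(amplitude/10, 2) in total."""
    theta = np.full(n_frames, theta0)
    offset = 0.0
    for b in bursts:
        total = np.pi * min(b.amplitude / 10.0, 2.0)
        k = np.arange(b.duration_frames)
        theta[b.start_frame : b.end_frame] = (
            theta0 + offset + total * k / (b.duration_frames - 1)
        )
        offset += total
        theta[b.end_frame :] = theta0 + offset
    return theta


def simulate_video(
    spec: DishSpec, schedule: CoilSchedule
) -> tuple[ImageStack, dict]:
    """Render a dish video for the given per-embryo coil schedule.

    Returns the stack and a ground-truth dict with keys ``circles`` (list of
    :class:`CircleROI`, sorted by (cy, cx) like ``detect_rois`` output),
    ``schedule`` (per-embryo bursts, matching the circle order), and
    ``spec``. Bit-reproducible for a fixed spec and schedule.
    """
    if len(schedule) != spec.n_eggs:
        raise ConfigurationError(
            f"schedule covers {len(schedule)} embryos, spec has {spec.n_eggs} eggs"
        )
    n_frames = spec.n_frames
    schedule = [_check_bursts(bursts, n_frames) for bursts in schedule]
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape

    radii = rng.uniform(spec.r_min, spec.r_max, spec.n_eggs)
    centers = (
        _place_grid(spec, rng)
        if spec.layout == "grid"
        else _place_random(spec, radii, rng)
    )

    # sort eggs by (cy, cx) so truth order matches detect_rois output order
    order = sorted(range(spec.n_eggs), key=lambda i: centers[i])
    centers = [centers[i] for i in order]
    radii = radii[order]
    schedule = [schedule[i] for i in order]

    base = np.full((h, w), _BG)
    egg_px: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = max(0, int(cy - r - 3)), min(h, int(cy + r + 4))
        x0, x1 = max(0, int(cx - r - 3)), min(w, int(cx + r + 4))
        ys, xs = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(ys - cy, xs - cx)
        base[y0:y1, x0:x1][d < r - _RING_HALF_WIDTH] = _INTERIOR
        base[y0:y1, x0:x1][np.abs(d - r) <= _RING_HALF_WIDTH] = _RING
        egg_px.append((ys, xs, ys - cy, xs - cx))

    theta0 = rng.uniform(0.0, 2.0 * np.pi, spec.n_eggs)
    thetas = np.stack(
        [
            _blob_angles(schedule[i], n_frames, theta0[i])
            for i in range(spec.n_eggs)
        ]
    )

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for t in range(n_frames):
        frame = base.copy()
        for i, ((ys, xs, dy, dx), r) in enumerate(zip(egg_px, radii)):
            a, b = 0.60 * r, 0.25 * r
            th = thetas[i, t]
            xr = dx * np.cos(th) + dy * np.sin(th)
            yr = -dx * np.sin(th) + dy * np.cos(th)
            inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
            frame[ys[inside], xs[inside]] = _BLOB
        if spec.mode == "brightfield":
            frame = 255.0 - frame
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        frames[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    circles = [
        CircleROI(cx=float(cx), cy=float(cy), r=float(r), score=1.0)
        for (cy, cx), r in zip(centers, radii)
    ]
    truth = {
        "circles": circles,
        "schedule": schedule,
        "spec": asdict(spec),
    }
    stack = ImageStack(
        frames=frames, fps=spec.fps, source_path=f"synthetic(seed={spec.seed})"
    )
    return stack, truth


def make_schedule(
    spec: DishSpec,
    coils_per_embryo: Sequence[int] | None = None,
    duration_frames: int = 20,
    amplitude: float = 10.0,
    min_gap_frames: int = 70,
    seed: int | None = None,
) -> CoilSchedule:
    """Evenly spaced, jittered bursts; one list per embryo.

    ``coils_per_embryo`` defaults to a reproducible draw of 2-8 coils per
    embryo (typical spontaneous rates for untreated ~24 hpf embryos over a
    one-minute recording). Bursts are guaranteed disjoint with at least
    ``min_gap_frames`` between consecutive bursts of the same embryo.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_frames = spec.n_frames
    margin = 10
    if coils_per_embryo is None:
        k_max = max(0, (n_frames - 2 * margin) // (duration_frames + min_gap_frames))
        lo, hi = min(2, k_max), min(8, k_max)
        coils_per_embryo = rng.integers(lo, hi + 1, spec.n_eggs).tolist()
    if len(coils_per_embryo) != spec.n_eggs:
        raise ConfigurationError("coils_per_embryo length must equal n_eggs")

    schedule: list[list[Burst]] = []
    for k in coils_per_embryo:
        bursts: list[Burst] = []
        if k > 0:
            period = (n_frames - 2 * margin) / k
            slack = period - duration_frames - min_gap_frames
            if slack < 0:
                raise ConfigurationError(
                    f"{k} coils of {duration_frames} frames with gap "
                    f"{min_gap_frames} do not fit {n_frames} frames"
                )
            for i in range(k):
                start = int(margin + i * period + rng.uniform(0, slack))
                bursts.append(Burst(start, duration_frames, amplitude))
        schedule.append(bursts)
    return schedule
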
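"""Reading video / image-sequence input and writing tabular results.

The pixel container for the whole pipeline is :class:`ImageStack`: an ordered
set of grayscale frames on a canonical 8-bit [0, 255] scale plus a frame rate.
All downstream thresholds (start threshold 3 grey levels, minimal peak
amplitudes around 0.6-0.95) are quoted on that 8-bit display scale, so any
deeper source is rescaled linearly on read.

Results are exported as a five-sheet workbook (TC, Intensity, Interval,
Duration, Summary) with a parallel set of plain CSV mirrors, one column per
embryo in the first four sheets and one row per embryo in Summary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, EmptyInputError, FormatError

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_workbook",
    "WORKBOOK_SHEETS",
]

#: ITU-R BT.709 luminance weights used for colour -> grayscale conversion.
LUMA_WEIGHTS = (0.2125, 0.7154, 0.0721)

WORKBOOK_SHEETS = ("TC", "Intensity", "Interval", "Duration", "Summary")

_VIDEO_SUFFIXES = {".avi", ".mp4", ".mov"}
_TIFF_SUFFIXES = {".tif", ".tiff"}
_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class ImageStack:
    """Ordered grayscale frames with a frame rate.

    Parameters
    ----------
    frames
        Array of shape (n_frames, height, width), values on the [0, 255]
        scale (float; fractional values appear after filtering).
    fps
        Frames per second; must be positive.
    source_path
        Provenance string (file the stack was read from, or a synthetic tag).
    """

    frames: np.ndarray
    fps: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, height, width), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise EmptyInputError("stack holds zero frames")
        if not self.fps > 0:
            raise ConfigurationError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    @property
    def duration_s(self) -> float:
        """Recording length in seconds (n_frames / fps)."""
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds (frame_index / fps, 0-based)."""
        return np.arange(self.n_frames) / self.fps


def _to_gray(frame: np.ndarray) -> np.ndarray:
    """Collapse a colour frame to luminance; pass grayscale through."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        rgb = frame[..., :3].astype(np.float64)
        return rgb @ np.asarray(LUMA_WEIGHTS)
    raise FormatError(f"cannot interpret frame of shape {frame.shape} as an image")


def _normalize_depth(frames: np.ndarray, source_dtype: np.dtype) -> np.ndarray:
    """Rescale integer bit depths > 8 linearly onto [0, 255].

    8-bit input is passed through untouched; floats are assumed to already be
    on the 8-bit scale and are clipped.
    """
    if np.issubdtype(source_dtype, np.integer):
        info = np.iinfo(source_dtype)
        if info.max > 255:
            return frames * (255.0 / info.max)
        return frames
    return np.clip(frames, 0.0, 255.0)


def _read_image_file(path: Path) -> np.ndarray:
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return tifffile.imread(str(path))
    import imageio.v3 as iio

    return iio.imread(str(path))


def _read_sequence_dir(path: Path) -> tuple[np.ndarray, np.dtype]:
    names = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not names:
        raise EmptyInputError(f"no PNG/TIFF frames found in directory {path}")
    raws = [_read_image_file(p) for p in names]
    dtype = np.asarray(raws[0]).dtype
    grays = [_to_gray(r) for r in raws]
    shapes = {g.shape for g in grays}
    if len(shapes) > 1:
        raise FormatError(f"frames in {path} differ in size: {sorted(shapes)}")
    return np.stack(grays), dtype


def _read_tiff_stack(path: Path) -> tuple[np.ndarray, np.dtype]:
    raw = tifffile.imread(str(path))
    raw = np.asarray(raw)
    dtype = raw.dtype
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim == 4:  # pages of colour frames
        raw = np.stack([_to_gray(page) for page in raw])
    elif raw.ndim == 3 and raw.shape[-1] in (3, 4) and raw.shape[0] > 4:
        # single colour image, not a stack of narrow frames
        raw = _to_gray(raw)[None]
    return raw.astype(np.float64), dtype


def _read_video(path: Path) -> tuple[np.ndarray, np.dtype, float | None]:
    try:
        import imageio.v3 as iio

        meta = iio.immeta(str(path))
        frames = [_to_gray(f) for f in iio.imiter(str(path))]
    except ImportError as exc:  # missing ffmpeg/pyav backend
        raise FormatError(
            f"no video backend available to read {path}; supply the stack as a "
            "multi-page TIFF or a PNG sequence instead"
        ) from exc
    except Exception as exc:
        raise FormatError(f"could not read video container {path}: {exc}") from exc
    if not frames:
        raise EmptyInputError(f"video {path} holds zero frames")
    fps = meta.get("fps")
    return np.stack(frames), np.dtype(np.uint8), fps


def read_stack(path: str | os.PathLike, fps_override: float | None = None) -> ImageStack:
    """Read AVI/MP4 video, a multi-page TIFF, or a PNG/TIFF frame directory.

    Colour input is collapsed to luminance; bit depths above 8 are rescaled
    linearly onto [0, 255]. Frame order is the container page order, or the
    lexicographic file-name order for a directory of frames.

    ``fps_override`` takes precedence over container metadata; image
    containers carry no frame rate, so for them the override is mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input path does not exist: {path}")
    if fps_override is not None and not fps_override > 0:
        raise ConfigurationError(f"fps_override must be positive, got {fps_override}")

    meta_fps: float | None = None
    if path.is_dir():
        frames, dtype = _read_sequence_dir(path)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        frames, dtype = _read_tiff_stack(path)
    elif path.suffix.lower() in _VIDEO_SUFFIXES:
        frames, dtype, meta_fps = _read_video(path)
    elif path.suffix.lower() == ".png":
        raw = _read_image_file(path)
        dtype = np.asarray(raw).dtype
        frames = _to_gray(raw)[None]
    else:
        raise FormatError(f"unsupported container: {path.suffix!r} ({path})")

    if frames.shape[0] == 0:
        raise EmptyInputError(f"{path} holds zero frames")
    fps = fps_override if fps_override is not None else meta_fps
    if fps is None:
        raise ConfigurationError(
            f"{path} carries no frame-rate metadata; pass fps_override"
        )
    frames = _normalize_depth(frames, dtype)
    return ImageStack(frames=frames, fps=float(fps), source_path=str(path))


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as an 8-bit multi-page TIFF, or a PNG sequence if
    ``path`` is a directory (created on demand)."""
    path = Path(path)
    data = np.clip(np.rint(stack.frames), 0, 255).astype(np.uint8)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(path), data, photometric="minisblack")
        return
    import imageio.v3 as iio

    path.mkdir(parents=True, exist_ok=True)
    ndigits = max(4, len(str(stack.n_frames - 1)))
    for i, frame in enumerate(data):
        iio.imwrite(str(path / f"frame_{i:0{ndigits}d}.png"), frame)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def _columns_frame(per_roi: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One column per embryo, NaN-padded to the longest column."""
    n = max((len(v) for v in per_roi.values()), default=0)
    data = {}
    for roi_id, vals in per_roi.items():
        col = np.full(n, np.nan)
        col[: len(vals)] = np.asarray(list(vals), dtype=float)
        data[roi_id] = col
    return pd.DataFrame(data)


def write_workbook(
    summaries: Sequence["EmbryoSummary"],  # noqa: F821 - see events module
    per_roi_tables: Mapping[str, Mapping[str, Sequence[float]]],
    path: str | os.PathLike,
) -> None:
    """Write the five-sheet results workbook plus per-sheet CSV mirrors.

    ``per_roi_tables`` maps roi_id -> {"tc": maxima frames,
    "intensity": maxima intensities, "interval": interval seconds,
    "duration": duration seconds}. ``summaries`` supplies the Summary sheet
    (one row per embryo). Incalculable entries (None/NaN) become empty cells.

    CSV mirrors are written next to the workbook as ``<stem>_<Sheet>.csv``.
    """
    if not per_roi_tables:
        raise EmptyInputError("write_workbook requires at least one analyzed ROI")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    sheet_key = {"TC": "tc", "Intensity": "intensity",
                 "Interval": "interval", "Duration": "duration"}
    sheets: dict[str, pd.DataFrame] = {
        name: _columns_frame(
            {rid: tables.get(key, []) for rid, tables in per_roi_tables.items()}
        )
        for name, key in sheet_key.items()
    }
    summary_rows = []
    for s in summaries:
        summary_rows.append(
            {
                "roi_id": s.roi_id,
                "frequency": s.tc_frequency,
                "mean_intensity": _nan(s.mean_intensity),
                "mean_interval_s": _nan(s.mean_interval_s),
                "mean_duration_s": _nan(s.mean_duration_s),
            }
        )
    sheets["Summary"] = pd.DataFrame(
        summary_rows,
        columns=["roi_id", "frequency", "mean_intensity",
                 "mean_interval_s", "mean_duration_s"],
    )

    try:
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name in WORKBOOK_SHEETS:
                sheets[name].to_excel(writer, sheet_name=name, index=False)
    except OSError as exc:
        raise OSError(f"cannot write workbook to {path}: {exc}") from exc

    stem = path.with_suffix("")
    for name in WORKBOOK_SHEETS:
        sheets[name].to_csv(f"{stem}_{name}.csv", index=False)


def _nan(value: float | None) -> float:
    return np.nan if value is None else float(value)
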
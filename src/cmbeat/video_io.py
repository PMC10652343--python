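"""Reading and writing the containers the pipeline touches.

A recording enters the pipeline either as a :class:`FrameStack` (grayscale
video of a beating monolayer, from a multi-page TIFF or a directory of
single-frame images) or as an :class:`IntensityTrace` (one fluorescence
intensity sample per frame, e.g. a Fluo-4 recording reduced over a region of
interest). Acquisition timing is always user-supplied: frame-rate metadata
embedded in TIFF containers is too unreliable to infer from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile


class VideoIOError(Exception):
    """Base class for container I/O failures."""


class MissingPathError(VideoIOError):
    """Input path does not exist."""


class EmptyStackError(VideoIOError):
    """No frames found at the input location."""


class FrameDimensionError(VideoIOError):
    """Frames in one recording do not share a single H x W shape."""


class FrameRateError(VideoIOError):
    """Non-positive or non-finite frame rate."""


class ROIError(VideoIOError):
    """Region of interest is empty or extends outside the frame."""


class TraceFormatError(VideoIOError):
    """Trace CSV is malformed (missing columns, non-numeric cells)."""


class TraceOrderError(VideoIOError):
    """Trace sample times are not strictly increasing."""


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class FrameStack:
    """An ordered grayscale video with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape (T, H, W); intensities are held as floats internally
        regardless of the source bit depth.
    frame_rate_hz
        Acquisition rate in frames per second (strictly positive).
    pixel_size_um
        Physical edge length of one pixel in micrometers.
    source_id
        Free-text provenance label.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FrameDimensionError(
                f"frames must be (T, H, W), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise EmptyStackError("a frame stack needs at least 2 frames")
        if not np.isfinite(self.frame_rate_hz) or self.frame_rate_hz <= 0:
            raise FrameRateError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class IntensityTrace:
    """A scalar intensity time series (e.g. mean Fluo-4 signal over an ROI)."""

    times_s: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise TraceFormatError("times_s and values must be 1-D and equal length")
        if self.times_s.size < 2:
            raise TraceFormatError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.times_s) > 0):
            raise TraceOrderError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse a color frame to one channel by the unweighted channel mean."""
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(float)
    if img.ndim == 3 and img.shape[-1] in (2, 3, 4):
        return img.astype(float).mean(axis=-1)
    raise FrameDimensionError(f"cannot interpret frame of shape {img.shape}")


def read_frames(
    path: str | Path,
    frame_rate_hz: float,
    pixel_size_um: float = 1.0,
) -> FrameStack:
    """Read a video as a :class:`FrameStack`.

    ``path`` is either a multi-page TIFF file or a directory of single-frame
    PNG/TIFF images. Directory frames are ordered by lexicographic filename
    sort, so the result is independent of filesystem enumeration order.
    Color frames are averaged across channels.
    """
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such file or directory: {path}")
    if not np.isfinite(frame_rate_hz) or frame_rate_hz <= 0:
        raise FrameRateError(f"frame_rate_hz must be > 0, got {frame_rate_hz}")

    raw_frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise EmptyStackError(f"no image files found in {path}")
        for f in files:
            raw_frames.append(_to_grayscale(iio.imread(f)))
    else:
        # read page by page: tifffile.imread() would silently return only the
        # first series when pages disagree in size, hiding a malformed file
        with tifffile.TiffFile(str(path)) as tif:
            for page in tif.pages:
                arr = np.asarray(page.asarray())
                if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[-1] in (2, 3, 4)):
                    raw_frames.append(_to_grayscale(arr))
                elif arr.ndim == 3:
                    raw_frames.extend(_to_grayscale(p) for p in arr)
                else:
                    raise FrameDimensionError(
                        f"unsupported TIFF page layout {arr.shape}"
                    )

    if len(raw_frames) == 0:
        raise EmptyStackError(f"zero frames read from {path}")
    shape0 = raw_frames[0].shape
    for i, fr in enumerate(raw_frames):
        if fr.shape != shape0:
            raise FrameDimensionError(
                f"frame {i} has shape {fr.shape}, expected {shape0}"
            )
    frames = np.stack(raw_frames).astype(float)
    return FrameStack(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        pixel_size_um=pixel_size_um,
        source_id=str(path),
    )


def trace_from_stack(
    stack: FrameStack,
    roi: tuple[int, int, int, int] | None = None,
) -> IntensityTrace:
    """Reduce a stack to one mean-intensity sample per frame.

    ``roi`` is ``(x, y, w, h)`` with x = column of the left edge and
    y = row of the top edge; ``None`` means the full frame.
    """
    H, W = stack.frame_shape
    if roi is None:
        x, y, w, h = 0, 0, W, H
    else:
        x, y, w, h = roi
    if w <= 0 or h <= 0:
        raise ROIError(f"empty roi {roi}")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ROIError(f"roi {roi} outside frame bounds {H}x{W}")
    values = stack.frames[:, y : y + h, x : x + w].mean(axis=(1, 2))
    return IntensityTrace(
        times_s=stack.frame_times_s(),
        values=values,
        label=stack.source_id,
    )


def read_trace(path: str | Path) -> IntensityTrace:
    """Read a trace CSV with header columns ``time_s,value``."""
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise TraceFormatError(f"{path} missing column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
    values = pd.to_numeric(df["value"], errors="coerce").to_numpy()
    if np.isnan(times).any() or np.isnan(values).any():
        raise TraceFormatError(f"{path} contains non-numeric cells")
    return IntensityTrace(times_s=times, values=values, label=str(path))


def write_trace(trace: IntensityTrace, path: str | Path) -> None:
    """Write a trace as CSV with header ``time_s,value`` (full precision)."""
    df = pd.DataFrame({"time_s": trace.times_s, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.17g")
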
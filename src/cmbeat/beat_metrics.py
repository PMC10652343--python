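"""Beat kinetics from aggregate motion traces and displacement fields.

The four read-outs quantify spontaneous beating of a cardiomyocyte monolayer:

frequency_hz
    Spontaneous beating rate, from the mean inter-beat interval of detected
    motion peaks. Interval-based estimation stays well defined for the few,
    irregular beats seen in aged cells, where an FFT peak would smear.
velocity_um_s
    Mean over detected beats of the aggregate motion speed at the beat peak
    (peak systolic speed, the standard contractility surrogate).
max_displacement_px / _um
    Maximum over frame pairs and valid blocks of the per-frame-pair
    displacement magnitude ("maximum displacement of a pixel in a frame").
beat_area_pct
    Percentage of valid blocks whose displacement amplitude marks them as
    participating in contraction.

Recovery after an insult is expressed by dividing each metric by its
own-sample baseline value (each sample normalized separately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

if TYPE_CHECKING:  # avoid a circular import; fields are duck-typed here
    from .motion_estimation import DisplacementField


class BeatMetricsError(Exception):
    """Base class for beat-metric failures."""


class NoDisplacementDataError(BeatMetricsError):
    """No valid blocks anywhere in the recording."""


@dataclass
class MotionTrace:
    """Scalar motion-speed time series used for beat detection.

    Samples live at frame-pair midpoints; ``n_valid_blocks`` records how many
    blocks contributed to each sample.
    """

    times_s: np.ndarray
    velocity_um_s: np.ndarray
    n_valid_blocks: np.ndarray
    #: conversion factor pixel_size_um * frame_rate_hz (um/s per px/frame-pair);
    #: lets detectors anchor thresholds to the 1 px displacement quantum.
    #: None for traces not derived from block matching.
    um_s_per_px_frame: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.velocity_um_s = np.asarray(self.velocity_um_s, dtype=float)
        self.n_valid_blocks = np.asarray(self.n_valid_blocks, dtype=int)
        if not np.all(np.diff(self.times_s) > 0):
            raise BeatMetricsError("trace times must be strictly increasing")
        if np.any(self.velocity_um_s < 0):
            raise BeatMetricsError("motion speeds must be non-negative")


@dataclass(frozen=True)
class BeatDetectionParams:
    """Peak-detection thresholds shared by beat and transient detection.

    prominence_frac
        Required peak prominence as a fraction of the trace's dynamic range
        (maximum minus 5th percentile). Referencing the maximum rather than a
        high percentile keeps the threshold meaningful for slow beaters,
        where beats occupy well under 5% of the samples and any percentile
        span would only measure the inter-beat noise floor.
    min_interbeat_s
        Refractory interval: of two candidate peaks closer than this, the
        earlier one is retained. Merges the contraction/relaxation speed-peak
        pair of a single beat into one event.
    area_amp_frac
        Per-block amplitude threshold for the beat area, as a fraction of the
        largest per-block amplitude on the grid.
    min_peak_px_per_frame
        Absolute beat-peak floor in mean displacement per frame pair
        (pixels). Block displacements are integer, so stray single-block
        mismatches on a non-beating monolayer produce trace values of order
        1/n_blocks px; a genuine beat displaces a visible fraction of the
        grid at once. Applied only to traces that carry the px-to-um/s
        conversion (i.e. came from block matching), and always against the
        raw (unsmoothed) peak height.
    smooth_s
        Boxcar window (seconds) applied to the motion trace before peak
        finding in :func:`detect_beats`. Block-matching noise is uncorrelated
        between frame pairs while a beat's speed pulse spans many samples, so
        modest smoothing suppresses spurious prominences at low SNR. Each
        smoothed peak is refined back to the raw-trace maximum inside the
        window, so reported beat times and heights come from the raw trace.
        Set to 0 to disable.
    height_consistency_frac
        Second-pass filter on beat candidates: each candidate's raw height
        must reach this fraction of the median candidate height above the
        trace's 5th-percentile baseline. Genuine beats of one recording have
        similar peak speeds while spurious noise prominences sit near the
        baseline, and as long as spurious candidates are a minority the
        median is anchored to the true beats. Set to 0 to disable.
    """

    prominence_frac: float = 0.3
    min_interbeat_s: float = 0.25
    area_amp_frac: float = 0.2
    min_peak_px_per_frame: float = 0.05
    smooth_s: float = 0.25
    height_consistency_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.prominence_frac <= 1):
            raise ValueError("prominence_frac must be in (0, 1]")
        if self.min_interbeat_s <= 0:
            raise ValueError("min_interbeat_s must be > 0")
        if not (0 < self.area_amp_frac <= 1):
            raise ValueError("area_amp_frac must be in (0, 1]")
        if self.min_peak_px_per_frame < 0:
            raise ValueError("min_peak_px_per_frame must be >= 0")
        if self.smooth_s < 0:
            raise ValueError("smooth_s must be >= 0")
        if not (0 <= self.height_consistency_frac <= 1):
            raise ValueError("height_consistency_frac must be in [0, 1]")


@dataclass
class BeatMetrics:
    """Per-recording beating read-outs."""

    frequency_hz: float
    velocity_um_s: float
    max_displacement_px: float
    max_displacement_um: float
    beat_area_pct: float
    n_beats: int
    is_beating: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _smoothing_width(times_s: np.ndarray, smooth_s: float) -> int:
    """Odd boxcar width (in samples) covering ``smooth_s`` seconds."""
    dt = float(np.median(np.diff(times_s)))
    if dt <= 0 or smooth_s <= 0:
        return 1
    return max(1, int(round(smooth_s / dt)) | 1)


def detect_beats(trace: MotionTrace, params: BeatDetectionParams | None = None) -> np.ndarray:
    """Detect beat events as prominent local maxima of the motion trace.

    The trace is boxcar-smoothed over ``smooth_s`` seconds and a peak
    qualifies if its prominence on the smoothed trace reaches
    ``prominence_frac`` times the smoothed trace's dynamic range (max minus
    5th percentile). Each qualifying peak is refined to the raw-trace maximum
    within half a smoothing window, and for block-matching traces that raw
    height must clear the absolute floor ``min_peak_px_per_frame``. A second
    pass drops candidates whose raw height falls below
    ``height_consistency_frac`` of the median candidate height above the
    trace's 5th-percentile baseline. Surviving
    peaks are swept in time order and any peak closer than ``min_interbeat_s``
    to the last kept one is dropped, so of two near-coincident peaks the
    earlier survives (ties inside one smoothing window also resolve to the
    earlier raw sample).

    Returns the beat times in seconds (empty for flat traces).
    """
    if params is None:
        params = BeatDetectionParams()
    v = trace.velocity_um_s
    n = v.size
    if n < 3:
        return np.array([])
    width = _smoothing_width(trace.times_s, params.smooth_s)
    # "mirror" padding keeps edge values consistent with the interior; with
    # "nearest", a single large boundary sample would be replicated across
    # half a window and distort the global dynamic range
    s = uniform_filter1d(v, size=width, mode="mirror") if width > 1 else v
    span = float(s.max() - np.percentile(s, 5))
    if span <= 0:
        return np.array([])
    idx, _ = find_peaks(s, prominence=params.prominence_frac * span)
    floor = None
    if trace.um_s_per_px_frame is not None:
        floor = params.min_peak_px_per_frame * trace.um_s_per_px_frame
    half = width // 2
    refined: list[int] = []
    for i in idx:
        lo = max(0, i - half)
        j = lo + int(np.argmax(v[lo : min(n, i + half + 1)]))
        if floor is not None and v[j] < floor:
            continue
        if not refined or j != refined[-1]:
            refined.append(j)
    if refined and params.height_consistency_frac > 0:
        base = float(np.percentile(v, 5))
        cut = base + params.height_consistency_frac * (
            float(np.median(v[np.asarray(refined)])) - base
        )
        refined = [j for j in refined if v[j] >= cut]
    kept_times: list[float] = []
    for j in sorted(refined):
        t = trace.times_s[j]
        if not kept_times or t - kept_times[-1] >= params.min_interbeat_s:
            kept_times.append(t)
    return np.array(kept_times)


def beating_frequency(beat_times: np.ndarray, recording_duration_s: float) -> float:
    """Beating frequency from the mean inter-beat interval.

    With n >= 2 beats the frequency is (n - 1) / (t_last - t_first); a single
    peak cannot define a period, so n <= 1 reports 0 Hz (not beating).
    """
    if recording_duration_s <= 0:
        raise BeatMetricsError("recording duration must be > 0")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        return 0.0
    return float((beat_times.size - 1) / (beat_times[-1] - beat_times[0]))


def beating_velocity(trace: MotionTrace, beat_times: np.ndarray) -> float:
    """Mean over detected beats of the motion speed at the beat peak (um/s)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        return 0.0
    idx = np.searchsorted(trace.times_s, beat_times)
    idx = np.clip(idx, 0, trace.times_s.size - 1)
    # beat times are trace sample times; guard against float round-off
    left = np.clip(idx - 1, 0, trace.times_s.size - 1)
    use_left = np.abs(trace.times_s[left] - beat_times) < np.abs(
        trace.times_s[idx] - beat_times
    )
    idx = np.where(use_left, left, idx)
    return float(trace.velocity_um_s[idx].mean())


def max_displacement(
    fields: list["DisplacementField"], pixel_size_um: float = 1.0
) -> tuple[float, float]:
    """Maximum displacement magnitude over all frame pairs and valid blocks.

    Returns (pixels, micrometers).
    """
    best = -np.inf
    any_valid = False
    for f in fields:
        if f.valid_mask.any():
            any_valid = True
            best = max(best, float(f.magnitudes()[f.valid_mask].max()))
    if not any_valid:
        raise NoDisplacementDataError("no valid blocks in any frame pair")
    return best, best * pixel_size_um


def _block_amplitudes(fields: list["DisplacementField"]) -> tuple[np.ndarray, np.ndarray]:
    """Per-block peak displacement magnitude over time, and an ever-valid mask."""
    shape = fields[0].valid_mask.shape
    amp = np.zeros(shape)
    ever_valid = np.zeros(shape, dtype=bool)
    for f in fields:
        mags = f.magnitudes()
        sel = f.valid_mask
        amp[sel] = np.maximum(amp[sel], mags[sel])
        ever_valid |= sel
    return amp, ever_valid


def beat_area(
    fields: list["DisplacementField"], params: BeatDetectionParams | None = None
) -> float:
    """Percentage of valid blocks classified as beating.

    A block beats if its displacement amplitude (max magnitude over time)
    reaches ``area_amp_frac`` times the largest per-block amplitude on the
    grid. If nothing moves anywhere the beat area is 0%.
    """
    if params is None:
        params = BeatDetectionParams()
    amp, ever_valid = _block_amplitudes(fields)
    if not ever_valid.any():
        raise NoDisplacementDataError("no valid blocks in any frame pair")
    amps = amp[ever_valid]
    max_amp = amps.max()
    if max_amp <= 0:
        return 0.0
    beating = amps >= params.area_amp_frac * max_amp
    return float(100.0 * beating.sum() / amps.size)


def compute_beat_metrics(
    trace: MotionTrace,
    fields: list["DisplacementField"],
    pixel_size_um: float = 1.0,
    params: BeatDetectionParams | None = None,
) -> BeatMetrics:
    """Assemble all beating read-outs for one recording."""
    if params is None:
        params = BeatDetectionParams()
    beat_times = detect_beats(trace, params)
    duration = float(trace.times_s[-1] - trace.times_s[0]) or 1.0
    freq = beating_frequency(beat_times, duration)
    disp_px, disp_um = max_displacement(fields, pixel_size_um)
    return BeatMetrics(
        frequency_hz=freq,
        velocity_um_s=beating_velocity(trace, beat_times),
        max_displacement_px=disp_px,
        max_displacement_um=disp_um,
        beat_area_pct=beat_area(fields, params),
        n_beats=int(beat_times.size),
        is_beating=beat_times.size >= 2,
    )


#: metrics that are normalized to a pre-insult baseline
_RATIO_KEYS = (
    "frequency_hz",
    "velocity_um_s",
    "max_displacement_px",
    "max_displacement_um",
    "beat_area_pct",
)


def normalize_to_baseline(
    metrics_t: BeatMetrics, metrics_baseline: BeatMetrics
) -> dict[str, float | None]:
    """Divide each metric by its own-sample baseline value.

    The baseline recording normalizes to exactly 1.0. A zero baseline leaves
    that ratio undefined (``None``), never infinity.
    """
    out: dict[str, float | None] = {}
    t = metrics_t.to_dict()
    b = metrics_baseline.to_dict()
    for key in _RATIO_KEYS:
        base = b[key]
        if base is None or base <= 0 or not math.isfinite(base):
            out[key] = None
        else:
            out[key] = t[key] / base
    return out
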
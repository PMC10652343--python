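"""Synthetic beating videos and calcium traces with known ground truth.

Real recordings of spontaneously beating cardiomyocyte monolayers are rarely
redistributable, so every stage of this pipeline is validated against
simulated data instead. The video generator renders a textured monolayer
displaced by a spatially enveloped, periodic contraction-relaxation motion
field; the trace generator renders Fluo-4-like calcium transients with a
linear upstroke and exponential decay. Both echo back exactly what they
applied (beat times, per-frame pulse values, transient onsets), so estimators
can be scored against the truth.

The motion waveform of one beat is a raised-cosine pulse: displacement rises
from zero to the peak amplitude and returns to zero, giving one
contraction/relaxation speed-peak pair per beat, as in real monolayer
recordings. Inter-beat intervals are drawn with a configurable coefficient of
variation; everything is reproducible from the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .video_io import FrameStack, IntensityTrace


class SyntheticDataError(Exception):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SyntheticVideoConfig:
    """Configuration of a simulated brightfield beating video.

    frequency_hz
        Target beating rate; beat times are drawn around period 1/f.
    amplitude_px
        Peak displacement of the motion field at the envelope maximum.
    envelope
        Spatial weighting of the motion: "gaussian" (centered bump of width
        ``envelope_sigma_px``, mimicking a focal contracting region) or
        "uniform".
    texture_grain_px
        Correlation length of the random monolayer texture.
    texture_contrast
        Standard deviation of the texture intensities; with ``noise_sd`` this
        sets the SNR (defaults give SNR = 10).
    irregularity
        Coefficient of variation of inter-beat intervals (0 = periodic).
    pulse_width_s
        Duration of the raised-cosine contraction-relaxation pulse.
    """

    frequency_hz: float = 0.5
    amplitude_px: float = 3.0
    duration_s: float = 30.0
    frame_rate_hz: float = 30.0
    frame_size: tuple[int, int] = (256, 256)
    envelope: str = "gaussian"
    envelope_sigma_px: float | None = None
    texture_grain_px: float = 8.0
    texture_contrast: float = 25.0
    texture_mean: float = 128.0
    noise_sd: float = 2.5
    irregularity: float = 0.05
    pulse_width_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.frame_size
        if self.frequency_hz <= 0:
            raise SyntheticDataError("frequency_hz must be > 0")
        if self.amplitude_px < 0:
            raise SyntheticDataError("amplitude_px must be >= 0")
        if self.duration_s * self.frame_rate_hz < 3:
            raise SyntheticDataError("need at least 3 frames")
        if self.amplitude_px > min(H, W) / 4:
            raise SyntheticDataError(
                f"amplitude {self.amplitude_px} px too large for frame {H}x{W}"
            )
        if self.envelope not in ("gaussian", "uniform"):
            raise SyntheticDataError(f"unknown envelope {self.envelope!r}")
        if self.irregularity < 0:
            raise SyntheticDataError("irregularity must be >= 0")
        if self.pulse_width_s >= 1.0 / self.frequency_hz:
            raise SyntheticDataError("pulse_width_s must be below the beat period")


@dataclass(frozen=True)
class SyntheticTraceConfig:
    """Configuration of a simulated Fluo-4 calcium-intensity trace.

    Each transient rises linearly for ``ttp_s`` to ``amplitude_dff`` above
    baseline and then decays exponentially with time constant
    ``decay_tau_s``. Defaults emulate a 30 s recording sampled at ~33 Hz
    (30 ms exposure). Transients must resolve between beats:
    ttp_s + 3 * decay_tau_s < 1 / frequency_hz.
    """

    frequency_hz: float = 0.5
    ttp_s: float = 0.3
    decay_tau_s: float = 0.4
    amplitude_dff: float = 2.0
    baseline_f0: float = 100.0
    noise_sd: float = 2.0
    irregularity: float = 0.05
    duration_s: float = 30.0
    sample_rate_hz: float = 100.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0 or self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise SyntheticDataError("rates and duration must be > 0")
        if self.ttp_s <= 0 or self.decay_tau_s <= 0 or self.amplitude_dff <= 0:
            raise SyntheticDataError("transient shape parameters must be > 0")
        if self.baseline_f0 <= 0:
            raise SyntheticDataError("baseline_f0 must be > 0")
        if self.ttp_s + 3 * self.decay_tau_s >= 1.0 / self.frequency_hz:
            raise SyntheticDataError(
                "transients overlap: require ttp_s + 3*decay_tau_s < 1/frequency_hz"
            )


@dataclass
class SyntheticGroundTruth:
    """Exactly what the generator applied, for scoring estimators.

    beat_times_s
        Centers at which a pulse/transient was applied (one per beat).
    pulse
        Video only: the scalar waveform value p(t) in [0, 1] per frame; the
        displacement applied at frame t and pixel (y, x) is
        ``amplitude_px * pulse[t] * envelope[y, x] * direction``.
    envelope, direction
        Video only: spatial weighting grid and unit motion direction (dx, dy).
    onset_times_s, peak_times_s, ttp_from_10pct_s
        Trace only: transient onsets/peaks, and the rise time measured from
        the 10%-amplitude level to the peak — the quantity a 10%-threshold
        onset detector estimates (0.9 * ttp_s for the linear upstroke).
    """

    config: object
    beat_times_s: np.ndarray
    pulse: np.ndarray | None = None
    envelope: np.ndarray | None = None
    direction: np.ndarray | None = None
    onset_times_s: np.ndarray | None = None
    peak_times_s: np.ndarray | None = None
    ttp_from_10pct_s: float | None = None

    @property
    def n_beats(self) -> int:
        return int(self.beat_times_s.size)

    @property
    def realized_frequency_hz(self) -> float:
        """Frequency implied by the realized beat times ((n-1)/span)."""
        b = self.beat_times_s
        if b.size < 2:
            return 0.0
        return float((b.size - 1) / (b[-1] - b[0]))

    def displacement_field(self, frame_index: int) -> np.ndarray:
        """Materialize the (H, W, 2) displacement applied at one video frame."""
        if self.pulse is None or self.envelope is None or self.direction is None:
            raise SyntheticDataError("not a video ground truth")
        cfg = self.config
        scale = cfg.amplitude_px * self.pulse[frame_index]
        return scale * self.envelope[..., None] * self.direction[None, None, :]

    def to_jsonable(self) -> dict:
        """A JSON-serializable summary (large grids omitted)."""
        out: dict = {"config": asdict(self.config)}
        out["beat_times_s"] = [float(t) for t in self.beat_times_s]
        if self.direction is not None:
            out["direction"] = [float(v) for v in self.direction]
        if self.onset_times_s is not None:
            out["onset_times_s"] = [float(t) for t in self.onset_times_s]
        if self.peak_times_s is not None:
            out["peak_times_s"] = [float(t) for t in self.peak_times_s]
        if self.ttp_from_10pct_s is not None:
            out["ttp_from_10pct_s"] = float(self.ttp_from_10pct_s)
        return out


def derive_seed(master_seed: int, *labels: object) -> int:
    """Deterministic, platform-stable per-sample seed below 2**31."""
    key = ":".join([str(master_seed), *map(str, labels)]).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _draw_beat_times(
    rng: np.random.Generator,
    frequency_hz: float,
    duration_s: float,
    irregularity: float,
    min_interval_s: float,
) -> np.ndarray:
    """Beat centers with inter-beat CV = irregularity, first beat at T/2."""
    period = 1.0 / frequency_hz
    beats = [0.5 * period]
    while True:
        if irregularity == 0:
            interval = period
        else:
            interval = rng.normal(period, irregularity * period)
        interval = max(interval, min_interval_s)
        t = beats[-1] + interval
        if t >= duration_s:
            break
        beats.append(t)
    return np.array(beats)


def _make_texture(rng: np.random.Generator, cfg: SyntheticVideoConfig) -> np.ndarray:
    H, W = cfg.frame_size
    white = rng.standard_normal((H, W))
    smooth = gaussian_filter(white, sigma=cfg.texture_grain_px / 2.0, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        raise SyntheticDataError("degenerate texture")
    return cfg.texture_mean + cfg.texture_contrast * (smooth - smooth.mean()) / sd


def _make_envelope(cfg: SyntheticVideoConfig) -> np.ndarray:
    H, W = cfg.frame_size
    if cfg.envelope == "uniform":
        return np.ones((H, W))
    sigma = cfg.envelope_sigma_px or min(H, W) / 4.0
    yy, xx = np.mgrid[0:H, 0:W]
    r2 = (yy - (H - 1) / 2.0) ** 2 + (xx - (W - 1) / 2.0) ** 2
    return np.exp(-r2 / (2.0 * sigma**2))


def _pulse_train(
    times: np.ndarray, beat_times: np.ndarray, pulse_width_s: float
) -> np.ndarray:
    """Raised-cosine contraction-relaxation waveform, one pulse per beat."""
    p = np.zeros_like(times)
    for b in beat_times:
        u = (times - b) / pulse_width_s
        mask = (u >= 0) & (u <= 1)
        p[mask] += 0.5 * (1.0 - np.cos(2.0 * np.pi * u[mask]))
    return p


def generate_beating_video(
    config: SyntheticVideoConfig,
) -> tuple[FrameStack, SyntheticGroundTruth]:
    """Render a beating-monolayer video and its ground truth.

    Frame t shows the seeded base texture inverse-warped (bilinear) by the
    displacement ``amplitude * pulse(t) * envelope(y, x) * direction``, with
    Gaussian pixel noise added last. Bit-identical for identical configs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.frame_size
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))

    texture = _make_texture(rng, cfg)
    envelope = _make_envelope(cfg)
    theta = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(theta), np.sin(theta)])  # (dx, dy)

    beat_times = _draw_beat_times(
        rng,
        cfg.frequency_hz,
        cfg.duration_s,
        cfg.irregularity,
        min_interval_s=1.05 * cfg.pulse_width_s,
    )
    frame_times = np.arange(n_frames) / cfg.frame_rate_hz
    pulse = _pulse_train(frame_times, beat_times, cfg.pulse_width_s)

    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    frames = np.empty((n_frames, H, W), dtype=np.float32)
    for t in range(n_frames):
        scale = cfg.amplitude_px * pulse[t]
        if scale == 0.0:
            warped = texture
        else:
            # content displaced by +d: frame(x) = texture(x - d(x))
            coord_r = rows - scale * direction[1] * envelope
            coord_c = cols - scale * direction[0] * envelope
            warped = map_coordinates(
                texture, [coord_r, coord_c], order=1, mode="reflect"
            )
        if cfg.noise_sd > 0:
            warped = warped + rng.normal(0.0, cfg.noise_sd, size=(H, W))
        frames[t] = warped

    stack = FrameStack(
        frames=frames,
        frame_rate_hz=cfg.frame_rate_hz,
        pixel_size_um=1.0,
        source_id=f"synthetic-video-seed{cfg.seed}",
    )
    truth = SyntheticGroundTruth(
        config=cfg,
        beat_times_s=beat_times,
        pulse=pulse,
        envelope=envelope,
        direction=direction,
    )
    return stack, truth


def generate_calcium_trace(
    config: SyntheticTraceConfig,
) -> tuple[IntensityTrace, SyntheticGroundTruth]:
    """Render a raw-fluorescence calcium trace and its ground truth.

    dF/F0 rises linearly from each onset to ``amplitude_dff`` over ``ttp_s``,
    then decays as exp(-(t - peak)/decay_tau_s); the raw signal is
    F = f0 * (1 + dff) plus Gaussian noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    times = np.arange(n) / cfg.sample_rate_hz

    min_interval = 1.02 * (cfg.ttp_s + 3.0 * cfg.decay_tau_s)
    onsets = _draw_beat_times(
        rng, cfg.frequency_hz, cfg.duration_s, cfg.irregularity, min_interval
    )
    dff = np.zeros(n)
    for onset in onsets:
        peak = onset + cfg.ttp_s
        rise = (times >= onset) & (times < peak)
        dff[rise] += cfg.amplitude_dff * (times[rise] - onset) / cfg.ttp_s
        decay = times >= peak
        dff[decay] += cfg.amplitude_dff * np.exp(-(times[decay] - peak) / cfg.decay_tau_s)

    raw = cfg.baseline_f0 * (1.0 + dff)
    if cfg.noise_sd > 0:
        raw = raw + rng.normal(0.0, cfg.noise_sd, size=n)

    trace = IntensityTrace(
        times_s=times, values=raw, label=f"synthetic-trace-seed{cfg.seed}"
    )
    truth = SyntheticGroundTruth(
        config=cfg,
        beat_times_s=onsets,
        onset_times_s=onsets,
        peak_times_s=onsets + cfg.ttp_s,
        ttp_from_10pct_s=0.9 * cfg.ttp_s,
    )
    return trace, truth


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of a simulated batch."""

    label: str
    config: SyntheticVideoConfig | SyntheticTraceConfig
    n_samples: int


def generate_group_dataset(
    group_specs: Sequence[GroupSpec], master_seed: int = 0
) -> tuple[list[dict], pd.DataFrame]:
    """Generate a multi-group batch of recordings with a ground-truth table.

    Per-sample seeds are derived deterministically from the master seed,
    group label and sample index, so a batch is reproducible regardless of
    generation order. Returns the recordings (dicts with keys ``sample_id``,
    ``group``, ``kind``, ``recording``, ``truth``) and a manifest DataFrame
    (sample_id, group, kind, seed, true_frequency_hz, n_beats).
    """
    labels = [g.label for g in group_specs]
    if len(set(labels)) != len(labels):
        raise SyntheticDataError(f"duplicate group labels in {labels}")
    recordings: list[dict] = []
    rows: list[dict] = []
    for spec in group_specs:
        if spec.n_samples < 1:
            raise SyntheticDataError("n_samples must be >= 1")
        for i in range(spec.n_samples):
            seed = derive_seed(master_seed, spec.label, i)
            cfg = type(spec.config)(**{**asdict(spec.config), "seed": seed})
            if isinstance(cfg, SyntheticVideoConfig):
                rec, truth = generate_beating_video(cfg)
                kind = "video"
            else:
                rec, truth = generate_calcium_trace(cfg)
                kind = "trace"
            sample_id = f"{spec.label}_{i:02d}"
            recordings.append(
                {
                    "sample_id": sample_id,
                    "group": spec.label,
                    "kind": kind,
                    "recording": rec,
                    "truth": truth,
                }
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": spec.label,
                    "kind": kind,
                    "seed": seed,
                    "true_frequency_hz": cfg.frequency_hz,
                    "n_beats": truth.n_beats,
                }
            )
    return recordings, pd.DataFrame(rows)
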
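"""Calcium-transient kinetics from Fluo-4 intensity traces.

Raw fluorescence is first normalized to dF/F0 against a percentile baseline.
Transients are detected with the same prominence/refractory peak rule used
for motion beats; each event gets an onset (last sample at or below 10% of
the transient's amplitude above its local baseline), a peak, and an
amplitude. Per transient the module measures

ttp_s
    time from onset to peak (surrogate for the calcium release rate),
apd50_s / apd90_s
    durations from the peak to 50% / 90% decay of the amplitude, with the
    crossing located by linear interpolation between bracketing samples
    (these calcium-transient durations carry the conventional "action
    potential duration" labels),
triangulation
    the APD90/APD50 ratio, a decay-shape descriptor that is >= 1 for any
    monotone decay and ln(10)/ln(2) ~ 3.32 for a pure exponential.

Recording-level features are medians across transients, which stay robust to
the inconsistent peak intensity and duration seen in aged cells. A transient
that is truncated before reaching its 90% decay is excluded from APD90 and
triangulation with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .beat_metrics import BeatDetectionParams, beating_frequency
from .video_io import IntensityTrace

logger = logging.getLogger(__name__)

#: onset threshold as a fraction of transient amplitude above local baseline
ONSET_AMP_FRAC = 0.1


class CalciumError(Exception):
    """Base class for calcium-analysis failures."""


class BaselineError(CalciumError):
    """Baseline fluorescence F0 is not strictly positive."""


@dataclass
class NormalizedTrace:
    """A dF/F0 trace with the baseline it was normalized against."""

    times_s: np.ndarray
    dff: np.ndarray
    f0: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.f0 <= 0:
            raise BaselineError(f"f0 must be > 0, got {self.f0}")


@dataclass
class TransientEvent:
    """One detected calcium transient."""

    onset_index: int
    peak_index: int
    onset_time_s: float
    peak_time_s: float
    amplitude: float


@dataclass
class TransientFeatures:
    """Per-recording calcium kinetics (medians across transients)."""

    frequency_hz: float
    ttp_s: float | None
    apd50_s: float | None
    apd90_s: float | None
    triangulation: float | None
    n_transients: int
    per_transient_table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "ttp_s": self.ttp_s,
            "apd50_s": self.apd50_s,
            "apd90_s": self.apd90_s,
            "triangulation": self.triangulation,
            "n_transients": self.n_transients,
        }


def normalize_dff(trace: IntensityTrace, baseline_percentile: float = 10.0) -> NormalizedTrace:
    """Normalize raw fluorescence to dF/F0.

    F0 is the given percentile of the raw values (default 10th, a robust
    quiescent-baseline estimate); dF/F0 = (F - F0) / F0.
    """
    values = np.asarray(trace.values, dtype=float)
    f0 = float(np.percentile(values, baseline_percentile))
    if f0 <= 0:
        raise BaselineError(
            f"baseline percentile {baseline_percentile} gives non-positive F0 = {f0}"
        )
    return NormalizedTrace(times_s=trace.times_s, dff=(values - f0) / f0, f0=f0)


def detect_transients(
    norm: NormalizedTrace, params: BeatDetectionParams | None = None
) -> list[TransientEvent]:
    """Detect calcium transients on a dF/F0 trace.

    Peaks follow the same prominence (fraction of the trace's dynamic range,
    max minus 5th percentile) and refractory rule as motion-beat detection,
    so slow beaters with sparse transients stay detectable. The onset is the
    last
    sample before the peak at or below ``ONSET_AMP_FRAC`` of the transient's
    amplitude above its local baseline (the dF/F0 minimum since the previous
    peak); the amplitude is dff(peak) - dff(onset). The reported onset *time*
    linearly interpolates the threshold crossing between that sample and the
    next, exactly as the APD decay crossings are interpolated.
    """
    if params is None:
        params = BeatDetectionParams()
    dff = norm.dff
    if dff.size < 5:
        raise CalciumError("trace too short for transient detection")
    span = float(dff.max() - np.percentile(dff, 5))
    if span <= 0:
        return []
    idx, _ = find_peaks(dff, prominence=params.prominence_frac * span)
    kept: list[int] = []
    for i in idx:
        if not kept or norm.times_s[i] - norm.times_s[kept[-1]] >= params.min_interbeat_s:
            kept.append(int(i))

    events: list[TransientEvent] = []
    for j, peak in enumerate(kept):
        start = kept[j - 1] if j > 0 else 0
        local_base = float(dff[start:peak + 1].min())
        amp0 = float(dff[peak]) - local_base
        if amp0 <= 0:
            continue
        threshold = local_base + ONSET_AMP_FRAC * amp0
        below = np.nonzero(dff[start:peak] <= threshold)[0]
        onset = start + int(below[-1]) if below.size else start
        # sub-sample onset: linearly interpolate the 10%-level crossing
        # between the onset sample and the next one (mirrors the interpolated
        # APD crossings; removes a one-sample quantization bias from ttp)
        onset_time = float(norm.times_s[onset])
        if onset + 1 <= peak and dff[onset + 1] > dff[onset]:
            t0, t1 = norm.times_s[onset], norm.times_s[onset + 1]
            v0, v1 = dff[onset], dff[onset + 1]
            if v1 > threshold >= v0:
                onset_time = float(t0 + (t1 - t0) * (threshold - v0) / (v1 - v0))
        events.append(
            TransientEvent(
                onset_index=onset,
                peak_index=peak,
                onset_time_s=onset_time,
                peak_time_s=float(norm.times_s[peak]),
                amplitude=float(dff[peak] - dff[onset]),
            )
        )
    return events


def _decay_crossing(
    norm: NormalizedTrace, peak: int, stop: int, level: float
) -> float | None:
    """First time after ``peak`` where dff falls to ``level``.

    Linearly interpolated between the bracketing samples; ``None`` when the
    trace is truncated (or the next transient starts) before the crossing.
    """
    dff = norm.dff
    for i in range(peak + 1, stop):
        if dff[i] <= level:
            t0, t1 = norm.times_s[i - 1], norm.times_s[i]
            v0, v1 = dff[i - 1], dff[i]
            if v0 == v1:
                return float(t1)
            return float(t0 + (t1 - t0) * (v0 - level) / (v0 - v1))
    return None


def transient_features(
    norm: NormalizedTrace, events: list[TransientEvent]
) -> TransientFeatures:
    """Measure per-transient kinetics and summarize them as medians.

    APD50/APD90 are decay-referenced: the duration from the transient peak to
    the first crossing of peak - 0.5 (resp. 0.9) x amplitude, searched up to
    the next transient's onset.
    """
    if not events:
        raise CalciumError("need at least one transient for kinetic features")
    rows: list[dict] = []
    for j, ev in enumerate(events):
        stop = events[j + 1].onset_index + 1 if j + 1 < len(events) else norm.dff.size
        peak_val = norm.dff[ev.peak_index]
        apd50 = _decay_crossing(norm, ev.peak_index, stop, peak_val - 0.5 * ev.amplitude)
        apd90 = _decay_crossing(norm, ev.peak_index, stop, peak_val - 0.9 * ev.amplitude)
        if apd90 is None:
            logger.warning(
                "transient at t=%.3f s truncated before 90%% decay; "
                "excluded from apd90/triangulation",
                ev.peak_time_s,
            )
        rows.append(
            {
                "onset_time_s": ev.onset_time_s,
                "peak_time_s": ev.peak_time_s,
                "amplitude": ev.amplitude,
                "ttp_s": ev.peak_time_s - ev.onset_time_s,
                "apd50_s": None if apd50 is None else apd50 - ev.peak_time_s,
                "apd90_s": None if apd90 is None else apd90 - ev.peak_time_s,
            }
        )
    table = pd.DataFrame(rows)
    table["triangulation"] = table["apd90_s"] / table["apd50_s"]

    peak_times = np.array([ev.peak_time_s for ev in events])
    duration = float(norm.times_s[-1] - norm.times_s[0])
    freq = beating_frequency(peak_times, duration)

    def _median(col: str) -> float | None:
        vals = table[col].dropna()
        return float(vals.median()) if len(vals) else None

    return TransientFeatures(
        frequency_hz=freq,
        ttp_s=_median("ttp_s"),
        apd50_s=_median("apd50_s"),
        apd90_s=_median("apd90_s"),
        triangulation=_median("triangulation"),
        n_transients=len(events),
        per_transient_table=table,
    )


def analyze_calcium_trace(
    trace: IntensityTrace,
    params: BeatDetectionParams | None = None,
    baseline_percentile: float = 10.0,
) -> TransientFeatures:
    """Normalize, detect and measure in one call."""
    norm = normalize_dff(trace, baseline_percentile)
    events = detect_transients(norm, params)
    return transient_features(norm, events)


#: features reported in a pre/post drug comparison
_DRUG_FEATURES = ("frequency_hz", "ttp_s", "apd50_s", "apd90_s", "triangulation")


def compare_drug_response(
    pre: TransientFeatures,
    post: TransientFeatures,
    responder_freq_frac: float = 0.10,
) -> dict:
    """Paired pre/post drug deltas for one sample.

    Per feature: absolute and percent change (post - pre); a feature missing
    on either side (e.g. APD90 of truncated transients) leaves that delta
    undefined. The sample is flagged a responder when the beating frequency
    increases by more than ``responder_freq_frac`` (chronotropic response,
    e.g. to isoproterenol).
    """
    pre_d, post_d = pre.to_dict(), post.to_dict()
    deltas: dict[str, dict] = {}
    for key in _DRUG_FEATURES:
        a, b = pre_d.get(key), post_d.get(key)
        if a is None or b is None:
            deltas[key] = {"pre": a, "post": b, "delta": None, "pct_change": None}
        else:
            deltas[key] = {
                "pre": a,
                "post": b,
                "delta": b - a,
                "pct_change": 100.0 * (b - a) / a if a != 0 else None,
            }
    freq = deltas["frequency_hz"]
    responder = (
        freq["pct_change"] is not None
        and freq["pct_change"] > 100.0 * responder_freq_frac
    )
    return {"features": deltas, "responder": bool(responder)}
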
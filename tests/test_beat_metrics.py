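import numpy as np
import pytest

from cmbeat.beat_metrics import (
    BeatDetectionParams,
    BeatMetrics,
    MotionTrace,
    NoDisplacementDataError,
    beat_area,
    beating_frequency,
    beating_velocity,
    compute_beat_metrics,
    detect_beats,
    max_displacement,
    normalize_to_baseline,
)
from cmbeat.motion_estimation import (
    BlockMatchParams,
    DisplacementField,
    compute_fields,
    motion_magnitude_trace,
)
from cmbeat.synthetic_data import SyntheticVideoConfig, generate_beating_video


def make_trace(values, fs=30.0, um_s_per_px_frame=None):
    values = np.asarray(values, dtype=float)
    return MotionTrace(
        times_s=np.arange(values.size) / fs,
        velocity_um_s=values,
        n_valid_blocks=np.ones(values.size, int),
        um_s_per_px_frame=um_s_per_px_frame,
    )


def make_field(vectors, valid=None, k=0):
    vectors = np.asarray(vectors, dtype=int)
    mask = np.ones(vectors.shape[:2], bool) if valid is None else np.asarray(valid, bool)
    return DisplacementField(k, vectors, mask)


class TestDetectBeats:
    def test_flat_trace_empty(self):
        assert detect_beats(make_trace(np.zeros(100))).size == 0

    def test_rectified_sinusoid_20_peaks(self):
        t = np.arange(600) / 30.0  # 20 s at 30 Hz
        trace = make_trace(np.abs(np.sin(2 * np.pi * 0.5 * t)))
        beats = detect_beats(trace)
        assert beats.size == 20
        np.testing.assert_allclose(np.diff(beats), 1.0, atol=0.05)

    def test_refractory_keeps_earlier_peak(self):
        v = np.zeros(300)
        v[100] = 5.0
        v[103] = 5.0  # 0.1 s later at 30 Hz
        beats = detect_beats(make_trace(v), BeatDetectionParams(min_interbeat_s=0.25))
        assert beats.size == 1
        assert beats[0] == pytest.approx(100 / 30.0)

    def test_short_trace_empty(self):
        assert detect_beats(make_trace([0.0, 1.0])).size == 0

    def test_absolute_floor_applies_to_block_matching_traces(self):
        # sub-floor peaks on a trace carrying the px conversion are rejected ...
        v = np.zeros(300)
        v[::30] = 0.5  # 0.5 um/s peaks, floor = 0.05 px/frame * 30 um/s/px = 1.5
        assert detect_beats(make_trace(v, um_s_per_px_frame=30.0)).size == 0
        # ... but the same trace without the conversion keeps them
        assert detect_beats(make_trace(v)).size > 0

    def test_deterministic(self, rng):
        v = np.abs(rng.normal(0, 1, 400)) + np.abs(np.sin(np.arange(400) / 10.0)) * 5
        t1 = detect_beats(make_trace(v))
        t2 = detect_beats(make_trace(v.copy()))
        np.testing.assert_array_equal(t1, t2)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            BeatDetectionParams(prominence_frac=0.0)
        with pytest.raises(ValueError):
            BeatDetectionParams(min_interbeat_s=0.0)
        with pytest.raises(ValueError):
            BeatDetectionParams(area_amp_frac=1.5)
        with pytest.raises(ValueError):
            BeatDetectionParams(smooth_s=-0.1)


class TestBeatingFrequency:
    def test_even_spacing(self):
        assert beating_frequency(np.arange(0, 20, 2.0), 20.0) == pytest.approx(0.5)

    def test_single_beat_is_zero(self):
        assert beating_frequency(np.array([12.0]), 30.0) == 0.0

    def test_uneven_spacing_hand_value(self):
        beats = np.array([0.0, 1.5, 3.5, 5.0])
        assert beating_frequency(beats, 30.0) == pytest.approx(3 / 5.0)

    def test_no_beats(self):
        assert beating_frequency(np.array([]), 30.0) == 0.0


class TestBeatingVelocity:
    def test_constant_peak_value(self):
        v = np.zeros(300)
        v[[30, 60, 90]] = 150.0
        trace = make_trace(v)
        beats = trace.times_s[[30, 60, 90]]
        assert beating_velocity(trace, beats) == pytest.approx(150.0)

    def test_mean_of_two_peaks(self):
        v = np.zeros(300)
        v[50], v[150] = 100.0, 200.0
        trace = make_trace(v)
        beats = trace.times_s[[50, 150]]
        assert beating_velocity(trace, beats) == pytest.approx(150.0)

    def test_no_beats_zero(self):
        assert beating_velocity(make_trace(np.zeros(10)), np.array([])) == 0.0


class TestMaxDisplacement:
    def test_all_zero(self):
        fields = [make_field(np.zeros((2, 2, 2)))]
        assert max_displacement(fields) == (0.0, 0.0)

    def test_three_four_gives_five(self):
        vec = np.zeros((2, 2, 2), int)
        vec[1, 1] = [3, 4]
        px, um = max_displacement([make_field(vec)], pixel_size_um=0.5)
        assert px == pytest.approx(5.0)
        assert um == pytest.approx(2.5)

    def test_window_bound(self, rng):
        vecs = rng.integers(-4, 5, (3, 2, 2, 2))
        fields = [make_field(v, k=k) for k, v in enumerate(vecs)]
        px, _ = max_displacement(fields)
        assert px <= 4 * np.sqrt(2) + 1e-12

    def test_invalid_blocks_ignored(self):
        vec = np.zeros((2, 2, 2), int)
        vec[0, 0] = [4, 4]
        valid = np.ones((2, 2), bool)
        valid[0, 0] = False
        px, _ = max_displacement([make_field(vec, valid)])
        assert px == 0.0

    def test_no_valid_blocks_raises(self):
        field = make_field(np.zeros((2, 2, 2)), valid=np.zeros((2, 2), bool))
        with pytest.raises(NoDisplacementDataError):
            max_displacement([field])


class TestBeatArea:
    def test_uniform_motion_full_area(self):
        vec = np.tile([1, 0], (3, 3, 1))
        assert beat_area([make_field(vec)]) == pytest.approx(100.0)

    def test_half_static_half_moving(self):
        vec = np.zeros((2, 2, 2), int)
        vec[0, 0] = vec[0, 1] = [2, 0]
        assert beat_area([make_field(vec)]) == pytest.approx(50.0)

    def test_all_static_zero_percent(self):
        assert beat_area([make_field(np.zeros((2, 2, 2)))]) == 0.0

    def test_monotone_in_area_amp_frac(self, rng):
        vecs = rng.integers(-3, 4, (5, 4, 4, 2))
        fields = [make_field(v, k=k) for k, v in enumerate(vecs)]
        areas = [
            beat_area(fields, BeatDetectionParams(area_amp_frac=f))
            for f in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(0 <= a <= 100 for a in areas)
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestNormalizeToBaseline:
    def _metrics(self, **over):
        base = dict(
            frequency_hz=0.6,
            velocity_um_s=10.0,
            max_displacement_px=3.0,
            max_displacement_um=3.0,
            beat_area_pct=80.0,
            n_beats=18,
            is_beating=True,
        )
        base.update(over)
        return BeatMetrics(**base)

    def test_baseline_normalizes_to_one(self):
        m = self._metrics()
        ratios = normalize_to_baseline(m, m)
        assert all(v == 1.0 for v in ratios.values())

    def test_halved_frequency(self):
        ratios = normalize_to_baseline(
            self._metrics(frequency_hz=0.3), self._metrics(frequency_hz=0.6)
        )
        assert ratios["frequency_hz"] == pytest.approx(0.5)

    def test_zero_baseline_undefined(self):
        ratios = normalize_to_baseline(self._metrics(), self._metrics(velocity_um_s=0.0))
        assert ratios["velocity_um_s"] is None
        assert ratios["frequency_hz"] == 1.0


class TestEndToEnd:
    """Pipeline invariants on small synthetic videos."""

    def _analyze(self, cfg):
        stack, truth = generate_beating_video(cfg)
        fields = compute_fields(stack, BlockMatchParams())
        trace = motion_magnitude_trace(fields, stack.frame_rate_hz, stack.pixel_size_um)
        return compute_beat_metrics(trace, fields, stack.pixel_size_um), truth

    def test_frequency_recovery(self):
        # scaled-down form of the recovery invariant (small frames, 5 seeds)
        for seed in range(5):
            cfg = SyntheticVideoConfig(
                frequency_hz=0.6, frame_size=(128, 128), duration_s=20, seed=seed
            )
            metrics, truth = self._analyze(cfg)
            f = truth.realized_frequency_hz
            assert metrics.is_beating
            assert abs(metrics.frequency_hz - f) <= max(0.05, 0.05 * f)

    def test_zero_amplitude_not_beating(self):
        cfg = SyntheticVideoConfig(
            amplitude_px=0.0, frame_size=(128, 128), duration_s=20, seed=3
        )
        metrics, _ = self._analyze(cfg)
        assert not metrics.is_beating
        assert metrics.frequency_hz == 0.0
        assert metrics.n_beats <= 1

    def test_time_reversal(self):
        cfg = SyntheticVideoConfig(
            frequency_hz=0.6, frame_size=(128, 128), duration_s=20,
            irregularity=0.0, seed=7,
        )
        stack, _ = generate_beating_video(cfg)
        rev = type(stack)(
            frames=stack.frames[::-1].copy(),
            frame_rate_hz=stack.frame_rate_hz,
            pixel_size_um=stack.pixel_size_um,
        )
        fwd_fields = compute_fields(stack, BlockMatchParams())
        rev_fields = compute_fields(rev, BlockMatchParams())
        fwd_trace = motion_magnitude_trace(fwd_fields, 30.0)
        rev_trace = motion_magnitude_trace(rev_fields, 30.0)
        fwd = compute_beat_metrics(fwd_trace, fwd_fields)
        bwd = compute_beat_metrics(rev_trace, rev_fields)
        period = 1.0 / fwd.frequency_hz
        assert abs(fwd.frequency_hz - bwd.frequency_hz) <= 0.05
        assert abs(fwd.max_displacement_px - bwd.max_displacement_px) <= 1.0
        assert abs(fwd.n_beats - bwd.n_beats) <= 1
        assert period == pytest.approx(1 / 0.6, rel=0.1)

    def test_metrics_dict_schema(self):
        cfg = SyntheticVideoConfig(frame_size=(64, 64), duration_s=10, seed=1)
        metrics, _ = self._analyze(cfg)
        assert set(metrics.to_dict()) == {
            "frequency_hz",
            "velocity_um_s",
            "max_displacement_px",
            "max_displacement_um",
            "beat_area_pct",
            "n_beats",
            "is_beating",
        }
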
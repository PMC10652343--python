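"""End-to-end convenience wrappers: video in, beat metrics out."""

from __future__ import annotations

from .beat_metrics import (
    BeatDetectionParams,
    BeatMetrics,
    MotionTrace,
    compute_beat_metrics,
)
from .motion_estimation import (
    BlockMatchParams,
    DisplacementField,
    compute_fields,
    motion_magnitude_trace,
)
from .video_io import FrameStack


def analyze_stack(
    stack: FrameStack,
    match_params: BlockMatchParams | None = None,
    detect_params: BeatDetectionParams | None = None,
) -> tuple[BeatMetrics, MotionTrace, list[DisplacementField]]:
    """Block-match a video, aggregate the motion, and extract beat metrics."""
    match_params = match_params or BlockMatchParams()
    detect_params = detect_params or BeatDetectionParams()
    fields = compute_fields(stack, match_params)
    trace = motion_magnitude_trace(fields, stack.frame_rate_hz, stack.pixel_size_um)
    metrics = compute_beat_metrics(trace, fields, stack.pixel_size_um, detect_params)
    return metrics, trace, fields
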
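"""Block-matching motion estimation for beating-monolayer video.

Each frame is divided into square N x N blocks on a fixed grid. The movement
of a block between frame k and frame k+1 is found by exhaustively scanning a
square search window of radius w pixels around the block's position and
picking the candidate offset that minimizes the Mean Absolute Difference
(MAD) between the reference block and the candidate patch. Displacements are
whole-pixel; there is no sub-pixel refinement and the grid is re-anchored at
every frame pair (no trajectory accumulation).

Ties in the MAD score are broken deterministically: smaller Euclidean norm of
the offset first, then lexicographic (dy, dx). Candidate offsets that would
place the target patch outside the frame are excluded. Blocks whose intensity
standard deviation falls below ``min_block_std`` are flagged invalid — MAD is
degenerate on flat blocks (every offset ties) — and excluded from aggregates.

Coordinates: x = column index increasing rightward, y = row index increasing
downward. A displacement (dx, dy) means the content of the block at frame k
is found at origin + (dx, dy) in frame k+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video_io import FrameStack
from .beat_metrics import MotionTrace


class MotionEstimationError(Exception):
    """Base class for block-matching failures."""


class BlockShapeError(MotionEstimationError):
    """Patches passed to the matching criterion differ in shape."""


class BlockOutOfFrameError(MotionEstimationError):
    """Reference block does not lie fully inside the frame."""


class FrameTooSmallError(MotionEstimationError):
    """Frame cannot hold a single block of the requested size."""


class NoValidBlocksError(MotionEstimationError):
    """A frame pair has no block passing the texture threshold."""


@dataclass(frozen=True)
class BlockMatchParams:
    """Parameters of the exhaustive block-matching search.

    block_size_px
        N, side of the square block in pixels.
    search_radius_px
        w, the maximum displacement searched per axis; the window spans
        (2w+1)^2 candidate offsets.
    min_block_std
        Minimum intensity standard deviation for a block to be tracked.
    """

    block_size_px: int = 16
    search_radius_px: int = 4
    min_block_std: float = 1e-6

    def __post_init__(self) -> None:
        if self.block_size_px < 2:
            raise ValueError("block_size_px must be >= 2")
        if self.search_radius_px < 1:
            raise ValueError("search_radius_px must be >= 1")
        if self.min_block_std < 0:
            raise ValueError("min_block_std must be >= 0")


@dataclass
class DisplacementField:
    """Per-block integer displacements for one consecutive frame pair.

    ``vectors[by, bx] = (dx, dy)`` for the block whose top-left pixel is at
    row ``by * N``, column ``bx * N`` in frame ``frame_pair_index``;
    ``valid_mask`` flags blocks passing the texture threshold.
    """

    frame_pair_index: int
    vectors: np.ndarray  # (n_by, n_bx, 2) int, last axis = (dx, dy)
    valid_mask: np.ndarray  # (n_by, n_bx) bool

    def magnitudes(self) -> np.ndarray:
        """Euclidean displacement magnitude per block, in pixels."""
        v = self.vectors.astype(float)
        return np.hypot(v[..., 0], v[..., 1])


def candidate_offsets(search_radius_px: int) -> list[tuple[int, int]]:
    """All (dy, dx) offsets of the search window in tie-break priority order.

    Sorted by squared Euclidean norm, then lexicographically by (dy, dx), so
    that taking the first minimum of the MAD scores in this order implements
    the documented tie-breaking.
    """
    w = search_radius_px
    offs = [(dy, dx) for dy in range(-w, w + 1) for dx in range(-w, w + 1)]
    offs.sort(key=lambda o: (o[0] * o[0] + o[1] * o[1], o[0], o[1]))
    return offs


def mad(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Mean Absolute Difference between two equal-shape intensity patches."""
    a = np.asarray(block_a, dtype=float)
    b = np.asarray(block_b, dtype=float)
    if a.shape != b.shape:
        raise BlockShapeError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def match_block(
    ref_block_origin: tuple[int, int],
    frame_k: np.ndarray,
    frame_k1: np.ndarray,
    params: BlockMatchParams,
) -> tuple[int, int, float]:
    """Match one block from frame k to frame k+1 by exhaustive MAD scan.

    Parameters
    ----------
    ref_block_origin
        (row, col) of the block's top-left pixel in frame k.
    frame_k, frame_k1
        Consecutive grayscale frames of identical shape.
    params
        Block size, search radius and texture threshold.

    Returns
    -------
    (dx, dy, score)
        Best offset within the window and its MAD score. Candidates whose
        target patch would leave the frame are excluded; (0, 0) is always a
        candidate, so the result is well defined.
    """
    r, c = ref_block_origin
    N = params.block_size_px
    H, W = frame_k.shape
    if r < 0 or c < 0 or r + N > H or c + N > W:
        raise BlockOutOfFrameError(
            f"block at ({r}, {c}) size {N} outside frame {H}x{W}"
        )
    ref = frame_k[r : r + N, c : c + N]
    best: tuple[int, int] | None = None
    best_score = np.inf
    for dy, dx in candidate_offsets(params.search_radius_px):
        rr, cc = r + dy, c + dx
        if rr < 0 or cc < 0 or rr + N > H or cc + N > W:
            continue
        score = mad(ref, frame_k1[rr : rr + N, cc : cc + N])
        if score < best_score:
            best_score = score
            best = (dx, dy)
    assert best is not None
    return best[0], best[1], best_score


def _pair_field(
    frame_k: np.ndarray,
    frame_k1: np.ndarray,
    pair_index: int,
    params: BlockMatchParams,
    offsets: list[tuple[int, int]],
) -> DisplacementField:
    """Vectorized exhaustive scan for all blocks of one frame pair.

    Equivalent to calling :func:`match_block` on every grid block (the test
    suite asserts this); computes, per candidate offset, the absolute
    difference image and reduces it to per-block sums in one pass.
    """
    N = params.block_size_px
    H, W = frame_k.shape
    n_by, n_bx = H // N, W // N
    Hc, Wc = n_by * N, n_bx * N
    ref = frame_k[:Hc, :Wc]

    blocks = ref.reshape(n_by, N, n_bx, N)
    valid = blocks.std(axis=(1, 3)) >= params.min_block_std

    scores = np.full((len(offsets), n_by, n_bx), np.inf)
    diff = np.empty((Hc, Wc), dtype=frame_k.dtype)
    for i, (dy, dx) in enumerate(offsets):
        # target patch rows/cols must stay inside frame_k1
        r0, r1 = max(0, -dy), min(Hc, H - dy)
        c0, c1 = max(0, -dx), min(Wc, W - dx)
        if r1 <= r0 or c1 <= c0:
            continue
        np.subtract(
            ref[r0:r1, c0:c1],
            frame_k1[r0 + dy : r1 + dy, c0 + dx : c1 + dx],
            out=diff[r0:r1, c0:c1],
        )
        np.abs(diff[r0:r1, c0:c1], out=diff[r0:r1, c0:c1])
        s = diff.reshape(n_by, N, n_bx, N).sum(axis=(1, 3), dtype=np.float64)
        # block rows/cols only partially covered by the overlap are not
        # legal candidates for this offset
        by0 = (r0 + N - 1) // N
        by1 = r1 // N
        bx0 = (c0 + N - 1) // N
        bx1 = c1 // N
        scores[i, by0:by1, bx0:bx1] = s[by0:by1, bx0:bx1]

    best = scores.argmin(axis=0)  # first occurrence = tie-break order
    off_arr = np.array(offsets)  # (n_off, 2) as (dy, dx)
    vectors = np.empty((n_by, n_bx, 2), dtype=int)
    vectors[..., 0] = off_arr[best, 1]  # dx
    vectors[..., 1] = off_arr[best, 0]  # dy
    return DisplacementField(
        frame_pair_index=pair_index, vectors=vectors, valid_mask=valid
    )


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(**kwargs):
        def deco(fn):
            return fn

        return deco


@_njit(cache=True)
def _match_stack_kernel(frames, N, min_std, offs):  # pragma: no cover - compiled
    """Exhaustive MAD scan for every block of every frame pair.

    Candidates are visited in tie-break priority order (``offs``); a strictly
    smaller absolute-difference total replaces the incumbent, so the result
    equals the plain exhaustive scan. Within one candidate the running total
    is abandoned as soon as it exceeds the incumbent (branch and bound),
    which cannot change the argmin: a tying candidate's partial sums never
    strictly exceed its own total.
    """
    T, H, W = frames.shape
    n_by = H // N
    n_bx = W // N
    n_off = offs.shape[0]
    vectors = np.zeros((T - 1, n_by, n_bx, 2), dtype=np.int64)
    valid = np.zeros((T - 1, n_by, n_bx), dtype=np.bool_)
    for k in range(T - 1):
        for by in range(n_by):
            for bx in range(n_bx):
                r = by * N
                c = bx * N
                s = 0.0
                s2 = 0.0
                for i in range(N):
                    for j in range(N):
                        v = frames[k, r + i, c + j]
                        s += v
                        s2 += v * v
                mean = s / (N * N)
                var = s2 / (N * N) - mean * mean
                if var < 0.0:
                    var = 0.0
                if var**0.5 < min_std:
                    continue
                valid[k, by, bx] = True
                best = np.inf
                best_dy = 0
                best_dx = 0
                for o in range(n_off):
                    dy = offs[o, 0]
                    dx = offs[o, 1]
                    rr = r + dy
                    cc = c + dx
                    if rr < 0 or cc < 0 or rr + N > H or cc + N > W:
                        continue
                    total = 0.0
                    for i in range(N):
                        for j in range(N):
                            d = frames[k, r + i, c + j] - frames[k + 1, rr + i, cc + j]
                            total += abs(d)
                        if total > best:
                            break
                    if total < best:
                        best = total
                        best_dy = dy
                        best_dx = dx
                vectors[k, by, bx, 0] = best_dx
                vectors[k, by, bx, 1] = best_dy
    return vectors, valid


def compute_fields(
    stack: FrameStack,
    params: BlockMatchParams | None = None,
    engine: str = "auto",
) -> list[DisplacementField]:
    """Block-match every consecutive frame pair of a stack.

    Returns T-1 displacement fields on the fixed floor(H/N) x floor(W/N)
    block grid. ``engine`` selects the implementation: "numba" (compiled
    branch-and-bound scan), "numpy" (vectorized full scan) or "auto" (numba
    when available). Both engines perform the same exhaustive search and
    return identical fields.
    """
    if params is None:
        params = BlockMatchParams()
    H, W = stack.frame_shape
    if params.block_size_px > min(H, W):
        raise FrameTooSmallError(
            f"block size {params.block_size_px} exceeds frame {H}x{W}"
        )
    if engine == "auto":
        engine = "numba" if _HAVE_NUMBA else "numpy"
    offsets = candidate_offsets(params.search_radius_px)
    if engine == "numba":
        frames = np.ascontiguousarray(stack.frames, dtype=np.float64)
        offs = np.array(offsets, dtype=np.int64)
        vectors, valid = _match_stack_kernel(
            frames, params.block_size_px, params.min_block_std, offs
        )
        return [
            DisplacementField(
                frame_pair_index=k, vectors=vectors[k], valid_mask=valid[k]
            )
            for k in range(stack.n_frames - 1)
        ]
    if engine != "numpy":
        raise ValueError(f"unknown engine {engine!r}")
    frames = stack.frames.astype(np.float64, copy=False)
    return [
        _pair_field(frames[k], frames[k + 1], k, params, offsets)
        for k in range(stack.n_frames - 1)
    ]


def motion_magnitude_trace(
    fields: list[DisplacementField],
    frame_rate_hz: float,
    pixel_size_um: float = 1.0,
) -> MotionTrace:
    """Aggregate displacement fields into a scalar motion-speed time series.

    Per frame pair: the mean over valid blocks of the displacement magnitude,
    converted from px/frame-pair to um/s. The sample time is the midpoint of
    the frame pair.
    """
    if not fields:
        raise MotionEstimationError("need at least one displacement field")
    times = np.empty(len(fields))
    speeds = np.empty(len(fields))
    counts = np.empty(len(fields), dtype=int)
    for i, f in enumerate(fields):
        n_valid = int(f.valid_mask.sum())
        if n_valid == 0:
            raise NoValidBlocksError(
                f"frame pair {f.frame_pair_index} has no valid blocks"
            )
        mags = f.magnitudes()[f.valid_mask]
        times[i] = (f.frame_pair_index + 0.5) / frame_rate_hz
        speeds[i] = mags.mean() * pixel_size_um * frame_rate_hz
        counts[i] = n_valid
    return MotionTrace(
        times_s=times,
        velocity_um_s=speeds,
        n_valid_blocks=counts,
        um_s_per_px_frame=pixel_size_um * frame_rate_hz,
    )
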
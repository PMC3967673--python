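"""Respiratory-motion stabilization by translational SSD registration.

Free breathing during cine acquisition translates the whole field of view,
mostly cranio-caudally.  Between successive frames the translation is
estimated by exhaustively minimizing the sum of squared intensity
differences (SSD) over a region of interest:

    E(n, n+1; b) = (1/|ROI|) * sum_{x in ROI} [I_n(x) - I_{n+1}(x + b)]^2

The integer shift b_n minimizing E is the displacement of frame n+1
relative to frame n.  Cumulative shifts chain the pairwise estimates so
every frame can be translated back onto frame 0.

The search is an exhaustive scan of the (2r+1)^2 integer candidates in
[-r, r]^2 — cheap at cine-MRI scale and exactly reproducible.  Among
equal-energy minima the smallest-magnitude shift is chosen, then the
lexicographically smallest (row, col): determinism that favours the null
under degeneracy.  No rotation, scaling or non-rigid motion is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FrameStack, ShiftTrace

__all__ = ["ShiftResult", "compute_shift", "stabilize_stack", "translate_frame"]


@dataclass
class ShiftResult:
    """Outcome of a single pairwise registration."""

    shift: tuple[int, int]  # (dy, dx) = (row, col)
    energy: float
    degenerate: bool = False


def _roi_bounds(roi, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    r0, r1, c0, c1 = (int(v) for v in roi)
    h, w = shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} outside frame bounds {shape}")
    return r0, r1, c0, c1


def _candidate_order(radius: int) -> list[tuple[int, int]]:
    cands = [(dy, dx) for dy in range(-radius, radius + 1)
             for dx in range(-radius, radius + 1)]
    cands.sort(key=lambda b: (b[0] * b[0] + b[1] * b[1], b[0], b[1]))
    return cands


def compute_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    roi: tuple[int, int, int, int],
    search_radius: int,
) -> ShiftResult:
    """Integer shift of ``frame_b`` relative to ``frame_a``.

    Parameters
    ----------
    frame_a, frame_b : ndarray (H, W)
        Consecutive raw frames on the same grid.
    roi : (r0, r1, c0, c1)
        Half-open row/col bounds of the region of interest, which must
        keep a margin of at least ``search_radius`` pixels to the frame
        border.
    search_radius : int
        Half-width of the square search window in pixels.

    Returns
    -------
    ShiftResult
        The (dy, dx) argmin of the ROI-mean SSD energy, the energy at
        that shift, and a degeneracy flag set when both ROIs are
        constant (the null shift is returned in that case).
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape or frame_a.ndim != 2:
        raise ValueError("frames must be 2D arrays on the same grid")
    radius = int(search_radius)
    if radius < 0:
        raise ValueError("search_radius must be >= 0")
    r0, r1, c0, c1 = _roi_bounds(roi, frame_a.shape)
    h, w = frame_a.shape
    if r0 - radius < 0 or r1 + radius > h or c0 - radius < 0 or c1 + radius > w:
        raise ValueError(
            f"ROI {roi} is within {radius} px of the frame border; "
            "shrink the ROI or the search radius"
        )
    a = frame_a[r0:r1, c0:c1]
    npix = a.size
    if np.ptp(a) == 0 and np.ptp(frame_b[r0 - radius:r1 + radius, c0 - radius:c1 + radius]) == 0:
        zero_d = frame_b[r0:r1, c0:c1] - a
        return ShiftResult((0, 0), float(np.sum(zero_d ** 2) / npix), degenerate=True)
    best: tuple[int, int] | None = None
    best_e = np.inf
    for dy, dx in _candidate_order(radius):
        d = frame_b[r0 + dy:r1 + dy, c0 + dx:c1 + dx] - a
        e = float(np.sum(d * d) / npix)
        if e < best_e:
            best_e, best = e, (dy, dx)
    assert best is not None
    return ShiftResult(best, best_e, degenerate=False)


def translate_frame(
    frame: np.ndarray, shift: tuple[int, int], fill: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``frame`` at positions offset by an integer ``shift``.

    Returns ``out`` with ``out[x] = frame[x + shift]`` and a boolean
    validity mask that is False where the source position fell outside
    the frame.  Vacated pixels are filled with ``fill`` (default: the
    median of the frame's border pixels).
    """
    frame = np.asarray(frame, dtype=float)
    dy, dx = (int(v) for v in shift)
    h, w = frame.shape
    if fill is None:
        border = np.concatenate([frame[0], frame[-1], frame[1:-1, 0], frame[1:-1, -1]])
        fill = float(np.median(border))
    out = np.full_like(frame, fill)
    valid = np.zeros(frame.shape, dtype=bool)
    src_r0, src_r1 = max(0, dy), min(h, h + dy)
    src_c0, src_c1 = max(0, dx), min(w, w + dx)
    if src_r0 < src_r1 and src_c0 < src_c1:
        dst_r0, dst_c0 = src_r0 - dy, src_c0 - dx
        out[dst_r0:dst_r0 + (src_r1 - src_r0), dst_c0:dst_c0 + (src_c1 - src_c0)] = \
            frame[src_r0:src_r1, src_c0:src_c1]
        valid[dst_r0:dst_r0 + (src_r1 - src_r0), dst_c0:dst_c0 + (src_c1 - src_c0)] = True
    return out, valid


def stabilize_stack(
    stack: FrameStack,
    roi: tuple[int, int, int, int],
    search_radius: int,
) -> tuple[FrameStack, ShiftTrace, np.ndarray]:
    """Align every frame of a cine stack to frame 0.

    Pairwise shifts are estimated on consecutive *raw* frames and chained
    into cumulative shifts; frame n is then resampled by its cumulative
    shift so the anatomy stays put.  Vacated pixels get the frame's
    border-median intensity and are flagged invalid.

    Returns
    -------
    (stabilized FrameStack, ShiftTrace, validity mask (T, H, W) bool)
    """
    n = stack.n_frames
    pair_shifts = np.zeros((max(n - 1, 0), 2), dtype=int)
    energies = np.zeros(max(n - 1, 0))
    degenerate = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        res = compute_shift(stack.frames[i], stack.frames[i + 1], roi, search_radius)
        pair_shifts[i] = res.shift
        energies[i] = res.energy
        degenerate[i] = res.degenerate
    cumulative = np.vstack([[0, 0], np.cumsum(pair_shifts, axis=0)]) if n > 1 \
        else np.zeros((1, 2), dtype=int)
    frames_out = np.empty_like(stack.frames)
    valid = np.ones(stack.frames.shape, dtype=bool)
    for i in range(n):
        frames_out[i], valid[i] = translate_frame(stack.frames[i], tuple(cumulative[i]))
    stabilized = FrameStack(
        frames=frames_out,
        pixel_spacing_x=stack.pixel_spacing_x,
        pixel_spacing_y=stack.pixel_spacing_y,
        frame_interval=stack.frame_interval,
        plane_id=stack.plane_id,
        scan_id=stack.scan_id,
    )
    trace = ShiftTrace(pair_shifts=pair_shifts, cumulative=cumulative,
                       energies=energies, degenerate=degenerate)
    return stabilized, trace, valid
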
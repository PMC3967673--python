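"""Wall contours: spline resampling, polygon geometry, frame averaging.

Manual outlining of the gut wall yields a sparse closed polygon (20 points
for the gastric fundus, 30 for the duodenum).  A periodic cubic spline
through the seeds, re-parameterized by arc length, turns it into a dense
equidistant contour (default 100 points) on which areas, centroids and
wall velocities are well defined.  Orientation is always normalized to
counterclockwise (positive shoelace area) so that the inward/
counterclockwise sign conventions of the velocity decomposition are
unambiguous.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .core import (
    ContourSeries,
    FrameStack,
    SeedContour,
    WallContour,
    is_simple_polygon,
    signed_area,
)

__all__ = [
    "resample_contour",
    "polygon_area",
    "polygon_centroid",
    "contour_frames",
    "average_image",
    "build_series",
]

#: dense-polyline oversampling factor used for arc-length evaluation
_DENSITY = 20


def resample_contour(seed: SeedContour | WallContour, n_points: int = 100) -> WallContour:
    """Resample a closed seed polygon to ``n_points`` equidistant points.

    A periodic cubic interpolating spline is fitted through the seed
    points (chord-length parameterization), its arc length is evaluated
    on a dense polyline, and the curve is sampled at ``n_points`` equal
    arc intervals.  The output is counterclockwise and starts at the
    spline point nearest the first seed point.

    Raises
    ------
    ValueError
        If the resampled polygon self-intersects (the spline overshoots
        between seeds); denser seed points are then required.
    """
    pts = np.asarray(seed.points, dtype=float)
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    closed = np.vstack([pts, pts[0]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(chord == 0):
        raise ValueError("duplicate consecutive seed points")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, closed, bc_type="periodic", axis=0)

    n_dense = _DENSITY * max(n_points, pts.shape[0])
    u = np.linspace(0.0, t[-1], n_dense + 1)
    dense = spline(u)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.arange(n_points) * total / n_points
    u_eq = np.interp(targets, arc, u)
    out = np.asarray(spline(u_eq), dtype=float)

    if signed_area(out) < 0:
        out = np.vstack([out[0], out[1:][::-1]])  # keep the start point first
    if not is_simple_polygon(out):
        raise ValueError(
            "resampled contour self-intersects; provide denser seed points "
            f"(frame {seed.frame_index})"
        )
    return WallContour(points=out, structure_label=seed.structure_label,
                       frame_index=seed.frame_index)


def polygon_area(contour: WallContour | np.ndarray) -> float:
    """Absolute shoelace area (mm^2) of a closed simple polygon."""
    pts = contour.points if isinstance(contour, WallContour) else np.asarray(contour, float)
    return abs(signed_area(pts))


def polygon_centroid(contour: WallContour | np.ndarray) -> np.ndarray:
    """Area centroid (centre of gravity of the enclosed region, mm).

    Uses the first-moment formula over the polygon's interior, not the
    vertex mean; the two differ for unevenly spaced vertices.
    """
    pts = contour.points if isinstance(contour, WallContour) else np.asarray(contour, float)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        raise ValueError("polygon area is (near) zero; centroid undefined")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def contour_frames(contour: WallContour) -> tuple[np.ndarray, np.ndarray]:
    """Per-point unit inward normals and unit counterclockwise tangents.

    The tangent at point k is the central difference of its neighbours
    along the closed sequence, normalized; the inward normal is the
    tangent rotated by +90 deg, which points into the enclosed region for
    a counterclockwise polygon (the interior lies to the left of the
    traversal direction).
    """
    pts = contour.points
    diff = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate contour: coincident neighbour points")
    tangents = diff / norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return normals, tangents


def average_image(stack: FrameStack) -> np.ndarray:
    """Pixelwise mean frame — the time-averaged organ shape.

    Spontaneous contractions blur out in the mean, leaving the envelope
    used to assess overall stomach shape and position.
    """
    return stack.frames.mean(axis=0)


def _best_cyclic_shift(curr: np.ndarray, prev: np.ndarray) -> int:
    n = curr.shape[0]
    costs = np.empty(n)
    for k in range(n):
        d = np.roll(curr, -k, axis=0) - prev
        costs[k] = np.sum(d * d)
    return int(np.argmin(costs))


def build_series(
    contours: Sequence[WallContour],
    frame_interval: float,
) -> ContourSeries:
    """Assemble per-frame contours into a corresponded series.

    All contours must share the point count (orientation is already
    normalized by :func:`resample_contour`).  Point index k is treated as
    the same material wall point across frames; since each frame is
    resampled independently, the start index of frame t > 0 is rotated to
    minimize the sum of squared distances to frame t-1's points over all
    cyclic shifts.
    """
    if not contours:
        raise ValueError("empty contour sequence")
    n = contours[0].n_points
    label = contours[0].structure_label
    aligned = [np.asarray(contours[0].points, dtype=float)]
    for c in contours[1:]:
        if c.n_points != n:
            raise ValueError(
                f"mismatched point counts: {c.n_points} vs {n} (frame {c.frame_index})"
            )
        k = _best_cyclic_shift(c.points, aligned[-1])
        aligned.append(np.roll(c.points, -k, axis=0))
    return ContourSeries(points=np.stack(aligned), structure_label=label,
                         frame_interval=frame_interval)
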
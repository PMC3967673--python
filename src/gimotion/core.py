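"""Core data containers for cine-MRI motility analysis.

All geometry lives in physical millimetre coordinates: the image origin is
the centre of the top-left pixel, x runs rightward along columns, y runs
downward along rows, and ``mm = pixel_index * spacing``.  Contours are
closed simple polygons stored as open rings (the first point is *not*
repeated at the end) with positive shoelace orientation, called
"counterclockwise" throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

__all__ = [
    "FrameStack",
    "SeedContour",
    "WallContour",
    "ContourSeries",
    "ShiftTrace",
    "VelocityField",
    "MotilityIndices",
    "GastricVolumeIndex",
    "signed_area",
    "is_simple_polygon",
]

SCAN_IDS = ("MS1", "MS2", "MS3")
STRUCTURE_LABELS = ("fundus", "duodenum")


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as an open ring.

    Positive for counterclockwise orientation under the package's
    coordinate convention.
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def is_simple_polygon(points: np.ndarray) -> bool:
    """True if the closed polygon through ``points`` is simple (non-self-
    intersecting) with nonzero area."""
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 3:
        return False
    poly = _ShPolygon(p)
    return bool(poly.is_valid) and poly.area > 0


@dataclass
class FrameStack:
    """One plane's cine series.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative image intensities in acquisition order.
    pixel_spacing_x, pixel_spacing_y : float
        Physical pixel size in mm/px along columns (x) and rows (y).
    frame_interval : float
        Time between successive frames in seconds.
    plane_id : int
        Coronal plane number (1-11 in the acquisition protocol).
    scan_id : str
        Motility-scan identifier, one of MS1/MS2/MS3.
    """

    frames: np.ndarray
    pixel_spacing_x: float
    pixel_spacing_y: float
    frame_interval: float
    plane_id: int = 1
    scan_id: str = "MS1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if not (self.pixel_spacing_x > 0 and self.pixel_spacing_y > 0):
            raise ValueError("pixel spacings must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])


@dataclass
class SeedContour:
    """Manually placed closed outline of a wall on one frame.

    ``points`` is an (m, 2) array of (x, y) mm coordinates forming a simple
    polygon, m >= 3, stored as an open ring.
    """

    points: np.ndarray
    frame_index: int
    structure_label: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (m, 2) array")
        m = self.points.shape[0]
        if m < 3:
            raise ValueError(
                f"seed contour needs at least 3 points, got {m} "
                f"(frame {self.frame_index})"
            )
        if len(np.unique(self.points, axis=0)) != m:
            raise ValueError(f"seed points must be distinct (frame {self.frame_index})")
        if not is_simple_polygon(self.points):
            raise ValueError(
                f"seed polygon is self-intersecting or degenerate "
                f"(frame {self.frame_index})"
            )
        if self.structure_label not in STRUCTURE_LABELS:
            raise ValueError(f"unknown structure_label {self.structure_label!r}")


@dataclass
class WallContour:
    """Equidistant closed wall polygon with normalized orientation.

    Exactly ``n_points`` ordered (x, y) mm points; counterclockwise
    (positive shoelace area); consecutive arc spacings equal to within
    1% relative tolerance.
    """

    points: np.ndarray
    structure_label: str
    frame_index: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if signed_area(self.points) <= 0:
            raise ValueError("wall contour must be counterclockwise (signed area > 0)")

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class ContourSeries:
    """One wall contour per frame with shared point count and orientation.

    ``points`` has shape (T, n, 2); index k refers to the same material
    wall point across frames once the start-point correspondence rule has
    been applied (see :func:`gimotion.contouring.build_series`).
    """

    points: np.ndarray
    structure_label: str
    frame_interval: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must be a (T, n, 2) array")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.points.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.points.shape[1])


@dataclass
class ShiftTrace:
    """Per-pair translation estimates from stabilization.

    ``pair_shifts[n]`` is the integer (dy, dx) shift b_n of frame n+1
    relative to frame n (rows, cols).  ``cumulative[k]`` is the shift of
    frame k relative to frame 0; ``cumulative[0] == (0, 0)`` and
    ``cumulative[n+1] == cumulative[n] + pair_shifts[n]``.
    """

    pair_shifts: np.ndarray
    cumulative: np.ndarray
    energies: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.pair_shifts = np.asarray(self.pair_shifts, dtype=int).reshape(-1, 2)
        self.cumulative = np.asarray(self.cumulative, dtype=int).reshape(-1, 2)
        self.energies = np.asarray(self.energies, dtype=float).reshape(-1)
        self.degenerate = np.asarray(self.degenerate, dtype=bool).reshape(-1)
        if np.any(self.cumulative[0] != 0):
            raise ValueError("cumulative shift of frame 0 must be (0, 0)")
        expect = np.vstack([[0, 0], np.cumsum(self.pair_shifts, axis=0)]) \
            if len(self.pair_shifts) else np.zeros((1, 2), dtype=int)
        if not np.array_equal(self.cumulative, expect):
            raise ValueError("cumulative shifts inconsistent with pair shifts")


@dataclass
class VelocityField:
    """Signed wall velocities per frame pair and wall point.

    ``v_normal[p, k]`` and ``v_tangent[p, k]`` (mm/s) are the velocity of
    wall point k between frames p and p+1, projected on the unit inward
    normal and unit counterclockwise tangent of the later frame's contour.
    Inward and counterclockwise motion are positive.
    """

    v_normal: np.ndarray
    v_tangent: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.v_normal = np.asarray(self.v_normal, dtype=float)
        self.v_tangent = np.asarray(self.v_tangent, dtype=float)
        if self.v_normal.shape != self.v_tangent.shape:
            raise ValueError("v_normal and v_tangent must have identical shape")


@dataclass
class MotilityIndices:
    """Summary motility indices for one structure in one scan.

    dm_area : percent variability of the enclosed area (100 * SD / mean).
    dm_gravity : centroid path length in mm.
    dm_vn, dm_vt : mean absolute normal / tangential wall speed in mm/s
        (None for structures without velocity analysis).
    """

    dm_area: float
    dm_gravity: float
    dm_vn: float | None
    dm_vt: float | None
    scan_id: str
    structure_label: str

    def __post_init__(self) -> None:
        for name in ("dm_area", "dm_gravity", "dm_vn", "dm_vt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class GastricVolumeIndex:
    """Summed mean fundus area per scan and its percentage relative to MS1.

    ``area_sums`` maps scan id to the sum over planes of the frame-mean
    fundus area (mm^2); ``percent`` maps scan id to 100 * sum / sum(MS1).
    """

    area_sums: dict[str, float]
    percent: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "MS1" not in self.area_sums:
            raise ValueError("MS1 is required to anchor the normalization")
        ref = self.area_sums["MS1"]
        if not ref > 0:
            raise ValueError("MS1 area sum must be positive")
        self.percent = {k: 100.0 * v / ref for k, v in self.area_sums.items()}
        self.percent["MS1"] = 100.0
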
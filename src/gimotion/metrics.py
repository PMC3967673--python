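"""Quantitative motility indices.

Three index families summarize gut-wall motion in a cine series:

* ``DM(A)`` — percent variability of the enclosed area, 100 * sample SD /
  mean over the frames.  Dimensionless; insensitive to absolute size.
* ``DM(G)`` — total excursion of the centre of gravity: the Euclidean path
  length (mm) of the area centroid across frames.  The per-frame Y-shift
  relative to the first frame, DG_Y(t), is exposed separately because
  respiratory and peristaltic displacements are predominantly
  cranio-caudal.
* ``DM(V_N)``, ``DM(V_T)`` — mean absolute wall velocity (mm/s) along the
  inward normal and counterclockwise tangent.  The point-wise velocity is
  the frame-to-frame displacement of each corresponded wall point divided
  by the frame interval, projected onto the later frame's local frame;
  absolute values prevent extension/contraction in the same image from
  cancelling.

Gastric emptying is indexed by the summed frame-mean fundus area over the
planes containing the liquid meal, normalized to the first motility scan
(MS1 = 100%).  Condition contrasts use classical paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .contouring import contour_frames, polygon_area, polygon_centroid
from .core import ContourSeries, GastricVolumeIndex, VelocityField, WallContour

__all__ = [
    "area_series",
    "centroid_series",
    "dm_area",
    "dm_gravity",
    "dgy_trace",
    "wall_velocities",
    "dm_velocity",
    "gastric_residual",
    "compare_paired",
    "PairedTestResult",
]


def area_series(series: ContourSeries) -> np.ndarray:
    """Enclosed area (mm^2) per frame."""
    return np.array([polygon_area(series.points[t]) for t in range(series.n_frames)])


def centroid_series(series: ContourSeries) -> np.ndarray:
    """Area centroid (mm) per frame, shape (T, 2)."""
    return np.stack([polygon_centroid(series.points[t]) for t in range(series.n_frames)])


def dm_area(areas: np.ndarray) -> float:
    """Percent area variability: 100 * sample SD / mean of the per-frame areas."""
    a = np.asarray(areas, dtype=float)
    if a.size < 2:
        raise ValueError("dm_area needs at least 2 frames")
    mean = a.mean()
    if mean == 0:
        raise ValueError("mean area is zero; DM(A) undefined")
    return 100.0 * float(a.std(ddof=1)) / float(mean)


def dm_gravity(centroids: np.ndarray) -> float:
    """Total centroid excursion: 2D Euclidean path length in mm."""
    c = np.asarray(centroids, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("dm_gravity needs at least 2 frames")
    return float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))


def dgy_trace(centroids: np.ndarray) -> np.ndarray:
    """Per-frame Y-shift of the centroid relative to the first frame (mm)."""
    c = np.asarray(centroids, dtype=float)
    return c[:, 1] - c[0, 1]


def wall_velocities(series: ContourSeries) -> VelocityField:
    """Signed normal/tangential wall velocities for every frame pair.

    For each pair (n-1, n) and wall point k, the displacement of the
    corresponded point divided by the frame interval is projected onto
    the unit inward normal and unit counterclockwise tangent of the
    frame-n contour at that point.  Inward and counterclockwise motion
    are positive.  The decomposition is exact: V_N^2 + V_T^2 equals the
    squared point speed because the local frame is orthonormal.
    """
    if series.n_frames < 2:
        raise ValueError("wall_velocities needs at least 2 frames")
    dt = series.frame_interval
    T, n = series.n_frames, series.n_points
    v_n = np.empty((T - 1, n))
    v_t = np.empty((T - 1, n))
    for p in range(1, T):
        later = WallContour(points=series.points[p],
                            structure_label=series.structure_label, frame_index=p)
        normals, tangents = contour_frames(later)
        vel = (series.points[p] - series.points[p - 1]) / dt
        v_n[p - 1] = np.einsum("ij,ij->i", vel, normals)
        v_t[p - 1] = np.einsum("ij,ij->i", vel, tangents)
    return VelocityField(v_normal=v_n, v_tangent=v_t, frame_interval=dt)


def dm_velocity(field: VelocityField) -> tuple[float, float]:
    """Mean absolute velocities (DM(V_N), DM(V_T)) in mm/s over all
    frame pairs and wall points."""
    if field.v_normal.size == 0:
        raise ValueError("empty velocity field")
    return float(np.mean(np.abs(field.v_normal))), float(np.mean(np.abs(field.v_tangent)))


def gastric_residual(
    per_plane_areas: Mapping[str, Mapping[int, np.ndarray]],
) -> GastricVolumeIndex:
    """Gastric residual volume index from per-plane fundus area series.

    Parameters
    ----------
    per_plane_areas : mapping scan_id -> {plane_id: per-frame areas (mm^2)}
        Every scan must cover the same plane set and MS1 must be present.

    Returns
    -------
    GastricVolumeIndex
        Per scan, the sum over planes of the frame-mean area, and its
        percentage relative to MS1 (exactly 100 at MS1).
    """
    if "MS1" not in per_plane_areas:
        raise ValueError("MS1 is required for normalization")
    planes = sorted(per_plane_areas["MS1"])
    sums: dict[str, float] = {}
    for scan, by_plane in per_plane_areas.items():
        if sorted(by_plane) != planes:
            raise ValueError(
                f"scan {scan} covers planes {sorted(by_plane)}, expected {planes}"
            )
        sums[scan] = float(sum(np.mean(np.asarray(by_plane[p], dtype=float))
                               for p in planes))
    return GastricVolumeIndex(area_sums=sums)


@dataclass
class PairedTestResult:
    """Classical paired t-test outcome."""

    t: float
    p: float
    n: int
    degenerate: bool = False


def compare_paired(
    values_a: Sequence[float],
    values_b: Sequence[float],
) -> PairedTestResult:
    """Two-sided paired t-test on per-subject differences (a - b).

    Inputs must be aligned by subject.  When every difference is exactly
    zero the test is degenerate: t = 0, p = 1 and the flag is set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired samples must be equal-length 1D arrays, n >= 2")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(t=0.0, p=1.0, n=a.size, degenerate=True)
    if np.std(d, ddof=1) == 0:
        # constant nonzero differences: infinitely strong evidence
        return PairedTestResult(t=float(np.sign(d.mean()) * np.inf), p=0.0, n=a.size)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), p=float(res.pvalue), n=a.size)
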
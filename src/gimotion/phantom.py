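"""Digital motion phantoms for cine motility analysis.

The generators emulate the scenes of a liquid-meal motility study so the
whole pipeline is testable without patient data:

* a **gastric fundus**: a bright ellipse whose area combines a slow
  sinusoidal oscillation (gastric pacemaker rhythm, period tens of
  seconds) with a per-scan emptying factor,
* a **duodenum**: a C-shaped tube whose radius is locally pinched by a
  Gaussian-profile contraction ring travelling along the centerline,
* whole-field **respiratory translation** (integer-pixel, cranio-caudal
  sinusoid) applied before
* additive Gaussian **noise**.

Each generator returns the rendered :class:`~gimotion.core.FrameStack`,
per-frame seed contours (ground-truth boundary points in the frame-0 /
stabilized geometry, i.e. without the respiratory shift), and a
:class:`GroundTruth` with exact boundaries, areas, centroids, per-point
wall velocities and the injected shifts.  All randomness flows from the
spec's seed; regeneration is bit-reproducible.

Rendering uses 4x-supersampled even-odd scanline occupancy averaged down
to gray levels, giving soft edges akin to MRI partial volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .core import FrameStack, SeedContour, signed_area
from .io import write_contour_series, write_frame_stack

__all__ = [
    "RespirationSpec",
    "FundusSpec",
    "DuodenumSpec",
    "StudySpec",
    "GroundTruth",
    "make_fundus_phantom",
    "make_duodenum_phantom",
    "make_study",
    "draw_subject_parameters",
    "rasterize_polygon",
    "seeds_in_raw_frame",
]

_SUPERSAMPLE = 4
_FOREGROUND = 1000.0  # arbitrary intensity units; background is 0
_RENDER_VERTICES = 512  # boundary vertices used for rasterization


# ---------------------------------------------------------------------------
# specs

@dataclass
class RespirationSpec:
    """Whole-field cranio-caudal translation, rounded to integer pixels."""

    amplitude_px: float = 4.0
    period_s: float = 4.0


@dataclass
class FundusSpec:
    """Gastric-fundus phantom: an ellipse with oscillating, emptying area.

    The enclosed area follows ``baseline * (1 - emptying_fraction) *
    (1 + oscillation_amplitude * sin(2 pi t / oscillation_period_s))``;
    emptying is constant within a scan (it acts between scans), the
    oscillation models the pacemaker rhythm within a scan.
    """

    grid_shape: tuple[int, int] = (192, 288)
    pixel_spacing_mm: float = 1.7
    n_frames: int = 40
    frame_interval_s: float = 0.656
    center_mm: tuple[float, float] | None = None
    semi_axes_mm: tuple[float, float] = (38.0, 27.0)
    oscillation_amplitude: float = 0.05
    oscillation_period_s: float = 20.0
    emptying_fraction: float = 0.0
    respiration: RespirationSpec = field(default_factory=RespirationSpec)
    noise_sigma: float = 0.05
    n_seeds: int = 20
    seed: int = 0


@dataclass
class DuodenumSpec:
    """Duodenal phantom: a C-shaped tube with a travelling contraction ring.

    The tube of ``tube_radius_mm`` follows a spline centerline through
    ``centerline_control_mm`` (default: a 200-degree circular arc).  A
    Gaussian radius pinch of fractional ``ring_depth`` and standard
    deviation ``ring_width_mm`` travels at ``ring_speed_mm_s``, re-entering
    every ``ring_period_s``.  A smooth envelope keeps the tube ends static
    so the end caps carry zero wall velocity.
    """

    grid_shape: tuple[int, int] = (192, 288)
    pixel_spacing_mm: float = 1.7
    n_frames: int = 40
    frame_interval_s: float = 0.656
    centerline_control_mm: np.ndarray | None = None
    tube_radius_mm: float = 10.0
    ring_depth: float = 0.5
    ring_width_mm: float = 8.0
    ring_speed_mm_s: float = 8.0
    ring_period_s: float = 13.0
    respiration: RespirationSpec = field(default_factory=RespirationSpec)
    noise_sigma: float = 0.05
    n_seeds: int = 30
    seed: int = 0


@dataclass
class StudySpec:
    """A paired two-condition motility study at the original effect scale.

    Per subject, the MS3 emptying fraction under the reference condition
    is drawn from N(mean, sd); the second condition adds a within-subject
    effect N(mean difference, effect sd), so the paired design carries
    between-subject correlation.  The effect SD defaults to
    ``sqrt(sd_b^2 - sd_a^2)``, the value implied by the additive model
    when both marginal SDs are as specified.  Contraction depth of the
    duodenal ring is drawn analogously.  Defaults follow the observed
    study scale: residual means 84% vs 73% at 60 min (emptying fractions
    0.16 vs 0.27) with marginal SDs of about 13 and 15 percentage points.
    """

    n_subjects: int = 8
    conditions: tuple[str, str] = ("control", "msg")
    emptying_ms3_mean: tuple[float, float] = (0.16, 0.27)
    emptying_ms3_sd: tuple[float, float] = (0.131, 0.146)
    depth_mean: tuple[float, float] = (0.15, 0.50)
    depth_sd: tuple[float, float] = (0.10, 0.15)
    planes: tuple[int, ...] = (1, 2, 3, 4)
    plane_scale: tuple[float, ...] = (1.0, 0.9, 0.75, 0.55)
    subject_size_sd: float = 0.08
    grid_shape: tuple[int, int] = (192, 288)
    pixel_spacing_mm: float = 1.7
    n_frames: int = 40
    frame_interval_s: float = 0.656
    oscillation_amplitude: float = 0.05
    oscillation_period_s: float = 20.0
    respiration: RespirationSpec = field(default_factory=RespirationSpec)
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a paired study needs at least 2 subjects")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        for sd in (*self.emptying_ms3_sd, *self.depth_sd, self.subject_size_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if len(self.plane_scale) != len(self.planes):
            raise ValueError("plane_scale must match planes")


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Exact kinematics of a rendered phantom.

    ``boundaries`` (T, M, 2) are dense counterclockwise boundary polygons
    in mm, respiration-free (frame-0-aligned geometry); index m is the
    same material point in every frame.  ``v_normal``/``v_tangent``
    (T-1, M) are signed wall velocities between consecutive frames under
    the inward-/counterclockwise-positive convention, with ``arc_weights``
    the local arc-length elements of the later frame for boundary
    averaging.  ``resp_shift_px`` (T, 2) records the injected whole-field
    (dy, dx) pixel shift of every rendered frame.
    """

    boundaries: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray
    v_normal: np.ndarray
    v_tangent: np.ndarray
    arc_weights: np.ndarray
    resp_shift_px: np.ndarray
    frame_interval: float

    def dm_vn(self) -> float:
        """Arc-weighted mean absolute normal wall speed (mm/s)."""
        return float(np.sum(self.arc_weights * np.abs(self.v_normal))
                     / np.sum(self.arc_weights))

    def dm_vt(self) -> float:
        """Arc-weighted mean absolute tangential wall speed (mm/s)."""
        return float(np.sum(self.arc_weights * np.abs(self.v_tangent))
                     / np.sum(self.arc_weights))


def _gt_velocities(boundaries: np.ndarray, dt: float):
    """Finite-difference material wall velocities on dense boundaries,
    projected on the later frame's local orthonormal frame."""
    T, M = boundaries.shape[0], boundaries.shape[1]
    v_n = np.zeros((max(T - 1, 0), M))
    v_t = np.zeros((max(T - 1, 0), M))
    w = np.zeros((max(T - 1, 0), M))
    for p in range(1, T):
        b = boundaries[p]
        diff = np.roll(b, -1, axis=0) - np.roll(b, 1, axis=0)
        tang = diff / np.linalg.norm(diff, axis=1, keepdims=True)
        norm = np.column_stack([-tang[:, 1], tang[:, 0]])  # inward for CCW
        vel = (b - boundaries[p - 1]) / dt
        v_n[p - 1] = np.einsum("ij,ij->i", vel, norm)
        v_t[p - 1] = np.einsum("ij,ij->i", vel, tang)
        seg = np.linalg.norm(np.roll(b, -1, axis=0) - b, axis=1)
        w[p - 1] = 0.5 * (seg + np.roll(seg, 1))
    return v_n, v_t, w


# ---------------------------------------------------------------------------
# rasterization

def rasterize_polygon(
    points_mm: np.ndarray,
    grid_shape: tuple[int, int],
    pixel_spacing: tuple[float, float],
    supersample: int = _SUPERSAMPLE,
) -> np.ndarray:
    """Occupancy image of a closed polygon by supersampled scanline fill.

    Even-odd fill on a ``supersample``-times finer grid, block-averaged to
    the target grid, yields fractional occupancy in [0, 1] with soft
    (partial-volume-like) edges.  Pixel centre convention: mm coordinate
    = pixel index * spacing.
    """
    H, W = grid_shape
    sy, sx = pixel_spacing[1], pixel_spacing[0]
    ss = supersample
    hf, wf = H * ss, W * ss
    col = ss * (np.asarray(points_mm)[:, 0] / sx + 0.5) - 0.5
    row = ss * (np.asarray(points_mm)[:, 1] / sy + 0.5) - 0.5
    y1, y2 = row, np.roll(row, -1)
    x1, x2 = col, np.roll(col, -1)
    keep = y1 != y2
    y1, y2, x1, x2 = y1[keep], y2[keep], x1[keep], x2[keep]
    ys = np.arange(hf, dtype=float)[:, None]
    lo = np.minimum(y1, y2)[None, :]
    hi = np.maximum(y1, y2)[None, :]
    hit = (ys >= lo) & (ys < hi)
    t = (ys - y1[None, :]) / (y2 - y1)[None, :]
    xs = x1[None, :] + t * (x2 - x1)[None, :]
    rows_idx, edge_idx = np.nonzero(hit)
    cols = np.clip(np.ceil(xs[rows_idx, edge_idx]).astype(int), 0, wf)
    acc = np.zeros((hf, wf + 1), dtype=np.int32)
    np.add.at(acc, (rows_idx, cols), 1)
    mask = (np.cumsum(acc, axis=1)[:, :wf] & 1).astype(float)
    return mask.reshape(H, ss, W, ss).mean(axis=(1, 3))


def _respiratory_shift_px(spec_resp: RespirationSpec, times: np.ndarray) -> np.ndarray:
    """Integer (dy, dx) whole-field shift per frame (dx stays 0)."""
    dy = np.rint(spec_resp.amplitude_px
                 * np.sin(2.0 * np.pi * times / spec_resp.period_s)).astype(int)
    return np.column_stack([dy, np.zeros_like(dy)])


def _check_in_grid(points_mm: np.ndarray, grid_shape, sx: float, sy: float,
                   margin_px: float = 2.0) -> None:
    H, W = grid_shape
    x, y = points_mm[:, 0], points_mm[:, 1]
    if (x.min() < margin_px * sx or x.max() > (W - 1 - margin_px) * sx
            or y.min() < margin_px * sy or y.max() > (H - 1 - margin_px) * sy):
        raise ValueError("phantom structure exceeds the image grid")


def _render_stack(
    boundaries_mm: np.ndarray,
    resp_shift_px: np.ndarray,
    grid_shape: tuple[int, int],
    spacing: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    T = boundaries_mm.shape[0]
    frames = np.empty((T, *grid_shape))
    step = max(1, boundaries_mm.shape[1] // _RENDER_VERTICES)
    for t in range(T):
        poly = boundaries_mm[t, ::step] + np.array(
            [resp_shift_px[t, 1] * spacing, resp_shift_px[t, 0] * spacing])
        _check_in_grid(poly, grid_shape, spacing, spacing)
        occ = rasterize_polygon(poly, grid_shape, (spacing, spacing))
        frame = _FOREGROUND * occ
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma * _FOREGROUND,
                                       size=frame.shape)
        frames[t] = np.clip(frame, 0.0, None)
    return frames


def _subsample_seeds(boundary: np.ndarray, n_seeds: int) -> np.ndarray:
    idx = (np.arange(n_seeds) * boundary.shape[0]) // n_seeds
    return boundary[idx]


def seeds_in_raw_frame(
    seeds: list[SeedContour], gt: GroundTruth, pixel_spacing: float
) -> list[SeedContour]:
    """Translate stabilized-frame seeds onto the raw (respiring) frames.

    Seed files describe the wall in the frame-0-aligned geometry; adding
    the injected per-frame shift gives the wall as it appears in the
    unstabilized stack, which is what an analysis without stabilization
    would outline.
    """
    out = []
    for s in seeds:
        shift = gt.resp_shift_px[s.frame_index]
        delta = np.array([shift[1] * pixel_spacing, shift[0] * pixel_spacing])
        out.append(SeedContour(points=s.points + delta,
                               frame_index=s.frame_index,
                               structure_label=s.structure_label))
    return out


# ---------------------------------------------------------------------------
# fundus phantom

def make_fundus_phantom(
    spec: FundusSpec,
) -> tuple[FrameStack, list[SeedContour], GroundTruth]:
    """Render a gastric-fundus phantom with exact ground truth.

    The ellipse boundary is scaled isotropically so the enclosed area
    follows the prescribed emptying/oscillation law exactly; ground-truth
    areas are analytic (pi * a * b * scale).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.grid_shape
    s = spec.pixel_spacing_mm
    a, b = spec.semi_axes_mm
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    center = np.array(spec.center_mm if spec.center_mm is not None
                      else [(W - 1) * s / 2.0, (H - 1) * s / 2.0])
    T = spec.n_frames
    times = np.arange(T) * spec.frame_interval_s
    area_scale = (1.0 - spec.emptying_fraction) * (
        1.0 + spec.oscillation_amplitude
        * np.sin(2.0 * np.pi * times / spec.oscillation_period_s))
    if np.any(area_scale <= 0):
        raise ValueError("area scale must stay positive")
    M = 4096
    theta = np.linspace(0.0, 2.0 * np.pi, M, endpoint=False)
    unit = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    boundaries = center + np.sqrt(area_scale)[:, None, None] * unit[None]
    areas = np.pi * a * b * area_scale
    centroids = np.tile(center, (T, 1))
    resp = _respiratory_shift_px(spec.respiration, times)
    frames = _render_stack(boundaries, resp, spec.grid_shape, s,
                           spec.noise_sigma, rng)
    stack = FrameStack(frames=frames, pixel_spacing_x=s, pixel_spacing_y=s,
                       frame_interval=spec.frame_interval_s)
    seeds = [SeedContour(points=_subsample_seeds(boundaries[t], spec.n_seeds),
                         frame_index=t, structure_label="fundus")
             for t in range(T)]
    v_n, v_t, w = _gt_velocities(boundaries, spec.frame_interval_s)
    gt = GroundTruth(boundaries=boundaries, areas=areas, centroids=centroids,
                     v_normal=v_n, v_tangent=v_t, arc_weights=w,
                     resp_shift_px=resp, frame_interval=spec.frame_interval_s)
    return stack, seeds, gt


# ---------------------------------------------------------------------------
# duodenum phantom

def _default_centerline(spec: DuodenumSpec) -> np.ndarray:
    """C-shaped arc centered in the grid; the arc radius shrinks on small
    grids so the tube (plus respiration margin) still fits."""
    H, W = spec.grid_shape
    s = spec.pixel_spacing_mm
    center = np.array([(W - 1) * s / 2.0, (H - 1) * s / 2.0])
    extent = min((H - 1) * s, (W - 1) * s)
    arc_radius = min(32.0, 0.5 * extent - spec.tube_radius_mm
                     - (abs(spec.respiration.amplitude_px) + 4.0) * s)
    if arc_radius <= spec.tube_radius_mm:
        raise ValueError("grid too small for the duodenal tube")
    phi = np.deg2rad(np.linspace(120.0, -80.0, 9))
    return center + arc_radius * np.column_stack([np.cos(phi), np.sin(phi)])


def _centerline_geometry(control: np.ndarray, n_side: int):
    """Arc-length-parameterized centerline with unit tangents/normals."""
    chord = np.linalg.norm(np.diff(control, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, control, axis=0)
    u = np.linspace(0.0, t[-1], 20 * n_side + 1)
    dense = spline(u)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    L = arc[-1]
    s_eq = np.linspace(0.0, L, n_side)
    u_eq = np.interp(s_eq, arc, u)
    pts = spline(u_eq)
    d = spline(u_eq, 1)
    tang = d / np.linalg.norm(d, axis=1, keepdims=True)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    return pts, tang, norm, s_eq, L


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_duodenum_phantom(
    spec: DuodenumSpec,
) -> tuple[FrameStack, list[SeedContour], GroundTruth]:
    """Render a duodenal-tube phantom with a travelling contraction ring.

    The wall radius along the centerline is
    ``r(s, t) = R * (1 - depth * w(s) * exp(-(s - c(t))^2 / (2 sigma^2)))``
    with an envelope ``w(s)`` that vanishes at both tube ends (static end
    caps) and ring centre ``c(t)`` advancing at the prescribed speed,
    re-entering each period.  Wall velocities are purely radial by
    construction, so the ground-truth tangential velocity is zero
    everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    control = (np.asarray(spec.centerline_control_mm, dtype=float)
               if spec.centerline_control_mm is not None
               else _default_centerline(spec))
    n_side, n_cap = 512, 64
    cline, ctang, cnorm, s_eq, L = _centerline_geometry(control, n_side)
    R = spec.tube_radius_mm
    sigma = spec.ring_width_mm
    if R <= 0 or sigma <= 0:
        raise ValueError("tube radius and ring width must be positive")
    if sigma > L:
        raise ValueError(f"ring width {sigma} mm exceeds tube length {L:.1f} mm")
    if not 0 <= spec.ring_depth < 1:
        raise ValueError("ring depth fraction must be in [0, 1)")
    # envelope: zero at the ends, cosine-smooth ramp over [2*sigma, 4*sigma]
    ramp0 = _smoothstep((s_eq - 2.0 * sigma) / (2.0 * sigma))
    ramp1 = _smoothstep((L - s_eq - 2.0 * sigma) / (2.0 * sigma))
    envelope = ramp0 * ramp1

    T = spec.n_frames
    times = np.arange(T) * spec.frame_interval_s
    alphas = np.linspace(0.0, np.pi, n_cap + 2)[1:-1]
    boundaries = np.empty((T, 2 * n_side + 2 * n_cap, 2))
    radii = np.empty((T, n_side))
    for t in range(T):
        c_t = spec.ring_speed_mm_s * (times[t] % spec.ring_period_s) - 3.0 * sigma
        pinch = spec.ring_depth * envelope * np.exp(
            -0.5 * ((s_eq - c_t) / sigma) ** 2)
        r = R * (1.0 - pinch)
        radii[t] = r
        side_a = cline + r[:, None] * cnorm
        side_b = (cline - r[:, None] * cnorm)[::-1]
        cap_end = (cline[-1]
                   + R * np.cos(alphas)[:, None] * cnorm[-1]
                   + R * np.sin(alphas)[:, None] * ctang[-1])
        cap_start = (cline[0]
                     - R * np.cos(alphas)[:, None] * cnorm[0]
                     - R * np.sin(alphas)[:, None] * ctang[0])
        boundaries[t] = np.vstack([side_a, cap_end, side_b, cap_start])
    reversed_order = signed_area(boundaries[0]) < 0
    if reversed_order:
        boundaries = boundaries[:, ::-1]

    areas = np.array([abs(signed_area(boundaries[t])) for t in range(T)])
    centroids = np.stack([_poly_centroid(boundaries[t]) for t in range(T)])
    resp = _respiratory_shift_px(spec.respiration, times)
    frames = _render_stack(boundaries, resp, spec.grid_shape,
                           spec.pixel_spacing_mm, spec.noise_sigma, rng)
    stack = FrameStack(frames=frames, pixel_spacing_x=spec.pixel_spacing_mm,
                       pixel_spacing_y=spec.pixel_spacing_mm,
                       frame_interval=spec.frame_interval_s)
    seeds = [SeedContour(points=_subsample_seeds(boundaries[t], spec.n_seeds),
                         frame_index=t, structure_label="duodenum")
             for t in range(T)]
    # wall motion is purely radial in the centerline frame: inward-positive
    # V_N = -dr/dt on both sides, exactly zero tangential velocity, static
    # end caps.  Arc weights come from the later frame's boundary.
    rate = -np.diff(radii, axis=0) / spec.frame_interval_s  # (T-1, n_side)
    zeros_cap = np.zeros((max(T - 1, 0), n_cap))
    v_n = np.concatenate([rate, zeros_cap, rate[:, ::-1], zeros_cap], axis=1)
    if reversed_order:
        v_n = v_n[:, ::-1]
    v_t = np.zeros_like(v_n)
    w = np.zeros_like(v_n)
    for p in range(1, T):
        seg = np.linalg.norm(np.roll(boundaries[p], -1, axis=0) - boundaries[p],
                             axis=1)
        w[p - 1] = 0.5 * (seg + np.roll(seg, 1))
    gt = GroundTruth(boundaries=boundaries, areas=areas, centroids=centroids,
                     v_normal=v_n, v_tangent=v_t, arc_weights=w,
                     resp_shift_px=resp, frame_interval=spec.frame_interval_s)
    return stack, seeds, gt


def _poly_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    return np.array([np.sum((x + xn) * cross), np.sum((y + yn) * cross)]) / (6.0 * a)


# ---------------------------------------------------------------------------
# study generation

def draw_subject_parameters(spec: StudySpec, seed: int | None = None) -> list[dict]:
    """Draw per-subject true emptying fractions and contraction depths.

    The second condition's value is the first condition's value plus a
    within-subject effect drawn from N(difference of means, effect SD)
    with effect SD = sqrt(sd_b^2 - sd_a^2) — the additive paired model
    consistent with both stated marginal SDs — floored at 20% of sd_b.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cond_a, cond_b = spec.conditions

    def paired_draw(mean_ab, sd_ab, lo, hi):
        base = rng.normal(mean_ab[0], sd_ab[0])
        # effect SD implied by the additive model; floored at 20% of the
        # second condition's marginal SD so it vanishes with it
        eff_sd = float(np.sqrt(max(sd_ab[1] ** 2 - sd_ab[0] ** 2,
                                   (0.2 * sd_ab[1]) ** 2)))
        other = base + rng.normal(mean_ab[1] - mean_ab[0], eff_sd)
        return float(np.clip(base, lo, hi)), float(np.clip(other, lo, hi))

    subjects = []
    for i in range(spec.n_subjects):
        e_a, e_b = paired_draw(spec.emptying_ms3_mean, spec.emptying_ms3_sd,
                               0.0, 0.90)
        d_a, d_b = paired_draw(spec.depth_mean, spec.depth_sd, 0.0, 0.90)
        size = float(np.clip(rng.normal(1.0, spec.subject_size_sd), 0.7, 1.3))
        subjects.append({
            "subject": f"S{i + 1:02d}",
            "size_scale": size,
            cond_a: {"emptying_ms3": e_a, "depth": d_a},
            cond_b: {"emptying_ms3": e_b, "depth": d_b},
        })
    return subjects


_SCAN_EMPTYING = {"MS1": 0.0, "MS2": 0.5, "MS3": 1.0}  # fraction of MS3 loss


def make_study(spec: StudySpec, out_dir: Path | str) -> dict:
    """Generate a full study tree on disk and return its layout manifest.

    Per subject x condition: three scans (MS1/MS2/MS3), each with one
    fundus stack per plane plus one duodenum stack, written as TIFF +
    sidecar with seed-contour files; true per-subject parameters are
    stored in ``ground_truth.json`` alongside.  The manifest
    (``manifest.json``) maps every stack/seed path and is returned as a
    dict (see :func:`gimotion.io.read_study_layout`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = draw_subject_parameters(spec)
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = iter(ss.generate_state(10 * spec.n_subjects * 2 * 3
                                         * (len(spec.planes) + 1)) >> 1)
    entries: dict = {}
    truth: dict = {}
    base_axes = np.array([38.0, 27.0])
    for sub in params:
        sid = sub["subject"]
        entries[sid] = {}
        truth[sid] = {"size_scale": sub["size_scale"]}
        for cond in spec.conditions:
            entries[sid][cond] = {}
            p = sub[cond]
            truth[sid][cond] = {
                **p,
                "residual_pct": {scan: 100.0 * (1.0 - frac * p["emptying_ms3"])
                                 for scan, frac in _SCAN_EMPTYING.items()},
            }
            for scan, frac in _SCAN_EMPTYING.items():
                scan_dir = out_dir / sid / cond / scan
                scan_dir.mkdir(parents=True, exist_ok=True)
                fundus_entry = {}
                for plane, pscale in zip(spec.planes, spec.plane_scale):
                    axes = base_axes * pscale * sub["size_scale"]
                    fspec = FundusSpec(
                        grid_shape=spec.grid_shape,
                        pixel_spacing_mm=spec.pixel_spacing_mm,
                        n_frames=spec.n_frames,
                        frame_interval_s=spec.frame_interval_s,
                        semi_axes_mm=tuple(axes),
                        oscillation_amplitude=spec.oscillation_amplitude,
                        oscillation_period_s=spec.oscillation_period_s,
                        emptying_fraction=frac * p["emptying_ms3"],
                        respiration=spec.respiration,
                        noise_sigma=spec.noise_sigma,
                        seed=int(next(child_seeds)),
                    )
                    stack, seeds, _ = make_fundus_phantom(fspec)
                    stack.plane_id = plane
                    stack.scan_id = scan
                    stack_path = scan_dir / f"fundus_p{plane}.tif"
                    write_frame_stack(stack, stack_path)
                    seeds_path = scan_dir / f"fundus_p{plane}.seeds.txt"
                    write_contour_series(seeds, seeds_path)
                    fundus_entry[str(plane)] = {
                        "stack": str(stack_path.relative_to(out_dir)),
                        "seeds": str(seeds_path.relative_to(out_dir)),
                    }
                dspec = DuodenumSpec(
                    grid_shape=spec.grid_shape,
                    pixel_spacing_mm=spec.pixel_spacing_mm,
                    n_frames=spec.n_frames,
                    frame_interval_s=spec.frame_interval_s,
                    ring_depth=p["depth"],
                    respiration=spec.respiration,
                    noise_sigma=spec.noise_sigma,
                    seed=int(next(child_seeds)),
                )
                dstack, dseeds, _ = make_duodenum_phantom(dspec)
                dstack.scan_id = scan
                dstack_path = scan_dir / "duodenum.tif"
                write_frame_stack(dstack, dstack_path)
                dseeds_path = scan_dir / "duodenum.seeds.txt"
                write_contour_series(dseeds, dseeds_path)
                entries[sid][cond][scan] = {
                    "fundus": fundus_entry,
                    "duodenum": {
                        "stack": str(dstack_path.relative_to(out_dir)),
                        "seeds": str(dseeds_path.relative_to(out_dir)),
                    },
                }
    manifest = {
        "subjects": [s["subject"] for s in params],
        "conditions": list(spec.conditions),
        "scans": list(_SCAN_EMPTYING),
        "planes": [int(p) for p in spec.planes],
        "frame_interval_s": spec.frame_interval_s,
        "entries": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest
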
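"""End-to-end study orchestration.

For every subject, condition and motility scan the pipeline stabilizes
the cine stacks (optional, on by default), resamples the seed outlines
into 100-point wall contours, computes the fundus residual-volume index
and the duodenal motility indices, and finally runs paired condition
contrasts across subjects.  All stages are deterministic given the
inputs and configuration.

Seed outlines are drawn on *stabilized* frames (as in the original
workflow, where stabilization precedes manual outlining); set
``seed_frame = "raw"`` in the configuration when outlines follow the
unstabilized frames, in which case the recovered cumulative shifts are
subtracted from the contours.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contouring, metrics
from .core import (
    ContourSeries,
    FrameStack,
    GastricVolumeIndex,
    MotilityIndices,
    SeedContour,
)
from .io import StudyLayout, read_frame_stack, read_seed_contours, write_metrics_table
from .stabilization import stabilize_stack

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "load_config",
    "SubjectResult",
    "StudyResult",
    "analyze_stack",
    "run_subject",
    "run_study",
]


@dataclass
class AnalysisConfig:
    """Resolved pipeline configuration.

    roi : (r0, r1, c0, c1) or None
        Stabilization region of interest; None selects the largest
        centred rectangle leaving a ``search_radius`` + 2 px margin.
    seed_frame : {"stabilized", "raw"}
        Coordinate frame the seed outlines were drawn in.
    """

    stabilize: bool = True
    search_radius: int = 10
    roi: tuple[int, int, int, int] | None = None
    n_points: int = 100
    seed_frame: str = "stabilized"
    planes: tuple[int, ...] | None = None
    subset: tuple[str, ...] = ()
    seed: int = 0

    def resolve_roi(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        if self.roi is not None:
            return self.roi
        margin = self.search_radius + 2
        h, w = shape
        if h <= 2 * margin or w <= 2 * margin:
            raise ValueError(f"frame {shape} too small for search radius "
                             f"{self.search_radius}")
        return (margin, h - margin, margin, w - margin)


def load_config(path: Path | str) -> AnalysisConfig:
    """Read a ``key = value`` (optionally ``[analysis]``-sectioned) file."""
    cp = configparser.ConfigParser()
    text = Path(path).read_text()
    if not text.lstrip().startswith("["):
        text = "[analysis]\n" + text
    cp.read_string(text)
    sec = cp["analysis"] if cp.has_section("analysis") else cp[cp.sections()[0]]
    cfg = AnalysisConfig()
    if "stabilize" in sec:
        cfg.stabilize = sec.getboolean("stabilize")
    if "search_radius" in sec:
        cfg.search_radius = sec.getint("search_radius")
    if "roi" in sec and sec["roi"].strip().lower() != "auto":
        cfg.roi = tuple(int(v) for v in sec["roi"].split(","))  # type: ignore[assignment]
    if "n_points" in sec:
        cfg.n_points = sec.getint("n_points")
    if "seed_frame" in sec:
        cfg.seed_frame = sec["seed_frame"].strip()
    if "planes" in sec:
        cfg.planes = tuple(int(v) for v in sec["planes"].split(","))
    if "subset" in sec and sec["subset"].strip():
        cfg.subset = tuple(s.strip() for s in sec["subset"].split(","))
    if "seed" in sec:
        cfg.seed = sec.getint("seed")
    return cfg


@dataclass
class StackAnalysis:
    """Per-stack results: contour series, per-frame measures, indices."""

    series: ContourSeries
    areas: np.ndarray
    centroids: np.ndarray
    dgy: np.ndarray
    indices: MotilityIndices
    shift_trace: object | None = None


def _correct_seeds(seeds: list[SeedContour], cumulative: np.ndarray,
                   sx: float, sy: float) -> list[SeedContour]:
    out = []
    for s in seeds:
        cum = cumulative[s.frame_index]
        delta = np.array([cum[1] * sx, cum[0] * sy])
        out.append(SeedContour(points=s.points - delta, frame_index=s.frame_index,
                               structure_label=s.structure_label))
    return out


def analyze_stack(
    stack: FrameStack,
    seeds: list[SeedContour],
    config: AnalysisConfig,
    compute_velocities: bool | None = None,
) -> StackAnalysis:
    """Stabilize (optionally), contour and quantify one cine stack.

    Velocities are computed for duodenal series by default; the fundus
    indices stop at DM(A)/DM(G).
    """
    trace = None
    if config.stabilize and stack.n_frames > 1:
        roi = config.resolve_roi(stack.shape)
        _, trace, _ = stabilize_stack(stack, roi, config.search_radius)
        if config.seed_frame == "raw":
            seeds = _correct_seeds(seeds, trace.cumulative,
                                   stack.pixel_spacing_x, stack.pixel_spacing_y)
    seeds = sorted(seeds, key=lambda s: s.frame_index)
    contours = [contouring.resample_contour(s, config.n_points) for s in seeds]
    series = contouring.build_series(contours, stack.frame_interval)
    areas = metrics.area_series(series)
    centroids = metrics.centroid_series(series)
    label = series.structure_label
    if compute_velocities is None:
        compute_velocities = label == "duodenum"
    dm_vn = dm_vt = None
    if compute_velocities and series.n_frames >= 2:
        field_v = metrics.wall_velocities(series)
        dm_vn, dm_vt = metrics.dm_velocity(field_v)
    idx = MotilityIndices(
        dm_area=metrics.dm_area(areas) if len(areas) >= 2 else 0.0,
        dm_gravity=metrics.dm_gravity(centroids) if len(centroids) >= 2 else 0.0,
        dm_vn=dm_vn,
        dm_vt=dm_vt,
        scan_id=stack.scan_id,
        structure_label=label,
    )
    return StackAnalysis(series=series, areas=areas, centroids=centroids,
                         dgy=metrics.dgy_trace(centroids), indices=idx,
                         shift_trace=trace)


@dataclass
class SubjectResult:
    """All per-scan results for one subject."""

    subject: str
    residual: dict[str, GastricVolumeIndex] = field(default_factory=dict)
    duodenum: dict[str, dict[str, MotilityIndices]] = field(default_factory=dict)
    fundus_dm_area: dict[str, dict[str, float]] = field(default_factory=dict)
    dgy: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def run_subject(layout: StudyLayout, subject: str,
                config: AnalysisConfig) -> SubjectResult:
    """Run the full per-subject analysis across conditions and scans.

    Raises a ``RuntimeError`` naming subject, condition, scan and plane
    whenever a stage fails, so the study loop can skip just this subject.
    """
    res = SubjectResult(subject=subject)
    planes = list(config.planes) if config.planes is not None else layout.planes
    entry = layout.entries[subject]
    for cond, scans in entry.items():
        per_plane_areas: dict[str, dict[int, np.ndarray]] = {}
        res.duodenum[cond] = {}
        res.fundus_dm_area[cond] = {}
        res.dgy[cond] = {}
        for scan in layout.scans:
            if scan not in scans:
                raise RuntimeError(f"{subject}/{cond}: scan {scan} missing")
            node = scans[scan]
            per_plane_areas[scan] = {}
            res.fundus_dm_area[cond][scan] = {}
            for plane in planes:
                ref = node["fundus"].get(str(plane)) or node["fundus"].get(plane)
                if ref is None:
                    raise RuntimeError(
                        f"{subject}/{cond}/{scan}: plane {plane} missing")
                try:
                    stack = read_frame_stack(layout.resolve(ref["stack"]))
                    seeds = read_seed_contours(layout.resolve(ref["seeds"]))
                    sa = analyze_stack(stack, seeds, config)
                except Exception as exc:
                    raise RuntimeError(
                        f"{subject}/{cond}/{scan}/plane{plane}: {exc}") from exc
                per_plane_areas[scan][plane] = sa.areas
                res.fundus_dm_area[cond][scan][plane] = sa.indices.dm_area
            duo = node.get("duodenum")
            if duo is not None:
                try:
                    dstack = read_frame_stack(layout.resolve(duo["stack"]))
                    dseeds = read_seed_contours(layout.resolve(duo["seeds"]))
                    dsa = analyze_stack(dstack, dseeds, config)
                except Exception as exc:
                    raise RuntimeError(f"{subject}/{cond}/{scan}/duodenum: {exc}") from exc
                dsa.indices.scan_id = scan
                res.duodenum[cond][scan] = dsa.indices
                res.dgy[cond][scan] = dsa.dgy
        res.residual[cond] = metrics.gastric_residual(per_plane_areas)
    return res


@dataclass
class StudyResult:
    """Across-subject paired comparisons and per-subject tables."""

    subjects: list[str]
    conditions: list[str]
    paired: pd.DataFrame
    residual_table: pd.DataFrame
    subject_results: dict[str, SubjectResult]
    subset_paired: pd.DataFrame | None = None


def _paired_rows(values: dict[str, dict[str, float]], subjects: list[str],
                 cond_a: str, cond_b: str, metric: str, scan: str,
                 units: str) -> dict | None:
    a = [values[s][cond_a] for s in subjects if cond_a in values.get(s, {})]
    b = [values[s][cond_b] for s in subjects if cond_b in values.get(s, {})]
    if len(a) != len(subjects) or len(b) != len(subjects) or len(a) < 2:
        return None
    test = metrics.compare_paired(a, b)
    return {
        "metric": metric, "scan": scan, "units": units,
        f"mean_{cond_a}": float(np.mean(a)), f"sd_{cond_a}": float(np.std(a, ddof=1)),
        f"mean_{cond_b}": float(np.mean(b)), f"sd_{cond_b}": float(np.std(b, ddof=1)),
        "t": test.t, "p": test.p, "n": test.n, "degenerate": test.degenerate,
    }


def _study_tests(results: dict[str, SubjectResult], subjects: list[str],
                 conditions: list[str], scans: list[str]) -> pd.DataFrame:
    cond_a, cond_b = conditions[:2]
    rows = []
    for scan in scans:
        if scan != "MS1":
            vals = {s: {c: results[s].residual[c].percent[scan]
                        for c in conditions if c in results[s].residual
                        and scan in results[s].residual[c].percent}
                    for s in subjects}
            row = _paired_rows(vals, subjects, cond_a, cond_b,
                               "residual", scan, "%")
            if row:
                rows.append(row)
        for name, units, getter in (
            ("DM_A", "%", lambda ix: ix.dm_area),
            ("DM_G", "mm", lambda ix: ix.dm_gravity),
            ("DM_VN", "mm/s", lambda ix: ix.dm_vn),
            ("DM_VT", "mm/s", lambda ix: ix.dm_vt),
        ):
            vals = {}
            for s in subjects:
                vals[s] = {}
                for c in conditions:
                    ix = results[s].duodenum.get(c, {}).get(scan)
                    if ix is not None and getter(ix) is not None:
                        vals[s][c] = getter(ix)
            row = _paired_rows(vals, subjects, cond_a, cond_b,
                               f"duodenum_{name}", scan, units)
            if row:
                rows.append(row)
    return pd.DataFrame(rows)


def run_study(layout: StudyLayout, config: AnalysisConfig,
              out_dir: Path | str | None = None) -> StudyResult:
    """Analyse every paired subject and contrast the two conditions.

    Subjects missing a condition are excluded with a logged warning, as
    is any subject whose analysis fails.  When ``out_dir`` is given,
    ``metrics.csv``, ``residual.csv`` and ``paired_tests.csv`` plus
    DG_Y-trace and residual-line plots are written there.
    """
    conditions = layout.conditions
    results: dict[str, SubjectResult] = {}
    for subject in sorted(layout.paired_subjects()):
        try:
            results[subject] = run_subject(layout, subject, config)
        except RuntimeError as exc:
            logger.warning("subject %s excluded: %s", subject, exc)
    unpaired = sorted(set(layout.subjects) - set(results))
    for s in unpaired:
        logger.warning("subject %s excluded: unpaired or failed", s)
    subjects = sorted(results)
    if len(subjects) < 2:
        raise ValueError("fewer than 2 complete paired subjects")
    paired = _study_tests(results, subjects, conditions, layout.scans)

    rows = []
    for s in subjects:
        for c in conditions:
            for scan in layout.scans:
                rows.append({"subject": s, "condition": c, "scan": scan,
                             "residual_pct": results[s].residual[c].percent.get(scan)})
    residual_table = pd.DataFrame(rows)

    subset_paired = None
    if config.subset:
        subset = [s for s in config.subset if s in results]
        if len(subset) >= 2:
            subset_paired = _study_tests(results, sorted(subset), conditions,
                                         layout.scans)

    study = StudyResult(subjects=subjects, conditions=list(conditions),
                        paired=paired, residual_table=residual_table,
                        subject_results=results, subset_paired=subset_paired)
    if out_dir is not None:
        _write_outputs(study, layout, config, Path(out_dir))
    return study


def _write_outputs(study: StudyResult, layout: StudyLayout,
                   config: AnalysisConfig, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    study.paired.to_csv(out_dir / "paired_tests.csv", index=False,
                        lineterminator="\n")
    study.residual_table.to_csv(out_dir / "residual.csv", index=False,
                                lineterminator="\n")
    if study.subset_paired is not None:
        study.subset_paired.to_csv(out_dir / "paired_tests_subset.csv",
                                   index=False, lineterminator="\n")
    records = []
    for s, res in study.subject_results.items():
        for c, scans in res.duodenum.items():
            for scan, ix in scans.items():
                for metric_name, value, units in (
                    ("DM_A", ix.dm_area, "%"),
                    ("DM_G", ix.dm_gravity, "mm"),
                    ("DM_VN", ix.dm_vn, "mm/s"),
                    ("DM_VT", ix.dm_vt, "mm/s"),
                ):
                    if value is not None:
                        records.append({"subject": s, "condition": c,
                                        "scan": scan, "plane": "",
                                        "metric": f"duodenum_{metric_name}",
                                        "value": value, "units": units})
    write_metrics_table(records, out_dir / "metrics.csv")

    # residual lines, one per subject (MS1 -> MS3), per condition
    fig, axes = plt.subplots(1, len(study.conditions), figsize=(8, 4),
                             sharey=True)
    for ax, cond in zip(np.atleast_1d(axes), study.conditions):
        for s in study.subjects:
            pct = [study.subject_results[s].residual[cond].percent[sc]
                   for sc in layout.scans]
            ax.plot(range(len(layout.scans)), pct, marker="o", label=s)
        ax.set_xticks(range(len(layout.scans)), layout.scans)
        ax.set_title(cond)
        ax.set_ylabel("residual volume (%)")
    fig.tight_layout()
    fig.savefig(out_dir / "residual_lines.png", dpi=110)
    plt.close(fig)

    # DG_Y traces in the last scan
    last = layout.scans[-1]
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in study.subjects:
        for cond in study.conditions:
            trace = study.subject_results[s].dgy.get(cond, {}).get(last)
            if trace is not None:
                ax.plot(np.arange(len(trace)) * layout.frame_interval_s, trace,
                        alpha=0.7, label=f"{s}/{cond}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("DG_Y (mm)")
    ax.set_title(f"duodenal centroid Y-shift, {last}")
    fig.tight_layout()
    fig.savefig(out_dir / "dgy_traces.png", dpi=110)
    plt.close(fig)
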
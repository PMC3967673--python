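"""Reading and writing of image stacks, contour files and metrics tables.

File formats
------------
* **Image stacks** — multi-page TIFF (one page per frame) or a directory of
  single-frame DICOM files, accompanied by a plain-text sidecar
  (``<stem>.meta``, ``key = value`` lines) carrying pixel spacing,
  frame interval, plane and scan ids whenever the container itself lacks
  them.  Pixel spacing is always external metadata and never guessed.
* **Contours** — line-oriented text, one record (frame) per line::

      <frame_index> <label> x1,y1 x2,y2 ...

  with coordinates in mm, written to 6 decimals.
* **Metrics** — CSV with header ``subject,condition,scan,plane,metric,
  value,units`` in deterministic row order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import ContourSeries, FrameStack, SeedContour, WallContour

__all__ = [
    "read_frame_stack",
    "write_frame_stack",
    "read_seed_contours",
    "write_contour_series",
    "write_metrics_table",
    "read_sidecar",
    "write_sidecar",
    "StudyLayout",
    "read_study_layout",
]

_SIDECAR_FLOAT_KEYS = ("pixel_spacing_x", "pixel_spacing_y", "frame_interval")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def write_sidecar(path: Path | str, meta: Mapping[str, object]) -> None:
    """Write a ``key = value`` sidecar file."""
    Path(path).write_text("\n".join(f"{k} = {v}" for k, v in meta.items()) + "\n")


def read_sidecar(path: Path | str) -> dict[str, str]:
    """Parse a ``key = value`` sidecar file into a string dict."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed sidecar line in {path}: {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _meta_from_sidecar(meta: Mapping[str, str], source: str) -> dict[str, object]:
    parsed: dict[str, object] = {}
    for key in _SIDECAR_FLOAT_KEYS:
        if key not in meta:
            raise ValueError(f"sidecar for {source} is missing required field {key!r}")
        parsed[key] = float(meta[key])
    parsed["plane_id"] = int(meta.get("plane_id", 1))
    parsed["scan_id"] = meta.get("scan_id", "MS1")
    return parsed


def read_frame_stack(path: Path | str, format_hint: str | None = None) -> FrameStack:
    """Read a cine image stack.

    Parameters
    ----------
    path : path
        Multi-page TIFF file or a directory of single-frame DICOM files.
    format_hint : {"tiff", "dicom", None}
        Force a container format; by default inferred from the path.

    Returns
    -------
    FrameStack
        Frames in acquisition order, intensities unmodified, metadata
        populated from the container or its sidecar.

    Raises
    ------
    ValueError
        If pixel spacing or frame interval is missing or contradictory,
        or if frames have mixed dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "dicom" if path.is_dir() else "tiff"
    if fmt == "tiff":
        return _read_tiff_stack(path)
    if fmt == "dicom":
        return _read_dicom_stack(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


def _read_tiff_stack(path: Path) -> FrameStack:
    frames = tifffile.imread(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a 2D+t grayscale stack, got shape {frames.shape}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"{path}: TIFF stacks require a sidecar {sidecar.name} with "
            "pixel_spacing_x, pixel_spacing_y and frame_interval"
        )
    meta = _meta_from_sidecar(read_sidecar(sidecar), str(path))
    return FrameStack(frames=frames, **meta)


def _read_dicom_stack(path: Path) -> FrameStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise ValueError(f"{path}: no DICOM files found")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    frames = []
    spacing = None
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        if frames and arr.shape != frames[0].shape:
            raise ValueError(f"{path}: mixed frame dimensions in DICOM series")
        frames.append(arr)
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            ps = (float(ps[0]), float(ps[1]))  # (row, col) = (y, x)
            if spacing is not None and spacing != ps:
                raise ValueError(f"{path}: contradictory PixelSpacing across series")
            spacing = ps
    sidecar = _sidecar_path(path if path.suffix else path / "series")
    side = read_sidecar(sidecar) if sidecar.exists() else {}
    if spacing is None:
        if "pixel_spacing_x" not in side or "pixel_spacing_y" not in side:
            raise ValueError(f"{path}: pixel spacing absent from DICOM headers and sidecar")
        spacing = (float(side["pixel_spacing_y"]), float(side["pixel_spacing_x"]))
    if "frame_interval" in side:
        interval = float(side["frame_interval"])
    else:
        ft = getattr(datasets[0], "FrameTime", None)  # milliseconds
        if ft is None:
            raise ValueError(f"{path}: frame_interval absent from DICOM headers and sidecar")
        interval = float(ft) / 1000.0
    return FrameStack(
        frames=np.stack(frames),
        pixel_spacing_x=spacing[1],
        pixel_spacing_y=spacing[0],
        frame_interval=interval,
        plane_id=int(side.get("plane_id", 1)),
        scan_id=side.get("scan_id", "MS1"),
    )


def write_frame_stack(stack: FrameStack, path: Path | str) -> None:
    """Write a stack as multi-page TIFF (float32) plus metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    write_sidecar(
        _sidecar_path(path),
        {
            "pixel_spacing_x": repr(stack.pixel_spacing_x),
            "pixel_spacing_y": repr(stack.pixel_spacing_y),
            "frame_interval": repr(stack.frame_interval),
            "plane_id": stack.plane_id,
            "scan_id": stack.scan_id,
        },
    )


def read_seed_contours(path: Path | str) -> list[SeedContour]:
    """Read a contour text file as validated seed contours, order preserved."""
    seeds: list[SeedContour] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"{path}:{lineno}: malformed contour record")
        frame_index = int(tokens[0])
        label = tokens[1]
        try:
            pts = np.array([[float(c) for c in tok.split(",")] for tok in tokens[2:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad coordinate token ({exc})") from None
        try:
            seeds.append(SeedContour(points=pts, frame_index=frame_index, structure_label=label))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return seeds


def write_contour_series(
    contours: ContourSeries | Sequence[SeedContour] | Sequence[WallContour],
    path: Path | str,
    label: str | None = None,
) -> None:
    """Write contours in the line-oriented text format (6-decimal mm).

    Accepts a :class:`ContourSeries` (frames numbered from 0) or any
    sequence of seed/wall contours carrying their own frame indices.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records: list[tuple[int, str, np.ndarray]] = []
    if isinstance(contours, ContourSeries):
        for t in range(contours.n_frames):
            records.append((t, contours.structure_label, contours.points[t]))
    else:
        for c in contours:
            records.append((c.frame_index, c.structure_label, c.points))
    lines = []
    for frame_index, lab, pts in records:
        coords = " ".join(f"{x:.6f},{y:.6f}" for x, y in np.asarray(pts, dtype=float))
        lines.append(f"{frame_index} {label or lab} {coords}")
    path.write_text("\n".join(lines) + "\n")


from dataclasses import dataclass, field


@dataclass
class StudyLayout:
    """Resolved study tree: subjects x conditions x scans x planes.

    ``entries[subject][condition][scan]`` holds ``{"fundus": {plane:
    {"stack": path, "seeds": path}}, "duodenum": {"stack": ..., "seeds":
    ...}}`` with paths relative to ``root``.
    """

    root: Path
    subjects: list[str]
    conditions: list[str]
    scans: list[str]
    planes: list[int]
    frame_interval_s: float
    entries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "MS1" not in self.scans:
            raise ValueError("MS1 must be present to anchor normalization")

    def resolve(self, relpath: str) -> Path:
        return self.root / relpath

    def paired_subjects(self) -> list[str]:
        """Subjects with every condition complete."""
        return [s for s in self.subjects
                if all(c in self.entries.get(s, {}) for c in self.conditions)]


def read_study_layout(path: Path | str) -> StudyLayout:
    """Load a study manifest (``manifest.json`` or its directory)."""
    import json

    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    data = json.loads(path.read_text())
    return StudyLayout(
        root=path.parent,
        subjects=list(data["subjects"]),
        conditions=list(data["conditions"]),
        scans=list(data["scans"]),
        planes=[int(p) for p in data["planes"]],
        frame_interval_s=float(data.get("frame_interval_s", 0.656)),
        entries=data["entries"],
    )


def write_metrics_table(records: Iterable[Mapping[str, object]], path: Path | str) -> None:
    """Write a metrics CSV with deterministic row order.

    Each record must carry ``subject, condition, scan, plane, metric,
    value, units``.  Rows are sorted by (subject, condition, scan, plane,
    metric) so re-runs on identical input are byte-identical.
    """
    cols = ["subject", "condition", "scan", "plane", "metric", "value", "units"]
    df = pd.DataFrame(list(records), columns=cols)
    if len(df):
        df = df.sort_values(["subject", "condition", "scan", "plane", "metric"],
                            kind="mergesort").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
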
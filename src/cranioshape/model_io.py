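"""Point-cloud, landmark and report I/O.

Point clouds are vertex sets in millimetres; faces, colours and normals in
mesh files are discarded. Supported carriers: PLY (ASCII or binary
little-endian, via trimesh), OBJ (``v`` records, via trimesh), XYZ
(whitespace separated) and CSV (headerless ``x,y,z``; a non-numeric header
row is detected and skipped). Landmarks travel in a JSON sidecar with keys
``preauricular_left``, ``preauricular_right`` and ``glabella`` — mesh
formats have no standard landmark slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .errors import FormatError, GeometryError, SchemaError

POINT_FORMATS = ("ply", "obj", "xyz", "csv")

LANDMARK_KEYS = ("preauricular_left", "preauricular_right", "glabella")


@dataclass
class Landmarks:
    """The three manually identified registration points (mm).

    ``glabella`` is the point between the eyes. The three points must be
    pairwise distinct and non-collinear (triangle area > 1 mm^2), otherwise
    the anatomical frame is undefined.
    """

    preauricular_left: np.ndarray
    preauricular_right: np.ndarray
    glabella: np.ndarray

    def __post_init__(self) -> None:
        for name in LANDMARK_KEYS:
            v = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise SchemaError(f"landmark {name!r} must be a finite 3-vector")
            setattr(self, name, v)
        area = 0.5 * np.linalg.norm(
            np.cross(
                self.preauricular_left - self.glabella,
                self.preauricular_right - self.glabella,
            )
        )
        if area <= 1.0:
            raise GeometryError(
                "landmarks are coincident or collinear "
                f"(triangle area {area:.3g} mm^2 <= 1 mm^2)"
            )

    def as_dict(self) -> dict[str, list[float]]:
        return {k: np.asarray(getattr(self, k)).tolist() for k in LANDMARK_KEYS}


@dataclass
class HeadModel:
    """A cranial-surface point cloud (mm) with optional landmarks."""

    id: str
    points: np.ndarray
    landmarks: Landmarks | None = None
    is_aligned: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise FormatError(f"points must be N x 3, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise FormatError("point cloud contains non-finite coordinates")
        self.points = pts

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in POINT_FORMATS:
        raise FormatError(f"unsupported point-cloud format {fmt!r}; expected one of {POINT_FORMATS}")
    return fmt


def _parse_delimited(path: Path, delimiter: str | None) -> np.ndarray:
    rows: list[list[float]] = []
    text = path.read_text()
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = [c for c in (line.split(delimiter) if delimiter else line.split()) if c != ""]
        try:
            vals = [float(c) for c in cells]
        except ValueError:
            if not rows and i == 0:
                continue  # non-numeric header row
            raise FormatError(f"{path.name}: non-numeric cell in row {i + 1}: {line!r}") from None
        if len(vals) < 3:
            raise FormatError(f"{path.name}: row {i + 1} has {len(vals)} columns, need 3")
        rows.append(vals[:3])
    if not rows:
        raise FormatError(f"{path.name}: no coordinate rows found")
    return np.asarray(rows, dtype=float)


def read_point_cloud(path: str | Path, format: str | None = None, id: str | None = None) -> HeadModel:
    """Read a head point cloud; vertices only, order preserved, units mm."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt in ("ply", "obj"):
        try:
            loaded = trimesh.load(str(path), file_type=fmt, process=False)
        except Exception as exc:  # trimesh raises assorted types on malformed files
            raise FormatError(f"{path.name}: could not parse as {fmt.upper()}: {exc}") from exc
        vertices = np.asarray(loaded.vertices, dtype=float)
        if vertices.size == 0:
            raise FormatError(f"{path.name}: no vertices found")
        points = vertices
    elif fmt == "xyz":
        points = _parse_delimited(path, delimiter=None)
    else:  # csv
        points = _parse_delimited(path, delimiter=",")
    return HeadModel(id=id or path.stem, points=points)


def write_point_cloud(model: HeadModel, path: str | Path, format: str | None = None) -> None:
    """Write the point cloud; the inverse of :func:`read_point_cloud`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        trimesh.PointCloud(model.points).export(str(path), file_type="ply")
    elif fmt == "obj":
        with open(path, "w") as fh:
            for x, y, z in model.points:
                fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
    elif fmt == "xyz":
        np.savetxt(path, model.points, fmt="%.9g", delimiter=" ")
    else:
        np.savetxt(path, model.points, fmt="%.9g", delimiter=",")


def read_landmarks(path: str | Path) -> Landmarks:
    """Read the three-landmark JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such landmark file: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path.name}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path.name}: landmark file must be a JSON object")
    missing = [k for k in LANDMARK_KEYS if k not in payload]
    if missing:
        raise SchemaError(f"{path.name}: missing landmark keys {missing}")
    return Landmarks(**{k: payload[k] for k in LANDMARK_KEYS})


def write_landmarks(landmarks: Landmarks, path: str | Path) -> None:
    Path(path).write_text(json.dumps(landmarks.as_dict(), indent=1))


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize one analysis report (JSON) or a cohort of them (CSV).

    JSON round-trips losslessly through ``AnalysisReport.from_dict``; the
    CSV form is one flat row per head with a fixed column schema.
    """
    from .report import AnalysisReport, reports_to_frame  # deferred: avoids an import cycle

    path = Path(path)
    fmt = format.lower()
    if fmt == "json":
        if not isinstance(report, AnalysisReport):
            raise SchemaError("JSON report output expects a single AnalysisReport")
        path.write_text(report.to_json())
    elif fmt == "csv":
        reports = [report] if isinstance(report, AnalysisReport) else list(report)
        reports_to_frame(reports).to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported report format {format!r}")
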
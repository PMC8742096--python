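"""Calliper-style cranial measurements and deformation indexes.

Reproduces, from the aligned point cloud, the measurements a clinician
takes with a cephalometer and tape: the maximum cranial perimeter CP in a
band of planes containing the ear-to-ear (Y) direction, the two oblique
diagonals a and b at +/-30 degrees to the anteroposterior axis within that
maximal slice, head length c and width d — plus the 3D-only split of each
diagonal into frontal and back halves, which yields the anterior and
posterior asymmetry indexes (AAI, PAI) that calliper measurements cannot
provide.

Index definitions (all lengths mm, signed where asymmetric):

    CI   = 100 * d / c          cephalic index (width over length, percent)
    AI   = a - b                cranial vault asymmetry (CVAI)
    OCLR = 100 * a / b          oblique cranial length ratio (percent)
    AAI  = a_frontal - b_frontal
    PAI  = a_back - b_back

Chords are measured through the anatomical origin (the inter-preauricular
midpoint), which makes the frontal/back split exact: a = a_frontal + a_back
and AI = AAI + PAI hold identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point, Polygon

from .errors import CoverageError, GeometryError
from .model_io import HeadModel

#: Perimeter-plane search constants: tilt about Y (deg), offset step and
#: slab half-width (mm). A ~530-point cloud needs a finite slab to populate
#: a slice; these are recorded in every report.
TILT_RANGE_DEG = 30.0
TILT_STEP_DEG = 1.0
OFFSET_STEP_MM = 2.0
SLAB_HALF_WIDTH_MM = 4.0
MIN_SLAB_POINTS = 10
MIN_CLOUD_POINTS = 100

#: Azimuth of the oblique diagonals from the anteroposterior axis.
OBLIQUE_ANGLE_DEG = 30.0


@dataclass(frozen=True)
class PerimeterPlane:
    """Slice plane containing the Y direction: normal (sin a, 0, cos a), offset mm."""

    tilt_deg: float
    offset: float

    @property
    def normal(self) -> np.ndarray:
        a = np.deg2rad(self.tilt_deg)
        return np.array([np.sin(a), 0.0, np.cos(a)])

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane axes: e1 (anteroposterior-ish), e2 = +Y (patient's left)."""
        a = np.deg2rad(self.tilt_deg)
        return np.array([np.cos(a), 0.0, -np.sin(a)]), np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class SlicePolygon:
    """Convex-hull outline of the maximal slice, CCW viewed from above."""

    plane: PerimeterPlane
    vertices_2d: np.ndarray  # (k, 2) in the (e1, e2) chart; world origin -> (0, 0)
    perimeter: float

    @property
    def vertices_3d(self) -> np.ndarray:
        e1, e2 = self.plane.basis
        u, v = self.vertices_2d[:, 0], self.vertices_2d[:, 1]
        return self.plane.offset * self.plane.normal + np.outer(u, e1) + np.outer(v, e2)


@dataclass(frozen=True)
class ObliqueChords:
    a: float
    b: float
    a_frontal: float
    a_back: float
    b_frontal: float
    b_back: float


@dataclass(frozen=True)
class AnthropometricMeasures:
    """The full calliper-analogue measurement set (mm)."""

    a: float
    b: float
    c: float
    d: float
    cp: float
    a_frontal: float
    a_back: float
    b_frontal: float
    b_back: float
    perimeter_plane: PerimeterPlane

    def as_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d, "cp": self.cp,
            "a_frontal": self.a_frontal, "a_back": self.a_back,
            "b_frontal": self.b_frontal, "b_back": self.b_back,
            "perimeter_plane_tilt_deg": self.perimeter_plane.tilt_deg,
            "perimeter_plane_offset": self.perimeter_plane.offset,
        }


@dataclass(frozen=True)
class IndexReport:
    """Deformation indexes for one head.

    ``f22`` is the raw spherical-harmonic asymmetry coefficient; ``f22_x10``
    is the 10x display scale used when plotting it against mm-valued
    indexes. Screening always compares the raw value.
    """

    CI: float
    AI: float
    OCLR: float
    OCLR100: float
    AAI: float
    PAI: float
    f22: float
    f22_x10: float
    lmax_used: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("CI", "AI", "OCLR", "OCLR100", "AAI", "PAI", "f22", "f22_x10", "lmax_used")}


def max_perimeter_slice(model: HeadModel | np.ndarray) -> tuple[PerimeterPlane, SlicePolygon, float]:
    """Find the maximum-perimeter slice of the head.

    Searches planes containing the Y direction, tilted about Y on a 1-degree
    grid within +/-30 degrees of horizontal, offsets on a 2 mm grid spanning
    the cloud; points within a +/-4 mm slab are projected into the plane and
    the perimeter of their 2D convex hull scored. Returns the maximising
    plane, its hull polygon and the cranial perimeter CP.
    """
    pts = model.points if isinstance(model, HeadModel) else np.asarray(model, dtype=float)
    if len(pts) < MIN_CLOUD_POINTS:
        raise CoverageError(
            f"{len(pts)} points are too few to populate perimeter slices "
            f"(need >= {MIN_CLOUD_POINTS})"
        )
    candidates: list[tuple[float, float, float]] = []  # (perimeter, tilt, offset)
    tilts = np.arange(-TILT_RANGE_DEG, TILT_RANGE_DEG + 0.5 * TILT_STEP_DEG, TILT_STEP_DEG)
    for tilt in tilts:
        plane0 = PerimeterPlane(tilt_deg=float(tilt), offset=0.0)
        n = plane0.normal
        e1, e2 = plane0.basis
        s = pts @ n
        offsets = np.arange(s.min(), s.max() + OFFSET_STEP_MM, OFFSET_STEP_MM)
        uv_all = np.column_stack([pts @ e1, pts @ e2])
        for off in offsets:
            mask = np.abs(s - off) <= SLAB_HALF_WIDTH_MM
            if int(mask.sum()) < MIN_SLAB_POINTS:
                continue
            try:
                hull = ConvexHull(uv_all[mask])
            except QhullError:
                continue
            # in 2D, ConvexHull.area is the perimeter
            candidates.append((float(hull.area), float(tilt), float(off)))
    if not candidates:
        raise CoverageError("no slice plane collected enough points for a perimeter")
    # Near-ties (within 0.1% of the maximum, e.g. a near-spherical head) are
    # broken deterministically toward the least-tilted, most central plane.
    cp_max = max(c[0] for c in candidates)
    cp, tilt, off = min(
        (c for c in candidates if c[0] >= cp_max * (1.0 - 1e-3)),
        key=lambda c: (abs(c[1]), c[1], abs(c[2]), c[2]),
    )
    plane = PerimeterPlane(tilt_deg=tilt, offset=off)
    e1, e2 = plane.basis
    s = pts @ plane.normal
    uv = np.column_stack([pts @ e1, pts @ e2])[np.abs(s - off) <= SLAB_HALF_WIDTH_MM]
    hull = ConvexHull(uv)
    poly = SlicePolygon(plane=plane, vertices_2d=uv[hull.vertices], perimeter=cp)
    return plane, poly, cp


def _ray_length(poly: Polygon, azimuth_deg: float) -> float:
    """Distance from the in-plane origin to the polygon boundary along a ray."""
    theta = np.deg2rad(azimuth_deg)
    reach = 4.0 * max(abs(b) for b in poly.bounds)
    ray = LineString([(0.0, 0.0), (reach * np.cos(theta), reach * np.sin(theta))])
    hit = poly.exterior.intersection(ray)
    if hit.is_empty:
        raise GeometryError(f"ray at azimuth {azimuth_deg} deg does not reach the slice boundary")

    def _coords(g):
        if hasattr(g, "geoms"):
            for sub in g.geoms:
                yield from _coords(sub)
        else:
            yield from g.coords

    return float(max(np.hypot(x, y) for x, y in _coords(hit)))


def oblique_chords(polygon: SlicePolygon) -> ObliqueChords:
    """Oblique diagonals at +/-30 degrees from the anteroposterior axis.

    ``a`` runs front-left to back-right (+30 degrees azimuth, +Y being the
    patient's left); ``b`` front-right to back-left. Each is split at the
    anatomical origin into its frontal and back half-chords.
    """
    poly = Polygon(polygon.vertices_2d)
    if not poly.contains(Point(0.0, 0.0)):
        raise GeometryError("anatomical origin lies outside the maximal slice polygon; "
                            "chords through the origin are undefined")
    a_frontal = _ray_length(poly, +OBLIQUE_ANGLE_DEG)
    a_back = _ray_length(poly, +OBLIQUE_ANGLE_DEG + 180.0)
    b_frontal = _ray_length(poly, -OBLIQUE_ANGLE_DEG)
    b_back = _ray_length(poly, -OBLIQUE_ANGLE_DEG + 180.0)
    return ObliqueChords(
        a=a_frontal + a_back, b=b_frontal + b_back,
        a_frontal=a_frontal, a_back=a_back, b_frontal=b_frontal, b_back=b_back,
    )


def head_length_width(model: HeadModel | np.ndarray, polygon: SlicePolygon) -> tuple[float, float]:
    """Head length c (X extent of the maximal slice) and width d (Y extent of the cloud)."""
    pts = model.points if isinstance(model, HeadModel) else np.asarray(model, dtype=float)
    if len(pts) == 0 or len(polygon.vertices_2d) == 0:
        raise GeometryError("empty cloud or slice polygon")
    c = float(np.ptp(polygon.vertices_3d[:, 0]))
    d = float(np.ptp(pts[:, 1]))
    return c, d


def compute_measures(model: HeadModel | np.ndarray) -> AnthropometricMeasures:
    """Run the full measurement chain on an aligned cloud."""
    plane, poly, cp = max_perimeter_slice(model)
    chords = oblique_chords(poly)
    c, d = head_length_width(model, poly)
    return AnthropometricMeasures(
        a=chords.a, b=chords.b, c=c, d=d, cp=cp,
        a_frontal=chords.a_frontal, a_back=chords.a_back,
        b_frontal=chords.b_frontal, b_back=chords.b_back,
        perimeter_plane=plane,
    )


def compute_indexes(m: AnthropometricMeasures, f22: float, lmax: int) -> IndexReport:
    """Deformation indexes from the measurement set plus the SH coefficient."""
    if m.b <= 0 or m.c <= 0:
        raise ValueError("measures must be positive to form ratio indexes")
    oclr = 100.0 * m.a / m.b
    return IndexReport(
        CI=100.0 * m.d / m.c,
        AI=m.a - m.b,
        OCLR=oclr,
        OCLR100=oclr - 100.0,
        AAI=m.a_frontal - m.b_frontal,
        PAI=m.a_back - m.b_back,
        f22=f22,
        f22_x10=10.0 * f22,
        lmax_used=lmax,
    )
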
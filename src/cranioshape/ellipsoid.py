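"""Ideal cranial ellipsoid: algebraic least-squares fit and orthogonal distances.

The ideal (undeformed) cranial shape is modelled as a triaxial ellipsoid
whose axes are parallel to the anatomical frame, so the reference surface is
symmetric about the anteroposterior axis and is itself blind to the
asymmetry being measured. The fit is the linear (algebraic) least-squares
solution of

    A x^2 + B y^2 + C z^2 + D x + E y + F z = 1

over all cloud points, converted to a centre and three semi-axes by
completing the square. Head-to-ellipsoid separation is the signed orthogonal
(foot-point) distance, positive outside the surface, computed by a
safeguarded Newton iteration on the single Lagrange parameter of the
closest-point conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import FitError, NumericError
from .model_io import HeadModel

_AXIS_NAMES = ("x", "y", "z")

#: Newton tolerance on the Lagrange-parameter step and iteration cap.
FOOT_POINT_TOL = 1e-10
FOOT_POINT_MAX_ITER = 100


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned triaxial ellipsoid: centre (mm) and semi-axes (mm)."""

    center: np.ndarray
    semi_axes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, dtype=float).reshape(3))
        if not np.all(self.semi_axes > 0):
            raise FitError(f"semi-axes must be positive, got {self.semi_axes}")

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """sum(((p - c)/a)^2) - 1; zero on the surface, negative inside."""
        w = (np.atleast_2d(points) - self.center) / self.semi_axes
        return np.einsum("ij,ij->i", w, w) - 1.0

    def surface_point(self, lat_deg, lon_deg) -> np.ndarray:
        """Map the geocentric (lat, lon) chart direction onto the surface.

        The returned point is the intersection of the ray from the centre in
        the (lat, lon) direction with the surface (not a foot point).
        """
        lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
        lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
        u = np.stack(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat) * np.ones_like(lon)],
            axis=-1,
        )
        scale = 1.0 / np.sqrt(np.sum((u / self.semi_axes) ** 2, axis=-1))
        return self.center + u * scale[..., None]


class FootPointResult(NamedTuple):
    """Closest surface point of one query point with diagnostics."""

    foot_point: np.ndarray
    normal: np.ndarray
    signed_distance: float
    iterations: int
    converged: bool
    ambiguous: bool = False


class SurfaceSample(NamedTuple):
    """One head point expressed in the ellipsoid chart (degrees, mm)."""

    lat: float
    lon: float
    distance: float


class SurfaceSamples:
    """Column-wise container of :class:`SurfaceSample` triples."""

    def __init__(self, lat: np.ndarray, lon: np.ndarray, distance: np.ndarray):
        self.lat = np.asarray(lat, dtype=float)
        self.lon = np.asarray(lon, dtype=float)
        self.distance = np.asarray(distance, dtype=float)
        if not (self.lat.shape == self.lon.shape == self.distance.shape):
            raise ValueError("lat, lon and distance must have identical shapes")

    def __len__(self) -> int:
        return self.lat.size

    def __iter__(self) -> Iterator[SurfaceSample]:
        for la, lo, d in zip(self.lat, self.lon, self.distance):
            yield SurfaceSample(float(la), float(lo), float(d))

    @classmethod
    def from_iterable(cls, samples) -> "SurfaceSamples":
        if isinstance(samples, cls):
            return samples
        triples = [(s.lat, s.lon, s.distance) for s in samples]
        arr = np.asarray(triples, dtype=float).reshape(-1, 3)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


def fit_ellipsoid(points: np.ndarray) -> Ellipsoid:
    """Fit the axis-aligned ellipsoid by linear least squares.

    Requires at least 9 non-coplanar points. Raises :class:`FitError`,
    naming the offending axis, when the quadratic coefficients are not all
    positive (the cloud is degenerate or not ellipsoidal).
    """
    pts = check_array(points, dtype=float, ensure_min_samples=9, ensure_min_features=3)
    if pts.shape[1] != 3:
        raise FitError(f"expected N x 3 points, got {pts.shape}")
    design = np.column_stack([pts**2, pts])
    rank = np.linalg.matrix_rank(design, tol=1e-8 * max(1.0, float(np.abs(design).max())))
    if rank < 6:
        raise FitError("degenerate point cloud: ellipsoid design matrix is rank deficient "
                       f"(rank {rank} < 6); points may be coplanar")
    coef, *_ = np.linalg.lstsq(design, np.ones(len(pts)), rcond=None)
    quad, lin = coef[:3], coef[3:]
    for name, q in zip(_AXIS_NAMES, quad):
        if q <= 0:
            raise FitError(f"non-positive quadratic coefficient along the {name} axis: "
                           "the least-squares quadric is not an ellipsoid")
    center = -lin / (2.0 * quad)
    gamma = 1.0 + np.sum(quad * center**2)
    if gamma <= 0:
        raise FitError("degenerate quadric: completing the square gives a non-positive constant")
    return Ellipsoid(center=center, semi_axes=np.sqrt(gamma / quad))


def _foot_points_vectorized(points: np.ndarray, e: Ellipsoid):
    """Foot points for many query points at once.

    Solves, per point, F(t) = sum_i a_i^2 w_i^2 / (a_i^2 + t)^2 - 1 = 0 with
    w = p - c; the foot point is q_i = c_i + a_i^2 w_i / (a_i^2 + t). F is
    strictly decreasing on (-a_min^2, inf), so a bracketed Newton iteration
    with bisection fallback is globally convergent.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    a2 = e.semi_axes**2
    a2min = float(a2.min())
    w = P - e.center
    outside = e.implicit(P) > 0.0

    n = len(P)
    L = np.linalg.norm(e.semi_axes * w, axis=1)  # F(L - a2min) <= 0 always
    t_lo = np.where(outside, 0.0, -a2min * (1.0 - 1e-12))
    t_hi = np.maximum(L - a2min, t_lo) + 1.0

    def F(t):
        return np.sum((e.semi_axes * w) ** 2 / (a2 + t[:, None]) ** 2, axis=1) - 1.0

    def dF(t):
        return -2.0 * np.sum(a2 * w**2 / (a2 + t[:, None]) ** 3, axis=1)

    # Medial-axis degeneracy: interior point whose component along every
    # shortest axis vanishes, so F has no root above -a2min.
    ambiguous = (~outside) & (F(t_lo) < 0.0)

    t = 0.5 * (t_lo + t_hi)
    converged = np.zeros(n, dtype=bool)
    iterations = np.zeros(n, dtype=int)
    active = ~ambiguous
    for it in range(FOOT_POINT_MAX_ITER):
        if not active.any():
            break
        f = F(t)
        shrink_hi = active & (f < 0.0)
        shrink_lo = active & (f >= 0.0)
        t_hi = np.where(shrink_hi, t, t_hi)
        t_lo = np.where(shrink_lo, t, t_lo)
        step = np.where(active, f / dF(t), 0.0)
        t_new = t - step
        bad = active & ((t_new <= t_lo) | (t_new >= t_hi) | ~np.isfinite(t_new))
        t_new = np.where(bad, 0.5 * (t_lo + t_hi), t_new)
        done = active & (np.abs(t_new - t) <= FOOT_POINT_TOL * (1.0 + np.abs(t_new)))
        iterations[active] = it + 1
        t = np.where(active, t_new, t)
        converged |= done
        active &= ~done
    if active.any():
        idx = int(np.flatnonzero(active)[0])
        raise NumericError(
            f"foot-point iteration failed to converge for point {idx} "
            f"(p={P[idx]}, t={t[idx]:.6g}, F={F(t[[idx]])[0]:.3g})"
        )

    q = e.center + a2 * w / (a2 + t[:, None])
    if ambiguous.any():
        # Deterministic choice: foot point displaced along the shortest axis.
        k = int(np.argmin(a2))
        other = [i for i in range(3) if i != k]
        for idx in np.flatnonzero(ambiguous):
            qi = e.center.copy()
            for i in other:
                denom = a2[i] - a2min
                qi[i] = e.center[i] + (a2[i] * w[idx, i] / denom if denom > 0 else 0.0)
            arg = 1.0 - sum(((qi[i] - e.center[i]) / e.semi_axes[i]) ** 2 for i in other)
            qi[k] = e.center[k] + e.semi_axes[k] * np.sqrt(max(arg, 0.0))
            q[idx] = qi
            converged[idx] = True

    normal = (q - e.center) / a2
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    dist = np.linalg.norm(P - q, axis=1)
    signed = np.where(outside, dist, -dist)
    return q, normal, signed, iterations, converged, ambiguous


def foot_point(p: np.ndarray, e: Ellipsoid) -> FootPointResult:
    """Orthogonal projection of one point onto the ellipsoid surface."""
    q, normal, signed, iters, conv, amb = _foot_points_vectorized(np.asarray(p, float).reshape(1, 3), e)
    return FootPointResult(q[0], normal[0], float(signed[0]), int(iters[0]), bool(conv[0]), bool(amb[0]))


def signed_distances(points: np.ndarray, e: Ellipsoid) -> np.ndarray:
    """Signed orthogonal distances (mm, + outside) for many points."""
    return _foot_points_vectorized(points, e)[2]


def surface_samples(model: HeadModel | np.ndarray, e: Ellipsoid) -> SurfaceSamples:
    """Chart every head point on the ellipsoid: one (lat, lon, distance) per point.

    Latitude/longitude are geocentric angles of the foot point about the
    ellipsoid centre (Z toward the vertex is the pole); longitude is wrapped
    to [0, 360). The chart is only an indexing of the reference surface.
    """
    pts = model.points if isinstance(model, HeadModel) else np.atleast_2d(np.asarray(model, float))
    try:
        q, _, signed, *_ = _foot_points_vectorized(pts, e)
    except NumericError as exc:
        raise NumericError(f"surface_samples: {exc}") from exc
    rel = q - e.center
    lat = np.degrees(np.arctan2(rel[:, 2], np.hypot(rel[:, 0], rel[:, 1])))
    lon = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
    return SurfaceSamples(lat=lat, lon=lon, distance=signed)


class EllipsoidFitter(TransformerMixin, BaseEstimator):
    """Estimator wrapper: fit the ideal ellipsoid, chart points against it.

    ``fit(X)`` takes an (n_points, 3) mm cloud and exposes ``center_``,
    ``semi_axes_`` and ``ellipsoid_``; ``transform(X)`` returns an
    (n_points, 3) array of (lat_deg, lon_deg, signed_distance_mm) columns —
    the scattered chart that the spherical-harmonic regression consumes.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.ellipsoid_ = fit_ellipsoid(X)
        self.center_ = self.ellipsoid_.center
        self.semi_axes_ = self.ellipsoid_.semi_axes
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "ellipsoid_")
        X = check_array(X, dtype=float)
        s = surface_samples(X, self.ellipsoid_)
        return np.column_stack([s.lat, s.lon, s.distance])
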
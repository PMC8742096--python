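"""Real spherical-harmonic expansion of the head-to-ellipsoid distance field.

The signed orthogonal distances d(lat, lon) sampled at the ~530 scattered
cap points are modelled as a truncated series

    d(lat, lon) = sum_{l=0}^{lmax} sum_{m=-l}^{l} f_l^m Y_l^m(lat, lon)

fitted by ordinary least squares. The basis is the geodesy-standard
4pi-normalized real convention without the Condon-Shortley phase:
Y_0^0 = 1 everywhere and the squared basis functions integrate to 4pi over
the sphere. The normalization is immutable — the DP screening threshold on
f_2^-2 is only meaningful under a fixed convention, so every expansion
carries the tag.

f_2^-2 varies as sin(2*lon) around the equator: it splits the head into
four alternating quadrants (two posterior, two anterior) and weighs
diagonally opposed surplus/deficit — exactly the deformational-plagiocephaly
pattern of one flattened posterior quadrant with optional contralateral
compensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy.special import lpmv
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .ellipsoid import SurfaceSamples
from .errors import IllConditionedError, InsufficientDataError

NORMALIZATION = "4π-normalized real, no Condon–Shortley phase"

#: Condition-number ceiling for the unregularized scattered-data design.
CONDITION_LIMIT = 1e8

#: Degree/order of the plagiocephaly asymmetry coefficient.
ASYMMETRY_DEGREE = 2
ASYMMETRY_ORDER = -2

DEFAULT_LMAX = 4
DEFAULT_SWEEP = tuple(range(2, 11))


def degree_order_pairs(lmax: int) -> list[tuple[int, int]]:
    """Coefficient storage order: (l, m) lexicographic, m from -l to l."""
    return [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]


def _legendre_norm(l: int, m: int) -> float:
    # sqrt((2 - delta_m0) (2l+1) (l-m)!/(l+m)!), computed in log space
    delta = 1.0 if m == 0 else 2.0
    return np.sqrt(delta * (2 * l + 1) * np.exp(lgamma(l - m + 1) - lgamma(l + m + 1)))


def basis_value(l: int, m: int, lat, lon):
    """Evaluate Y_l^m (4pi-normalized real, no CS phase) at degrees lat/lon.

    m >= 0 pairs with cos(m*lon), m < 0 with sin(|m|*lon). Vectorized over
    lat/lon.
    """
    if l < 0 or abs(m) > l:
        raise ValueError(f"invalid degree/order (l={l}, m={m}): need 0 <= |m| <= l")
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    am = abs(m)
    # scipy's lpmv includes the Condon-Shortley (-1)^m; strip it.
    plm = (-1.0) ** am * lpmv(am, l, np.sin(lat))
    norm = _legendre_norm(l, am)
    if m >= 0:
        val = norm * plm * np.cos(am * lon)
    else:
        val = norm * plm * np.sin(am * lon)
    return val if np.ndim(val) else float(val)


def design_matrix(lat, lon, lmax: int) -> np.ndarray:
    """(n, (lmax+1)^2) scattered-data design matrix in storage order."""
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    return np.column_stack([basis_value(l, m, lat, lon) for l, m in degree_order_pairs(lmax)])


@dataclass(frozen=True)
class SHExpansion:
    """Fitted real spherical-harmonic coefficients up to ``lmax``."""

    lmax: int
    coefficients: np.ndarray  # ((lmax+1)^2,) in storage order
    rmse: float
    n_samples: int
    ridge: float = 0.0
    normalization: str = field(default=NORMALIZATION)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float).reshape(-1)
        expected = (self.lmax + 1) ** 2
        if coef.size != expected:
            raise ValueError(f"lmax={self.lmax} needs {expected} coefficients, got {coef.size}")
        if self.normalization != NORMALIZATION:
            raise ValueError(f"normalization tag is immutable: {NORMALIZATION!r}")
        object.__setattr__(self, "coefficients", coef)

    def coefficient(self, l: int, m: int) -> float:
        """f_l^m by degree and order."""
        if abs(m) > l or l > self.lmax:
            raise ValueError(f"(l={l}, m={m}) outside expansion (lmax={self.lmax})")
        return float(self.coefficients[l * l + (m + l)])

    @property
    def f22(self) -> float:
        """The DP asymmetry coefficient f_2^-2."""
        return self.coefficient(ASYMMETRY_DEGREE, ASYMMETRY_ORDER)

    def to_table(self) -> pd.DataFrame:
        pairs = degree_order_pairs(self.lmax)
        return pd.DataFrame(
            {"l": [p[0] for p in pairs], "m": [p[1] for p in pairs], "coefficient": self.coefficients}
        )


class SphericalHarmonicsRegression(RegressorMixin, BaseEstimator):
    """Scattered-data least-squares spherical-harmonic fit.

    Parameters
    ----------
    lmax : int
        Truncation degree; (lmax+1)^2 coefficients are estimated.
    ridge : float
        Optional Tikhonov penalty for partial-coverage clouds (cap sampling
        that omits the head base mildly ill-conditions high degrees).
        Default 0 (ordinary least squares); any nonzero value used is
        recorded in the resulting expansion.

    ``fit(X, y)`` takes X = (n, 2) of (lat_deg, lon_deg) and y = signed
    distances (mm); ``predict(X)`` evaluates the truncated series.
    """

    def __init__(self, lmax: int = DEFAULT_LMAX, ridge: float = 0.0):
        self.lmax = lmax
        self.ridge = ridge

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape[1] != 2:
            raise ValueError(f"X must be (n, 2) of (lat, lon) degrees, got {X.shape}")
        n_coef = (self.lmax + 1) ** 2
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if len(y) < n_coef:
            raise InsufficientDataError(
                f"{len(y)} samples cannot determine {n_coef} coefficients (lmax={self.lmax})"
            )
        G = design_matrix(X[:, 0], X[:, 1], self.lmax)
        if self.ridge:
            A = G.T @ G + self.ridge * np.eye(n_coef)
            coef = np.linalg.solve(A, G.T @ y)
        else:
            sv = np.linalg.svd(G, compute_uv=False)
            cond = np.inf if sv[-1] == 0 else sv[0] / sv[-1]
            if cond > CONDITION_LIMIT:
                raise IllConditionedError(
                    f"design matrix condition number {cond:.3g} exceeds {CONDITION_LIMIT:.0e}; "
                    "samples are too clustered or coverage too partial for this lmax — "
                    "spread samples or set a ridge penalty"
                )
            coef, *_ = np.linalg.lstsq(G, y, rcond=None)
        resid = y - G @ coef
        self.coef_ = coef
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.n_features_in_ = 2
        self.expansion_ = SHExpansion(
            lmax=self.lmax, coefficients=coef, rmse=self.rmse_, n_samples=len(y), ridge=self.ridge
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return design_matrix(X[:, 0], X[:, 1], self.lmax) @ self.coef_


def expand(samples, lmax: int, ridge: float = 0.0) -> SHExpansion:
    """Least-squares expansion of a scattered (lat, lon, distance) sample set."""
    s = SurfaceSamples.from_iterable(samples)
    reg = SphericalHarmonicsRegression(lmax=lmax, ridge=ridge)
    reg.fit(np.column_stack([s.lat, s.lon]), s.distance)
    return reg.expansion_


def reconstruct(expansion: SHExpansion, lat, lon):
    """Evaluate the truncated series at (lat, lon) degrees."""
    lat_a = np.atleast_1d(np.asarray(lat, dtype=float))
    lon_a = np.atleast_1d(np.asarray(lon, dtype=float))
    val = design_matrix(lat_a, lon_a, expansion.lmax) @ expansion.coefficients
    return float(val[0]) if np.ndim(lat) == 0 and np.ndim(lon) == 0 else val


def expansion_rmse(expansion: SHExpansion, samples) -> float:
    """Root-mean-square residual of the expansion against a sample set."""
    s = SurfaceSamples.from_iterable(samples)
    if len(s) == 0:
        raise ValueError("cannot compute an RMSE over zero samples")
    resid = s.distance - reconstruct(expansion, s.lat, s.lon)
    return float(np.sqrt(np.mean(resid**2)))


def coefficient_vs_lmax(
    samples,
    lmax_list=DEFAULT_SWEEP,
    l: int = ASYMMETRY_DEGREE,
    m: int = ASYMMETRY_ORDER,
    ridge: float = 0.0,
) -> dict[int, tuple[float, float]]:
    """Refit independently per lmax; map lmax -> (f_l^m, training RMSE)."""
    out: dict[int, tuple[float, float]] = {}
    for lm in lmax_list:
        exp = expand(samples, lmax=int(lm), ridge=ridge)
        out[int(lm)] = (exp.coefficient(l, m), exp.rmse)
    return out
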
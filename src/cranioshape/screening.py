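"""Threshold screening for deformational plagiocephaly and group statistics.

Two independent screening routes are implemented:

* the classical index rule — a head is flagged DP when any asymmetry index
  exceeds 4 mm in magnitude (strictly) or the OCLR leaves the 94–106 %
  normal band (bounds inclusive normal). The cephalic index outside 75–95 %
  raises an informational scaphocephaly/brachycephaly flag that does not
  enter the DP call;
* the spherical-harmonic rule — DP when |f_2^-2| (at the default lmax = 4,
  fixed 4π real normalization) strictly exceeds 0.42. The sign of f_2^-2
  only encodes the flattened side (negative right, positive left).

Group comparisons mirror the clinical evaluation: per parameter, absolute
values per group, Shapiro–Wilk normality and Levene homoscedasticity checks
(reported, not gating), and a pooled-variance two-sided Student t-test,
ranked by ascending p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .anthropometry import IndexReport
from .errors import DegenerateDataError, SampleSizeError

HEALTHY = "Healthy"
DP = "DP"


@dataclass(frozen=True)
class ScreeningConfig:
    """Clinical normal ranges; defaults follow standard practice.

    ``asym_threshold``: abnormal iff |index| strictly > threshold (mm).
    ``oclr_normal`` / ``ci_normal``: percent intervals, bounds inclusive
    normal. ``f22_threshold``: strict bound on |f_2^-2| at ``lmax_default``.
    """

    asym_threshold: float = 4.0
    oclr_normal: tuple[float, float] = (94.0, 106.0)
    ci_normal: tuple[float, float] = (75.0, 95.0)
    f22_threshold: float = 0.42
    lmax_default: int = 4

    def __post_init__(self) -> None:
        if self.asym_threshold <= 0 or self.f22_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for lo, hi in (self.oclr_normal, self.ci_normal):
            if not lo < hi:
                raise ValueError("normal intervals must be ordered (lo < hi)")

    def as_dict(self) -> dict:
        return {
            "asym_threshold": self.asym_threshold,
            "oclr_normal": list(self.oclr_normal),
            "ci_normal": list(self.ci_normal),
            "f22_threshold": self.f22_threshold,
            "lmax_default": self.lmax_default,
        }


@dataclass(frozen=True)
class ScreeningResult:
    """Per-index flags and the two Healthy/DP calls for one head."""

    ai_flag: bool
    aai_flag: bool
    pai_flag: bool
    oclr_flag: bool
    ci_flag: bool  # informational only: scaphocephaly/brachycephaly range
    f22_flag: bool
    classification_indexes: str
    classification_sh: str
    initial_label: str | None = None
    reclassified: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "ai_flag", "aai_flag", "pai_flag", "oclr_flag", "ci_flag", "f22_flag",
            "classification_indexes", "classification_sh", "initial_label", "reclassified")}


@dataclass(frozen=True)
class GroupComparison:
    """Pooled t-test of one parameter's absolute values between groups."""

    parameter: str
    n_healthy: int
    n_dp: int
    mean_abs_healthy: float
    mean_abs_dp: float
    sd_abs_healthy: float
    sd_abs_dp: float
    t: float
    p: float
    shapiro_p_healthy: float
    shapiro_p_dp: float
    levene_p: float


def classify_by_sh(f22: float, cfg: ScreeningConfig | None = None) -> str:
    """DP iff |f_2^-2| strictly exceeds the threshold (raw scale)."""
    cfg = cfg or ScreeningConfig()
    return DP if abs(f22) > cfg.f22_threshold else HEALTHY


def classify_by_indexes(
    r: IndexReport, cfg: ScreeningConfig | None = None, initial_label: str | None = None
) -> ScreeningResult:
    """Apply the classical index rule (and, informationally, the SH rule)."""
    cfg = cfg or ScreeningConfig()
    thr = cfg.asym_threshold
    ai_flag = abs(r.AI) > thr
    aai_flag = abs(r.AAI) > thr
    pai_flag = abs(r.PAI) > thr
    oclr_flag = not (cfg.oclr_normal[0] <= r.OCLR <= cfg.oclr_normal[1])
    ci_flag = not (cfg.ci_normal[0] <= r.CI <= cfg.ci_normal[1])
    by_indexes = DP if (ai_flag or aai_flag or pai_flag or oclr_flag) else HEALTHY
    sh_call = classify_by_sh(r.f22, cfg)
    return ScreeningResult(
        ai_flag=ai_flag, aai_flag=aai_flag, pai_flag=pai_flag,
        oclr_flag=oclr_flag, ci_flag=ci_flag,
        f22_flag=sh_call == DP,
        classification_indexes=by_indexes,
        classification_sh=sh_call,
        initial_label=initial_label,
        reclassified=initial_label is not None and initial_label != by_indexes,
    )


def composite_index(r: IndexReport) -> float:
    """|AAI| + |PAI| — the compensation-proof summary asymmetry (mm)."""
    return abs(r.AAI) + abs(r.PAI)


def compare_groups(
    values_by_head: dict[str, np.ndarray], labels
) -> list[GroupComparison]:
    """Two-group comparison of |parameter| values, sorted by ascending p.

    ``values_by_head`` maps a parameter name to per-head signed values
    aligned with ``labels`` (entries ``Healthy``/``DP``).
    """
    labels = np.asarray(list(labels))
    mask_h = labels == HEALTHY
    mask_d = labels == DP
    n_h, n_d = int(mask_h.sum()), int(mask_d.sum())
    if n_h < 2 or n_d < 2:
        raise SampleSizeError(f"need >= 2 heads per group, got {n_h} Healthy / {n_d} DP")
    out: list[GroupComparison] = []
    for name, values in values_by_head.items():
        v = np.abs(np.asarray(values, dtype=float))
        if v.shape != labels.shape:
            raise ValueError(f"parameter {name!r}: {v.size} values for {labels.size} labels")
        g_h, g_d = v[mask_h], v[mask_d]
        if np.var(g_h, ddof=1) == 0.0 and np.var(g_d, ddof=1) == 0.0:
            raise DegenerateDataError(f"parameter {name!r}: zero pooled variance in both groups")
        t, p = stats.ttest_ind(g_h, g_d, equal_var=True)
        out.append(GroupComparison(
            parameter=name, n_healthy=n_h, n_dp=n_d,
            mean_abs_healthy=float(g_h.mean()), mean_abs_dp=float(g_d.mean()),
            sd_abs_healthy=float(g_h.std(ddof=1)), sd_abs_dp=float(g_d.std(ddof=1)),
            t=float(t), p=float(p),
            shapiro_p_healthy=_shapiro_p(g_h), shapiro_p_dp=_shapiro_p(g_d),
            levene_p=float(stats.levene(g_h, g_d).pvalue),
        ))
    out.sort(key=lambda c: (c.p, c.parameter))
    return out


def _shapiro_p(x: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0.0:
        return float("nan")
    return float(stats.shapiro(x).pvalue)


class ThresholdScreener(ClassifierMixin, BaseEstimator):
    """Rule-based DP screener over an index feature matrix.

    ``X`` is a DataFrame (or (n, 4+) array) with columns AI, AAI, PAI, OCLR
    in mm/percent; ``predict`` returns ``"Healthy"``/``"DP"`` per row. The
    thresholds are fixed clinical constants, so ``fit`` only records the
    class labels; the estimator still plays with sklearn pipelines and
    cross-validation utilities.
    """

    _COLUMNS = ("AI", "AAI", "PAI", "OCLR")

    def __init__(self, asym_threshold: float = 4.0,
                 oclr_normal: tuple[float, float] = (94.0, 106.0)):
        self.asym_threshold = asym_threshold
        self.oclr_normal = oclr_normal

    def fit(self, X, y=None):
        self.classes_ = np.array([DP, HEALTHY])
        self.n_features_in_ = np.shape(X)[1]
        return self

    def _matrix(self, X) -> np.ndarray:
        if hasattr(X, "loc"):
            return X.loc[:, list(self._COLUMNS)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X[:, : len(self._COLUMNS)]

    def predict(self, X):
        M = self._matrix(X)
        asym = np.abs(M[:, :3]) > self.asym_threshold
        oclr = (M[:, 3] < self.oclr_normal[0]) | (M[:, 3] > self.oclr_normal[1])
        return np.where(asym.any(axis=1) | oclr, DP, HEALTHY)
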
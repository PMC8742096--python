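"""End-to-end analysis: align, fit, chart, expand, measure, screen.

The analysis itself is deterministic and seed-free; randomness only enters
through the synthetic generator. Stage errors propagate with the stage name
attached and partial reports are never emitted.
"""

from __future__ import annotations

import logging
import time
import warnings

import numpy as np

from . import anthropometry
from .anthropometry import compute_indexes, compute_measures
from .ellipsoid import fit_ellipsoid, surface_samples
from .errors import CranioShapeError, GeometryError, InsufficientDataError
from .frame import align_head
from .harmonics import NORMALIZATION, coefficient_vs_lmax, expand
from .model_io import HeadModel
from .report import AnalysisReport
from .screening import DP, HEALTHY, ScreeningConfig, classify_by_indexes, compare_groups, composite_index

logger = logging.getLogger(__name__)

DEFAULT_LMAX = 4


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except CranioShapeError as exc:
        raise type(exc)(f"stage {name!r}: {exc}") from exc
    logger.info("stage %s finished in %.1f ms", name, 1e3 * (time.perf_counter() - t0))
    return result


def _effective_config(cfg: ScreeningConfig, lmax: int, ridge: float) -> dict:
    return {
        "screening": cfg.as_dict(),
        "lmax": lmax,
        "ridge": ridge,
        "normalization": NORMALIZATION,
        "slice_search": {
            "tilt_range_deg": anthropometry.TILT_RANGE_DEG,
            "tilt_step_deg": anthropometry.TILT_STEP_DEG,
            "offset_step_mm": anthropometry.OFFSET_STEP_MM,
            "slab_half_width_mm": anthropometry.SLAB_HALF_WIDTH_MM,
            "oblique_angle_deg": anthropometry.OBLIQUE_ANGLE_DEG,
        },
    }


def analyze_head(
    model: HeadModel,
    cfg: ScreeningConfig | None = None,
    lmax: int = DEFAULT_LMAX,
    lmax_sweep=None,
    ridge: float = 0.0,
    initial_label: str | None = None,
) -> AnalysisReport:
    """Full single-head analysis.

    The model must carry landmarks or already be aligned. ``lmax_sweep``
    optionally refits the expansion at each listed degree and records the
    (f_2^-2, RMSE) pairs in the report.
    """
    cfg = cfg or ScreeningConfig()
    if not model.is_aligned and model.landmarks is None:
        raise GeometryError("stage 'align': model has no landmarks and is not aligned")
    n_coef = (lmax + 1) ** 2
    if model.n_points < max(25, n_coef):
        raise InsufficientDataError(
            f"{model.n_points} points cannot support the analysis "
            f"(need >= {max(25, n_coef)} for lmax={lmax})"
        )
    aligned = model if model.is_aligned else _stage("align", align_head, model)
    ellipsoid = _stage("fit_ellipsoid", fit_ellipsoid, aligned.points)
    samples = _stage("surface_samples", surface_samples, aligned, ellipsoid)
    expansion = _stage("expand", expand, samples, lmax, ridge)
    sweep = (
        _stage("lmax_sweep", coefficient_vs_lmax, samples, list(lmax_sweep), 2, -2, ridge)
        if lmax_sweep is not None
        else {}
    )
    measures = _stage("anthropometry", compute_measures, aligned)
    indexes = _stage("indexes", compute_indexes, measures, expansion.f22, lmax)
    screening = _stage("screening", classify_by_indexes, indexes, cfg, initial_label)
    return AnalysisReport(
        head_id=model.id,
        ellipsoid=ellipsoid,
        measures=measures,
        indexes=indexes,
        expansion=expansion,
        sweep=sweep,
        screening=screening,
        config=_effective_config(cfg, lmax, ridge),
    )


def cohort_parameters(reports, sweep_lmaxes=()) -> dict[str, np.ndarray]:
    """The parameter set compared between groups, per head (signed values)."""
    params: dict[str, np.ndarray] = {}
    for lm in list(sweep_lmaxes) or []:
        params[f"f22_lmax{lm}"] = np.array([r.sweep[lm][0] for r in reports])
    if not params:
        params["f22_lmax%d" % reports[0].expansion.lmax] = np.array(
            [r.indexes.f22 for r in reports]
        )
    params["AI"] = np.array([r.indexes.AI for r in reports])
    params["AAI_plus_PAI"] = np.array([composite_index(r.indexes) for r in reports])
    params["OCLR100"] = np.array([r.indexes.OCLR100 for r in reports])
    return params


def analyze_cohort(
    models,
    cfg: ScreeningConfig | None = None,
    lmax: int = DEFAULT_LMAX,
    lmax_sweep=None,
    labels=None,
):
    """Per-head reports plus group statistics over the standard parameter set.

    ``models`` is an iterable of HeadModel or (HeadModel, label) pairs; an
    explicit ``labels`` sequence overrides. Without usable labels (or with a
    group smaller than two heads) the statistics are skipped with a warning
    and ``None`` is returned in their place.
    """
    models = list(models)
    if models and isinstance(models[0], tuple):
        pair_labels = [lab for _, lab in models]
        models = [m for m, _ in models]
        labels = labels if labels is not None else pair_labels
    reports = [analyze_head(m, cfg=cfg, lmax=lmax, lmax_sweep=lmax_sweep) for m in models]
    if labels is None:
        labels = [r.screening.classification_indexes for r in reports]
    labels = list(labels)
    params = cohort_parameters(reports, sweep_lmaxes=lmax_sweep or ())
    n_h, n_d = labels.count(HEALTHY), labels.count(DP)
    if n_h < 2 or n_d < 2:
        warnings.warn(
            f"group statistics skipped: {n_h} Healthy / {n_d} DP heads (need >= 2 each)",
            stacklevel=2,
        )
        return reports, None
    return reports, compare_groups(params, labels)
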
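"""Analysis report: the complete, serializable record of one head's analysis.

A report captures everything needed to reproduce each stage: the fitted
ellipsoid, the anthropometric measures and indexes, the spherical-harmonic
coefficient table with its immutable normalization tag, the per-lmax sweep
of (f_2^-2, RMSE), the screening outcome and the effective configuration.
JSON serialization is deterministic (keys sorted, floats at 9 significant
digits) and round-trips losslessly through :meth:`AnalysisReport.from_dict`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anthropometry import AnthropometricMeasures, IndexReport, PerimeterPlane
from .ellipsoid import Ellipsoid
from .errors import SchemaError
from .harmonics import SHExpansion
from .screening import ScreeningResult

import json


def _round_floats(obj):
    """Normalise a JSON tree: floats to 9 significant digits, arrays to lists."""
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.9g}")
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, dict):
        return {str(k): _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


@dataclass(eq=False)
class AnalysisReport:
    head_id: str
    ellipsoid: Ellipsoid
    measures: AnthropometricMeasures
    indexes: IndexReport
    expansion: SHExpansion
    sweep: dict[int, tuple[float, float]]  # lmax -> (f_2^-2, rmse)
    screening: ScreeningResult | None
    config: dict

    def to_dict(self) -> dict:
        if self.screening is None:
            raise SchemaError("report is incomplete: screening block missing")
        pairs_table = self.expansion.to_table()
        return _round_floats({
            "head_id": self.head_id,
            "ellipsoid": {
                "center": self.ellipsoid.center,
                "semi_axes": self.ellipsoid.semi_axes,
            },
            "measures": self.measures.as_dict(),
            "indexes": self.indexes.as_dict(),
            "expansion": {
                "lmax": self.expansion.lmax,
                "normalization": self.expansion.normalization,
                "rmse": self.expansion.rmse,
                "n_samples": self.expansion.n_samples,
                "ridge": self.expansion.ridge,
                "coefficients": pairs_table.to_numpy().tolist(),
            },
            "sweep": {str(k): {"f22": v[0], "rmse": v[1]} for k, v in self.sweep.items()},
            "screening": self.screening.as_dict(),
            "config": self.config,
        })

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        exp = d["expansion"]
        coef_rows = sorted(exp["coefficients"], key=lambda r: (r[0], r[1]))
        expansion = SHExpansion(
            lmax=int(exp["lmax"]),
            coefficients=np.array([r[2] for r in coef_rows], dtype=float),
            rmse=float(exp["rmse"]),
            n_samples=int(exp["n_samples"]),
            ridge=float(exp.get("ridge", 0.0)),
        )
        meas = dict(d["measures"])
        plane = PerimeterPlane(
            tilt_deg=meas.pop("perimeter_plane_tilt_deg"),
            offset=meas.pop("perimeter_plane_offset"),
        )
        return cls(
            head_id=d["head_id"],
            ellipsoid=Ellipsoid(center=d["ellipsoid"]["center"], semi_axes=d["ellipsoid"]["semi_axes"]),
            measures=AnthropometricMeasures(perimeter_plane=plane, **meas),
            indexes=IndexReport(**d["indexes"]),
            expansion=expansion,
            sweep={int(k): (v["f22"], v["rmse"]) for k, v in d["sweep"].items()},
            screening=ScreeningResult(**d["screening"]),
            config=d["config"],
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


def report_row(r: AnalysisReport) -> dict:
    """One flat CSV row per head (fixed column schema)."""
    d = r.to_dict()
    row: dict = {"id": r.head_id}
    row.update({f"center_{ax}": v for ax, v in zip("xyz", d["ellipsoid"]["center"])})
    row.update({f"semi_axis_{ax}": v for ax, v in zip("xyz", d["ellipsoid"]["semi_axes"])})
    row.update(d["measures"])
    row.update(d["indexes"])
    row["rmse"] = d["expansion"]["rmse"]
    row["n_samples"] = d["expansion"]["n_samples"]
    row.update(d["screening"])
    return row


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([report_row(r) for r in reports])
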
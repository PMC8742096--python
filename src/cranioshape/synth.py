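"""Synthetic cap-sampled heads with known ellipsoid and planted deformation.

Every analysis stage is testable without patient data: heads are generated
as triaxial ellipsoids sampled on a Fibonacci spiral restricted to a
spherical cap (emulating a measurement cap that leaves the head base
uncovered), deformed by smooth Gaussian bumps applied along the outward
surface normal — a flattening is a negative-amplitude bump on a posterior
quadrant, optionally compensated by ipsilateral frontal bossing (an
opposite-sign bump at the azimuth mirrored across the ear-to-ear axis,
the parallelogram deformity) — plus isotropic-in-normal measurement noise.

Bumps are parameterised by great-circle width rather than planting a
spherical harmonic directly, so coefficient-recovery tests are not
circular. Landmarks sit exactly on the undeformed ellipsoid (the
preauricular points at the +/-Y surface points, the glabella at +X), so a
generated head is already in its anatomical frame and alignment is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ellipsoid import Ellipsoid
from .model_io import HeadModel, Landmarks
from .screening import DP, HEALTHY

_GOLDEN_ANGLE_DEG = 360.0 * (1.0 - 1.0 / ((1.0 + np.sqrt(5.0)) / 2.0))

#: Smallest smooth-bump width (deg): keeps the planted field representable
#: at low truncation degrees, as an infant flattening is.
MIN_ANGULAR_SD_DEG = 20.0


@dataclass(frozen=True)
class Bump:
    """One smooth radial deformation: Gaussian in great-circle angle.

    Negative amplitude is a flattening (surface pushed inward), positive a
    bossing. ``azimuth_deg`` is measured from +X (anterior) toward +Y
    (patient's left); posterior quadrants live near 120-240 degrees.
    """

    azimuth_deg: float
    lat_deg: float
    amplitude_mm: float
    angular_sd_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.angular_sd_deg < MIN_ANGULAR_SD_DEG:
            raise ValueError(
                f"angular_sd_deg {self.angular_sd_deg} < {MIN_ANGULAR_SD_DEG}: "
                "bumps this narrow are not a smooth DP-like deformation"
            )

    def direction(self) -> np.ndarray:
        lat, lon = np.deg2rad(self.lat_deg), np.deg2rad(self.azimuth_deg)
        return np.array([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)])


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator conditions for one head.

    Defaults emulate the clinical acquisition: ~530 points evenly spread
    over an infant-head-sized ellipsoid, cap coverage down to -25 degrees
    latitude, 0.3 mm measurement noise.
    """

    semi_axes: tuple[float, float, float] = (85.0, 65.0, 60.0)
    n_points: int = 530
    cap_min_lat: float = -25.0
    deformations: tuple[Bump, ...] = ()
    compensation: bool = False
    noise_sd: float = 0.3
    seed: int = 0
    landmark_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 25:
            raise ValueError(f"n_points {self.n_points} < 25")
        if not all(a > 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if self.noise_sd < 0 or self.landmark_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not -90.0 <= self.cap_min_lat < 90.0:
            raise ValueError(f"cap_min_lat {self.cap_min_lat} outside [-90, 90)")
        object.__setattr__(self, "deformations", tuple(self.deformations))
        object.__setattr__(self, "semi_axes", tuple(float(a) for a in self.semi_axes))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for closing the loop in tests."""

    ellipsoid: Ellipsoid
    label: str
    f22_proxy: float
    spec: SyntheticSpec


def fibonacci_cap(n: int, min_lat_deg: float) -> np.ndarray:
    """n near-equal-area unit directions on the cap lat >= min_lat_deg."""
    i = np.arange(n)
    z0 = np.sin(np.deg2rad(min_lat_deg))
    z = z0 + (i + 0.5) * (1.0 - z0) / n
    lon = np.deg2rad((i * _GOLDEN_ANGLE_DEG) % 360.0)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(lon), r * np.sin(lon), z])


def _effective_bumps(spec: SyntheticSpec) -> list[Bump]:
    bumps = list(spec.deformations)
    if spec.compensation:
        # Parallelogram deformity: a posterior flattening is compensated by
        # ipsilateral frontal bossing — opposite sign, azimuth mirrored
        # across the ear-to-ear (Y) axis.
        bumps += [
            replace(b, azimuth_deg=(180.0 - b.azimuth_deg) % 360.0, amplitude_mm=-b.amplitude_mm)
            for b in spec.deformations
        ]
    return bumps


def generate_head(spec: SyntheticSpec, id: str | None = None) -> tuple[HeadModel, GroundTruth]:
    """Generate one head; RNG fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(spec.semi_axes)
    u = fibonacci_cap(spec.n_points, spec.cap_min_lat)
    surface = u * a  # ellipsoid centred at the anatomical origin
    normals = surface / a**2
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    disp = np.zeros(spec.n_points)
    for b in _effective_bumps(spec):
        cosang = np.clip(u @ b.direction(), -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        disp += b.amplitude_mm * np.exp(-(ang**2) / (2.0 * b.angular_sd_deg**2))
    noise = rng.normal(0.0, spec.noise_sd, spec.n_points) if spec.noise_sd > 0 else 0.0
    points = surface + (disp + noise)[:, None] * normals

    lm_pts = np.array([[0.0, a[1], 0.0], [0.0, -a[1], 0.0], [a[0], 0.0, 0.0]])
    if spec.landmark_noise_sd > 0:
        lm_pts = lm_pts + rng.normal(0.0, spec.landmark_noise_sd, lm_pts.shape)
    landmarks = Landmarks(
        preauricular_left=lm_pts[0], preauricular_right=lm_pts[1], glabella=lm_pts[2]
    )

    truth = GroundTruth(
        ellipsoid=Ellipsoid(center=np.zeros(3), semi_axes=a),
        label=DP if any(abs(b.amplitude_mm) > 0 for b in spec.deformations) else HEALTHY,
        f22_proxy=_f22_proxy(u, disp),
        spec=spec,
    )
    model = HeadModel(
        id=id or f"synthetic-{spec.seed}", points=points, landmarks=landmarks, is_aligned=True
    )
    return model, truth


def _f22_proxy(u: np.ndarray, disp: np.ndarray) -> float:
    """OLS projection of the noise-free planted field onto f_2^-2 (lmax 4)."""
    from .harmonics import design_matrix  # local import: synth stays importable standalone

    if not np.any(disp):
        return 0.0
    lat = np.degrees(np.arcsin(np.clip(u[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(u[:, 1], u[:, 0])) % 360.0
    G = design_matrix(lat, lon, 4)
    coef, *_ = np.linalg.lstsq(G, disp, rcond=None)
    return float(coef[4 + 0])  # (l=2, m=-2) in storage order: index l^2 + (m + l)


@dataclass(frozen=True)
class Cohort:
    """Generated heads with truth labels and a per-head manifest."""

    heads: tuple[HeadModel, ...]
    truths: tuple[GroundTruth, ...]
    manifest: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.truths]

    def pairs(self) -> list[tuple[HeadModel, str]]:
        return list(zip(self.heads, self.labels))

    def __len__(self) -> int:
        return len(self.heads)


def generate_cohort(
    n_healthy: int,
    n_dp: int,
    seed: int,
    severity_range: tuple[float, float] = (5.0, 10.0),
) -> Cohort:
    """A labelled cohort: noise-only regular heads plus DP heads.

    DP heads carry one posterolateral flattening with magnitude drawn
    uniformly from ``severity_range`` (mm, applied inward). The bump centre
    is drawn uniformly over the lateral occipital band — azimuth in
    [120, 160] degrees or its mirror [200, 240] with equal probability,
    latitude in [0, 15] degrees — because deformational plagiocephaly is a
    unilateral flattening clearly off the midline near ear level; a
    midline-centred flattening is a symmetric (brachycephaly-like)
    phenotype. Half the DP heads receive a frontal compensation bump.
    Per-head semi-axes are jittered +/-10 %; per-head sub-seeds derive
    deterministically from the master seed.
    """
    master = np.random.default_rng(seed)
    rows, heads, truths = [], [], []
    labels = [HEALTHY] * n_healthy + [DP] * n_dp
    for k, label in enumerate(labels):
        sub_seed = int(master.integers(2**31))
        axes = np.array([85.0, 65.0, 60.0]) * master.uniform(0.9, 1.1, 3)
        if label == DP:
            amplitude = -float(master.uniform(*severity_range))
            azimuth = float(master.uniform(120.0, 160.0))
            if master.uniform() < 0.5:  # mirror to the right posterolateral band
                azimuth = 360.0 - azimuth
            bump_lat = float(master.uniform(0.0, 15.0))
            compensation = bool(master.uniform() < 0.5)
            deformations = (Bump(azimuth_deg=azimuth, lat_deg=bump_lat, amplitude_mm=amplitude),)
        else:
            amplitude, azimuth, bump_lat, compensation = 0.0, float("nan"), float("nan"), False
            deformations = ()
        spec = SyntheticSpec(
            semi_axes=tuple(axes), deformations=deformations,
            compensation=compensation, seed=sub_seed,
        )
        head_id = f"{'H' if label == HEALTHY else 'P'}{k + 1 if label == HEALTHY else k - n_healthy + 1}"
        model, truth = generate_head(spec, id=head_id)
        heads.append(model)
        truths.append(truth)
        rows.append({
            "id": head_id, "label": label, "amplitude_mm": amplitude,
            "azimuth_deg": azimuth, "bump_lat_deg": bump_lat,
            "compensation": compensation, "seed": sub_seed,
        })
    return Cohort(heads=tuple(heads), truths=tuple(truths), manifest=pd.DataFrame(rows))
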
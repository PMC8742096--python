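import numpy as np
import pytest

from cranioshape import (
    Bump,
    SyntheticSpec,
    analyze_head,
    fit_ellipsoid,
    generate_head,
    surface_samples,
)


def sphere_cloud(n: int, radius: float, seed: int = 0, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """n exact points on a sphere, uniformly distributed."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return np.asarray(center) + radius * u


def ellipsoid_cloud(n: int, semi_axes, seed: int = 0, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """n exact surface points of an axis-aligned ellipsoid."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return np.asarray(center) + u * np.asarray(semi_axes)


def spread_chart(n: int, seed: int = 0, min_lat: float = -90.0):
    """Well-spread (lat, lon) sites in degrees over a cap."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(np.sin(np.deg2rad(min_lat)), 1.0, n)
    lat = np.degrees(np.arcsin(z))
    lon = rng.uniform(0.0, 360.0, n)
    return lat, lon


@pytest.fixture(scope="session")
def healthy_head():
    """Noise-free undeformed synthetic head (already aligned)."""
    return generate_head(SyntheticSpec(noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def dp_head():
    """Back-left flattened head, -8 mm, with measurement noise."""
    spec = SyntheticSpec(
        deformations=(Bump(azimuth_deg=135.0, lat_deg=10.0, amplitude_mm=-8.0),), seed=4
    )
    return generate_head(spec)


@pytest.fixture(scope="session")
def dp_report(dp_head):
    return analyze_head(dp_head[0])


@pytest.fixture(scope="session")
def healthy_report(healthy_head):
    return analyze_head(healthy_head[0])


@pytest.fixture(scope="session")
def healthy_samples(healthy_head):
    model, truth = healthy_head
    e = fit_ellipsoid(model.points)
    return surface_samples(model, e)
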
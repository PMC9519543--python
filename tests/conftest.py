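import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from spiris import DetectionKernel, DetectionParams, SimulationConfig, TrackingParams
from spiris.simulate import _add_gaussian

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def kernel() -> DetectionKernel:
    return DetectionKernel.gaussian(1.5)


@pytest.fixture
def det_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def trk_params() -> TrackingParams:
    return TrackingParams()


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(shot_noise_scale=0.0)


def plant_particles(shape, n, amplitude, sigma=1.5, background=1000.0,
                    min_sep=10.0, margin=10, seed=0, noise_sd=0.0):
    """A single frame with n well-separated Gaussian particles; returns
    (image, positions)."""
    rng = np.random.default_rng(seed)
    pts: list[tuple[float, float]] = []
    h, w = shape
    while len(pts) < n:
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - px) ** 2 + (y - py) ** 2 > min_sep**2 for px, py in pts):
            pts.append((x, y))
    img = np.full(shape, background)
    for x, y in pts:
        _add_gaussian(img, x, y, amplitude, sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    return img, pts


@pytest.fixture
def plant_scene():
    return plant_particles
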
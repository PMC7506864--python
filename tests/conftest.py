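import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import canopyheight as ch

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_layout():
    """The study plot: 2.5 m side, 5 x 5 subplots of 0.5 m, 0.3 m crops."""
    return ch.make_layout(2.5, 5, 0.5, 0.3)


@pytest.fixture(scope="session")
def flat_constant_scene():
    """Flat ground, every blade tip at exactly 0.400 m: the analytic scene."""
    layout = ch.make_layout(1.0, 2, 0.5, 0.3)
    ground = ch.generate_ground(layout, relief_sd=0.0, correlation_length=0.5, seed=0)
    scene = ch.generate_canopy(ground, layout, [400.0] * 4, height_cv=0.0,
                               blades_per_m2=4000.0, seed=1)
    return scene


def random_cloud(rng: np.random.Generator, n: int, extent=(0.0, 0.0, 1.0, 1.0),
                 z_range=(0.0, 0.5)) -> ch.PointCloud:
    x0, y0, x1, y1 = extent
    xyz = np.column_stack([
        rng.uniform(x0, x1, n),
        rng.uniform(y0, y1, n),
        rng.uniform(*z_range, n),
    ])
    return ch.PointCloud(xyz)
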
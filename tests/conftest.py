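import numpy as np
import pytest

from geomstate import (
    DesignSpec,
    PlantedGeometry,
    generate_design,
    generate_epochs,
    goal_labels,
    goal_square_coords,
)


@pytest.fixture(scope="session")
def small_design():
    """72-trial counterbalanced table (2 reps per cell)."""
    return generate_design(DesignSpec(reps_per_cell=2), seed=11)


@pytest.fixture(scope="session")
def goal_geometry():
    """Unit-half-side planted goal square, active through Delay 1."""
    return PlantedGeometry(coords=goal_square_coords(2.0),
                           activation={"delay1": 1.0}, label="goal")


@pytest.fixture(scope="session")
def noisefree_epochs(small_design, goal_geometry):
    """Noise-free epochs: the planted square is the only signal."""
    return generate_epochs(small_design, goal_geometry, n_channels=16,
                           noise_sd=0.0, seed=21)


@pytest.fixture(scope="session")
def small_labels(small_design):
    return goal_labels(small_design)


def random_simple_quadrilaterals(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random simple quadrilaterals: 4 uniform points ordered by angle
    around their centroid (star-shaped w.r.t. the centroid, hence simple)."""
    pts = rng.random((n, 4, 2))
    c = pts.mean(axis=1, keepdims=True)
    ang = np.arctan2(pts[..., 1] - c[..., 1], pts[..., 0] - c[..., 0])
    order = np.argsort(ang, axis=1)
    return np.take_along_axis(pts, order[..., None], axis=1)
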
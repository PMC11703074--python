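"""Circularity index and condition-subspace fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geomstate.errors import (
    ConfigurationError,
    DegenerateInputError,
    IncompatibleSpaceError,
    InvalidPolygonError,
    InvalidWindowError,
    MissingConditionError,
)
from geomstate.geometry import (
    GOAL_ORDER,
    STIM_HEX_ORDER,
    ConditionMatrix,
    circularity,
    condition_average,
    fit_subspace,
    group_concatenate,
    polygon_circularity,
    polygon_from,
    project,
    standardize_conditions,
    top2_scores,
)

from conftest import random_simple_quadrilaterals


def regular_polygon(n, radius=1.0):
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


@pytest.mark.parametrize(
    "vertices, expected",
    [
        (regular_polygon(360), np.pi * np.cos(np.pi / 360) / (360 * np.sin(np.pi / 360))),
        ([(0, 0), (1, 0), (1, 1), (0, 1)], np.pi / 4),  # unit square
        ([(0, 0), (2, 0), (2, 1), (0, 1)], 2 * np.pi / 9),  # 2x1 rectangle: A=2, P=6
        ([(0, 0), (1, 0), (2, 0), (3, 0)], 0.0),  # collinear
    ],
)
def test_circularity_known_shapes(vertices, expected):
    c = circularity(np.asarray(vertices, dtype=float))
    assert c.C == pytest.approx(expected, abs=1e-12)


def test_circle_approaches_one_and_square_is_pi_over_4():
    assert circularity(regular_polygon(360)).C == pytest.approx(1.0, abs=1e-3)
    assert circularity(regular_polygon(4)).C == pytest.approx(np.pi / 4, abs=1e-12)


def test_degenerate_and_invalid_polygons():
    assert circularity(np.zeros((4, 2))).C == 0.0  # zero perimeter rule
    with pytest.raises(InvalidPolygonError):
        circularity(np.array([[0.0, 0.0], [1.0, 1.0]]))


def test_bowtie_ordering_collapses_area():
    """Swapping the goal walk into a crossing order must score near zero:
    the signed shoelace lobes of a bow-tie cancel."""
    square = np.array([(1, 1), (1, -1), (-1, -1), (-1, 1)], dtype=float)
    good = circularity(square).C
    bowtie = square[[0, 2, 1, 3]]  # BR, SG, BG, SR
    x, y = bowtie[:, 0], bowtie[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    assert abs(0.5 * np.sum(x * yn - xn * y)) < 1e-12  # shoelace oracle: lobes cancel
    assert circularity(bowtie).C < 1e-12 < good


def test_circularity_matches_shapely_oracle():
    shapely = pytest.importorskip("shapely")
    rng = np.random.default_rng(5)
    for quad in random_simple_quadrilaterals(200, rng):
        poly = shapely.Polygon(quad)
        expected = 4 * np.pi * poly.area / poly.length**2
        assert circularity(quad).C == pytest.approx(expected, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    angle=st.floats(-np.pi, np.pi),
    scale=st.floats(0.05, 20.0),
    dx=st.floats(-20, 20),
    dy=st.floats(-20, 20),
    reflect=st.booleans(),
    seed=st.integers(0, 2**16),
)
def test_circularity_rigid_transform_invariance(angle, scale, dx, dy, reflect, seed):
    """C is invariant to translation, rotation, reflection, uniform scaling."""
    v = random_simple_quadrilaterals(1, np.random.default_rng(seed))[0]
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    if reflect:
        rot = rot @ np.diag([1.0, -1.0])
    w = scale * (v @ rot.T) + np.array([dx, dy])
    # exact in real arithmetic; the tolerance covers float cancellation when
    # a small shape sits far from the origin
    assert circularity(w).C == pytest.approx(circularity(v).C, rel=1e-7, abs=1e-9)


def test_isoperimetric_bound_for_quadrilaterals():
    quads = random_simple_quadrilaterals(2000, np.random.default_rng(7))
    assert polygon_circularity(quads).max() <= np.pi / 4 + 1e-9


def test_vertex_count_bounds():
    """4-gons cannot exceed the square's C; 6-gons the regular hexagon's."""
    assert circularity(regular_polygon(4)).C <= np.pi / 4 + 1e-9
    hex_bound = np.pi * np.sqrt(3) / 6
    assert circularity(regular_polygon(6)).C == pytest.approx(hex_bound, abs=1e-9)


# ---------------------------------------------------------------------------
# condition averaging / subspace
# ---------------------------------------------------------------------------

def test_condition_average_constant_conditions():
    data = np.repeat(np.arange(4.0)[:, None], 3, axis=1)  # condition value = label
    data = np.tile(data, (2, 1))[:, :, None] * np.ones((8, 3, 5))
    labels = list(range(4)) * 2
    cm = condition_average(data, labels, order=[0, 1, 2, 3])
    assert np.allclose(cm.values, np.repeat(np.arange(4.0)[:, None], 3, axis=1))


def test_condition_average_window_matches_bruteforce(noisefree_epochs, small_labels):
    cm = condition_average(noisefree_epochs, small_labels, window=(400.0, 1700.0),
                           order=GOAL_ORDER)
    t = noisefree_epochs.times
    m = (t >= 400) & (t < 1700)
    for r, cond in enumerate(GOAL_ORDER):
        sel = [i for i, l in enumerate(small_labels) if l == cond]
        brute = noisefree_epochs.data[sel][:, :, m].mean(axis=(0, 2))
        assert np.allclose(cm.values[r], brute, atol=1e-12)


def test_condition_average_errors(noisefree_epochs, small_labels):
    with pytest.raises(InvalidWindowError):
        condition_average(noisefree_epochs, small_labels, window=(-9000.0, -8000.0))
    with pytest.raises(MissingConditionError):
        condition_average(noisefree_epochs, small_labels, order=[("huge", "bluer")])


def test_fit_subspace_matches_sklearn_pca():
    from sklearn.decomposition import PCA

    rng = np.random.default_rng(3)
    vals = rng.standard_normal((6, 10))
    cm = ConditionMatrix(vals, list(range(6)), list(range(10)))
    sub = fit_subspace(cm)
    z = (vals - vals.mean(0)) / vals.std(0)
    ref = PCA(n_components=2).fit(z)
    # components agree up to sign
    for k in range(2):
        dots = np.abs(ref.components_[k] @ sub.components[k])
        assert dots == pytest.approx(1.0, abs=1e-9)
    scores = project(sub, cm)
    assert np.allclose(np.abs(scores), np.abs(ref.transform(z)), atol=1e-9)


def test_fit_subspace_planted_plane_procrustes():
    """Noise-free planted 2D structure is recovered up to a similarity
    transform (Procrustes disparity ~ 0)."""
    from scipy.spatial import procrustes

    rng = np.random.default_rng(4)
    latent = np.array([(1, 1), (1, -1), (-1, -1), (-1, 1)], dtype=float)
    theta = rng.uniform(0, np.pi) + np.pi * np.arange(12) / 12
    mixing = np.column_stack([np.cos(theta), np.sin(theta)]) / np.sqrt(6)
    cm = ConditionMatrix(latent @ mixing.T, list(range(4)), list(range(12)))
    coords = project(fit_subspace(cm), cm)
    _, _, disparity = procrustes(latent, coords)
    assert disparity < 1e-12


def test_zero_variance_column_equivalent_to_dropping():
    rng = np.random.default_rng(9)
    vals = rng.standard_normal((4, 6))
    vals[:, 2] = 3.14  # constant channel
    cm_full = ConditionMatrix(vals, list(range(4)), list(range(6)))
    cm_drop = ConditionMatrix(np.delete(vals, 2, axis=1), list(range(4)),
                              [0, 1, 3, 4, 5])
    c_full = polygon_circularity(project(fit_subspace(cm_full), cm_full))
    c_drop = polygon_circularity(project(fit_subspace(cm_drop), cm_drop))
    assert c_full == pytest.approx(c_drop, abs=1e-12)


def test_identical_rows_give_zero_circularity():
    cm = ConditionMatrix(np.ones((4, 5)), list(range(4)), list(range(5)))
    coords = project(fit_subspace(cm), cm)
    assert polygon_circularity(coords) == 0.0


def test_fit_subspace_requires_three_conditions():
    with pytest.raises(DegenerateInputError):
        fit_subspace(ConditionMatrix(np.ones((2, 5)), [0, 1], list(range(5))))


def test_project_channel_mismatch():
    cm = ConditionMatrix(np.eye(4), list(range(4)), list("abcd"))
    other = ConditionMatrix(np.eye(4), list(range(4)), list("wxyz"))
    with pytest.raises(IncompatibleSpaceError):
        project(fit_subspace(cm), other)


def test_rotation_invariance_without_standardization():
    """Centered-only PCA (no per-channel scaling) is exactly invariant to an
    orthogonal rotation of channel space; the standardized default is only
    approximately stable."""
    from scipy.stats import ortho_group

    rng = np.random.default_rng(12)
    vals = rng.standard_normal((4, 10))
    rot = ortho_group.rvs(10, random_state=1)
    a = ConditionMatrix(vals, list(range(4)), list(range(10)))
    b = ConditionMatrix(vals @ rot.T, list(range(4)), list(range(10)))
    c_a = polygon_circularity(project(fit_subspace(a, standardize=False), a))
    c_b = polygon_circularity(project(fit_subspace(b, standardize=False), b))
    assert c_a == pytest.approx(c_b, abs=1e-9)
    s_a = polygon_circularity(project(fit_subspace(a), a))
    s_b = polygon_circularity(project(fit_subspace(b), b))
    assert s_a == pytest.approx(s_b, abs=0.05)


def test_pca_beats_random_2frames():
    """Variance captured by the top-2 PCs dominates any random orthonormal
    2-frame on the same standardized matrix."""
    rng = np.random.default_rng(15)
    vals = rng.standard_normal((6, 12))
    z = standardize_conditions(vals)
    pca_var = (top2_scores(z) ** 2).sum()
    for _ in range(50):
        frame, _ = np.linalg.qr(rng.standard_normal((12, 2)))
        assert ((z @ frame) ** 2).sum() <= pca_var + 1e-9


# ---------------------------------------------------------------------------
# polygon ordering conventions
# ---------------------------------------------------------------------------

def test_goal_order_is_edge_walk():
    for a, b in zip(GOAL_ORDER, GOAL_ORDER[1:] + GOAL_ORDER[:1]):
        assert sum(x != y for x, y in zip(a, b)) == 1  # neighbors differ on one dim


def test_polygon_from_reorders_by_condition_ids():
    square = {("bigger", "redder"): (1, 1), ("bigger", "greener"): (1, -1),
              ("smaller", "greener"): (-1, -1), ("smaller", "redder"): (-1, 1)}
    ids = sorted(square)  # scrambled relative to the convention
    coords = np.array([square[i] for i in ids], dtype=float)
    poly = polygon_from(coords, "goal_square", condition_ids=ids)
    assert circularity(poly).C == pytest.approx(np.pi / 4, abs=1e-12)


def test_stimulus_hex_order_is_convex_walk():
    grid = {(s, c): (float(s), float(c)) for s in (1, 2, 3) for c in (1, 3)}
    coords = np.array([grid[k] for k in STIM_HEX_ORDER])
    c = circularity(polygon_from(coords, "stimulus_hex"))
    assert c.area == pytest.approx(4.0, abs=1e-12)  # full 2x2 rectangle swept
    assert len(STIM_HEX_ORDER) == 6


def test_polygon_from_unknown_convention():
    with pytest.raises(ConfigurationError):
        polygon_from(np.zeros((4, 2)), "pentagon_of_doom")


def test_group_concatenate_shapes():
    cms = [ConditionMatrix(np.random.default_rng(i).standard_normal((4, 5)),
                           list(range(4)), list(range(5))) for i in range(3)]
    cat = group_concatenate(cms)
    assert cat.values.shape == (4, 15)
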
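"""Condition-subspace geometry: PCA plane fitting and the circularity index.

The pipeline's core statistic asks how closely the neural arrangement of task
conditions matches the designed 2D task space.  Condition-mean activity
(conditions x channels) is column-standardized, the top-2 principal
components define the condition subspace, conditions are projected into that
plane, connected in the fixed design order into a polygon, and the polygon's
circularity

    C = 4 * pi * Area / Perimeter**2

is the scalar readout: 1 for a circle, pi/4 (~0.785) for a square — the
maximum attainable by any quadrilateral — and near 0 for collinear or
self-intersecting (crossed) arrangements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    IncompatibleSpaceError,
    InvalidPolygonError,
    InvalidWindowError,
    MissingConditionError,
)

__all__ = [
    "GOAL_ORDER",
    "STIM_HEX_ORDER",
    "MOTOR_ORDER",
    "ORDER_CONVENTIONS",
    "ConditionMatrix",
    "Subspace",
    "PolygonCoords",
    "Circularity",
    "condition_average",
    "fit_subspace",
    "project",
    "polygon_from",
    "circularity",
    "standardize_conditions",
    "top2_scores",
    "polygon_circularity",
    "group_concatenate",
]

# Goal polygon vertex order: bigger-redder, bigger-greener, smaller-greener,
# smaller-redder — consecutive goals differ on exactly one dimension, so the
# designed square is walked along its edges, never its diagonals.
GOAL_ORDER: list[tuple] = [
    ("bigger", "redder"),
    ("bigger", "greener"),
    ("smaller", "greener"),
    ("smaller", "redder"),
]

# Stimulus hexagon: perimeter walk of the 3-size x 2-color grid that remains
# after the middle color bin is dropped (size_bin, color_bin); color_bin 1 is
# the red end, 3 the green end.
STIM_HEX_ORDER: list[tuple] = [
    (1, 3),
    (2, 3),
    (3, 3),
    (3, 1),
    (2, 1),
    (1, 1),
]

# Motor (adjustment-direction) labels share the goal-square convention.
MOTOR_ORDER: list[tuple] = list(GOAL_ORDER)

ORDER_CONVENTIONS: dict[str, list[tuple] | None] = {
    "goal_square": GOAL_ORDER,
    "stimulus_hex": STIM_HEX_ORDER,
    "motor_square": MOTOR_ORDER,
    "custom": None,
}

_EPS = 1e-300


@dataclass
class ConditionMatrix:
    """Condition-mean activity, one row per condition, one column per channel."""

    values: np.ndarray
    condition_ids: list
    channel_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DegenerateInputError("condition matrix must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise MissingConditionError("condition matrix contains non-finite entries")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "values": self.values.tolist(),
                "condition_ids": [list(c) if isinstance(c, tuple) else c for c in self.condition_ids],
                "channel_ids": list(self.channel_ids),
            }
        )


@dataclass
class Subspace:
    """Standardization parameters plus the two orthonormal component loadings."""

    column_means: np.ndarray
    column_sds: np.ndarray
    components: np.ndarray  # (2, n_channels), rows orthonormal
    channel_ids: list = field(default_factory=list)
    explained_variance: np.ndarray | None = None


@dataclass
class PolygonCoords:
    """Ordered 2D vertices; the order is fixed by convention, never by data."""

    vertices: np.ndarray
    order_label: str = "custom"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise InvalidPolygonError("vertices must be an (n, 2) array")


@dataclass
class Circularity:
    C: float
    area: float
    perimeter: float


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + (times[1] - times[0]) + 1e-9:
        raise InvalidWindowError(f"window {window} outside epoch [{times[0]}, {times[-1]}]")
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise InvalidWindowError(f"window {window} contains no samples")
    return mask


def condition_average(
    data,
    labels: Sequence,
    window: tuple[float, float] | None = None,
    order: Sequence | None = None,
    times: np.ndarray | None = None,
    channel_ids: Sequence | None = None,
) -> ConditionMatrix:
    """Average trials within condition (and over a time window) into a matrix.

    Parameters
    ----------
    data
        Either an epoch container with ``.data`` (trials x channels x samples),
        ``.times`` and ``.ch_names``, or a plain array: trials x channels x
        samples (``times`` then required when ``window`` is given) or already
        trials x channels.
    labels
        One hashable condition label per trial.
    window
        ``(t_lo, t_hi)`` in ms, half-open; samples with t_lo <= t < t_hi are
        averaged.  ``None`` averages the full epoch (or uses 2D data as-is).
    order
        Row order of the output.  Defaults to the sorted unique labels; the
        polygon conventions are applied later by :func:`polygon_from`.
    """
    if hasattr(data, "data") and hasattr(data, "times"):
        times = np.asarray(data.times, dtype=float)
        channel_ids = list(getattr(data, "ch_names", []))
        arr = np.asarray(data.data, dtype=float)
    else:
        arr = np.asarray(data, dtype=float)

    labels = list(labels)
    if arr.shape[0] != len(labels):
        raise MissingConditionError("one label per trial is required")

    if arr.ndim == 3:
        if window is not None:
            if times is None:
                raise InvalidWindowError("times required to apply a window to 3D data")
            arr = arr[:, :, _window_mask(np.asarray(times, float), window)].mean(axis=2)
        else:
            arr = arr.mean(axis=2)
    elif window is not None:
        raise InvalidWindowError("cannot window 2D (already time-averaged) data")

    if order is None:
        order = sorted(set(labels))
    rows = []
    lab_arr = np.empty(len(labels), dtype=object)
    lab_arr[:] = labels
    for cond in order:
        sel = np.array([l == cond for l in labels], dtype=bool)
        if not sel.any():
            raise MissingConditionError(f"no trials for condition {cond!r}")
        rows.append(arr[sel].mean(axis=0))
    if channel_ids is None or len(channel_ids) == 0:
        channel_ids = list(range(arr.shape[1]))
    return ConditionMatrix(np.vstack(rows), list(order), list(channel_ids))


# ---------------------------------------------------------------------------
# standardization + PCA (vectorized over an arbitrary leading batch shape)
# ---------------------------------------------------------------------------

def standardize_conditions(values: np.ndarray) -> np.ndarray:
    """Z-score each channel column across condition rows.

    Zero-variance columns are set to zero (rather than dropped) so channel
    indexing stays stable.  Works on any (..., n_conditions, n_channels) batch.
    """
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=-2, keepdims=True)
    sd = values.std(axis=-2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    return np.where(sd > 0, z, 0.0)


def top2_scores(z: np.ndarray) -> np.ndarray:
    """PCA scores on the top-2 components of a standardized condition matrix.

    Uses the eigendecomposition of the small n_cond x n_cond Gram matrix
    Z Z^T = U S^2 U^T, whose scores U S equal the SVD-based PCA scores; this
    is what makes 10^5-fold permutation loops affordable.  Batched over any
    leading shape.
    """
    z = np.asarray(z, dtype=float)
    gram = z @ np.swapaxes(z, -1, -2)
    w, u = np.linalg.eigh(gram)  # ascending eigenvalues
    s2 = np.clip(w[..., ::-1][..., :2], 0.0, None)  # top-2, descending
    vecs = u[..., ::-1][..., :2]  # columns for top-2
    return vecs * np.sqrt(s2)[..., None, :]


def fit_subspace(matrix: ConditionMatrix, standardize: bool = True) -> Subspace:
    """Standardize columns and extract the top-2 principal components.

    ``standardize=False`` centers columns only; the resulting pipeline is then
    exactly invariant to orthogonal rotations of channel space (per-channel
    variance scaling is what breaks that exact invariance).
    """
    if matrix.n_conditions < 3:
        raise DegenerateInputError("need at least 3 conditions to fit a 2D subspace")
    vals = matrix.values
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0) if standardize else np.ones(vals.shape[1])
    z = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    # full SVD of the small standardized matrix; right singular vectors are
    # the component loadings
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    comps = vt[:2].copy()
    # deterministic sign: largest-|loading| element of each component positive
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1.0
    if comps.shape[0] < 2:  # fewer channels than 2: pad (degenerate but legal)
        comps = np.vstack([comps, np.zeros((2 - comps.shape[0], z.shape[1]))])
    return Subspace(
        column_means=mu,
        column_sds=sd,
        components=comps,
        channel_ids=list(matrix.channel_ids),
        explained_variance=(s[:2] ** 2) / max(matrix.n_conditions - 1, 1),
    )


def project(subspace: Subspace, matrix: ConditionMatrix) -> np.ndarray:
    """Project condition means into the fitted plane.

    Standardization reuses the *fitting* matrix's column means/sds, so
    held-out data (e.g., good/bad trial splits) land in a comparable space.
    Returns an (n_conditions, 2) coordinate array ordered like ``matrix``.
    """
    if list(subspace.channel_ids) != list(matrix.channel_ids):
        raise IncompatibleSpaceError("channel sets of subspace and matrix differ")
    sd = subspace.column_sds
    z = np.where(sd > 0, (matrix.values - subspace.column_means) / np.where(sd > 0, sd, 1.0), 0.0)
    return z @ subspace.components.T


def polygon_from(
    coords: np.ndarray,
    order_label: str,
    condition_ids: Sequence | None = None,
) -> PolygonCoords:
    """Order projected coordinates into the conventional polygon walk.

    With ``condition_ids`` given, rows are reordered so vertices follow the
    named convention; with ``order_label='custom'`` (or no ids) the rows are
    taken as already ordered.
    """
    if order_label not in ORDER_CONVENTIONS:
        raise ConfigurationError(f"unknown order label {order_label!r}")
    coords = np.asarray(coords, dtype=float)
    convention = ORDER_CONVENTIONS[order_label]
    if convention is not None and condition_ids is not None:
        ids = list(condition_ids)
        if len(ids) != len(convention) or set(ids) != set(convention):
            raise MissingConditionError(
                f"condition ids {ids} do not match the {order_label} convention"
            )
        idx = [ids.index(c) for c in convention]
        coords = coords[idx]
    elif convention is not None and len(coords) != len(convention):
        raise MissingConditionError(
            f"{order_label} expects {len(convention)} vertices, got {len(coords)}"
        )
    return PolygonCoords(coords, order_label)


# ---------------------------------------------------------------------------
# circularity
# ---------------------------------------------------------------------------

def polygon_circularity(vertices: np.ndarray) -> np.ndarray:
    """Batched C = 4*pi*|shoelace area| / perimeter**2 over (..., n, 2) cycles.

    Degenerate rule: zero perimeter (all vertices coincide) gives C = 0.
    Self-intersecting walks are *not* repaired; their signed lobes cancel,
    which is exactly why crossed (task-incongruent) arrangements score low.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[..., 0], v[..., 1]
    xn = np.roll(x, -1, axis=-1)
    yn = np.roll(y, -1, axis=-1)
    area = 0.5 * np.abs(np.sum(x * yn - xn * y, axis=-1))
    perim = np.sum(np.hypot(xn - x, yn - y), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 4.0 * np.pi * area / (perim**2 + _EPS)
    return np.where(perim > 0, c, 0.0)


def circularity(polygon: PolygonCoords | np.ndarray) -> Circularity:
    """Circularity of a single ordered polygon, with area and perimeter."""
    v = polygon.vertices if isinstance(polygon, PolygonCoords) else np.asarray(polygon, float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise InvalidPolygonError("a polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(float(np.sum(x * yn - xn * y)))
    perim = float(np.sum(np.hypot(xn - x, yn - y)))
    c = 0.0 if perim == 0 else 4.0 * np.pi * area / perim**2
    return Circularity(C=c, area=area, perimeter=perim)


def group_concatenate(matrices: Sequence[ConditionMatrix]) -> ConditionMatrix:
    """Concatenate per-subject condition matrices horizontally.

    Convenience for group-level visualization of the shared plane (conditions
    x (channels*subjects)); not part of the validated inference path.
    """
    ids = matrices[0].condition_ids
    for m in matrices:
        if m.condition_ids != ids:
            raise MissingConditionError("condition orders differ across subjects")
    vals = np.hstack([m.values for m in matrices])
    chans = [f"s{i}:{c}" for i, m in enumerate(matrices) for c in m.channel_ids]
    return ConditionMatrix(vals, ids, chans)
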
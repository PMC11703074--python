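"""Representational similarity analysis of the goal geometry.

Two model RDMs over the four goals: a 2D model whose distances count
mismatches on the two goal dimensions (0 same goal, 0.5 one shared dimension,
1 none — a scaled hamming distance, i.e., the designed square geometry), and
a conjunctive model in which all distinct goals are equidistant (distance 1).
Data RDMs are cross-validated correlation distances between condition means
estimated from disjoint stratified folds; model-data comparison uses Spearman
rank correlation, or partial Spearman when the (correlated) models compete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidParameterError,
    MissingConditionError,
)
from .simulate import EpochArray
from .timecourse import window_means, window_partition

__all__ = [
    "RDM",
    "model_rdm_2d",
    "model_rdm_conjunctive",
    "data_rdm_crossval",
    "rsa_compare",
    "rsa_timecourse",
    "group_significance_pointwise",
]


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    labels: list
    distances: np.ndarray
    allow_negative: bool = False  # cross-validated distances can dip below 0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise InvalidParameterError("RDM must be square and match its labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise InvalidParameterError("RDM must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise InvalidParameterError("RDM diagonal must be zero")
        if not self.allow_negative and (d < -1e-12).any():
            raise InvalidParameterError("model RDM entries must be non-negative")
        self.distances = d

    def vector(self) -> np.ndarray:
        """Lower-triangle (off-diagonal) entries as a vector."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.distances[i, j]

    def to_frame(self) -> pd.DataFrame:
        names = ["/".join(map(str, l)) if isinstance(l, tuple) else str(l) for l in self.labels]
        return pd.DataFrame(self.distances, index=names, columns=names)


def _goal_of(label):
    """Extract the (size, color) goal pair from a plain or enriched label."""
    if isinstance(label, tuple) and len(label) == 2 and all(isinstance(x, str) for x in label):
        return label
    if isinstance(label, tuple) and len(label) >= 1 and isinstance(label[0], tuple):
        return label[0]
    raise ConfigurationError(f"cannot extract a goal pair from label {label!r}")


def model_rdm_2d(labels: Sequence) -> RDM:
    """2D goal model: distance = (2 - #matching goal dimensions) / 2.

    Yields exactly 0 for identical goals, 0.5 when one of the two dimensions
    matches, and 1 when neither does.
    """
    goals = [_goal_of(l) for l in labels]
    n = len(goals)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            matches = sum(a == b for a, b in zip(goals[i], goals[j]))
            d[i, j] = (2 - matches) / 2.0
    return RDM(list(labels), d)


def model_rdm_conjunctive(labels: Sequence) -> RDM:
    """Conjunctive model: all distinct goals equidistant (0 within, 1 between)."""
    goals = [_goal_of(l) for l in labels]
    if len(set(goals)) < 2:
        raise InvalidParameterError("need at least 2 distinct goals")
    n = len(goals)
    d = np.array([[0.0 if goals[i] == goals[j] else 1.0 for j in range(n)] for i in range(n)])
    return RDM(list(labels), d)


def _corr_normalize(m: np.ndarray) -> np.ndarray:
    """Center and unit-norm pattern rows so dot products are Pearson r."""
    c = m - m.mean(axis=-1, keepdims=True)
    nrm = np.linalg.norm(c, axis=-1, keepdims=True)
    return np.where(nrm > 0, c / np.where(nrm > 0, nrm, 1.0), 0.0)


def data_rdm_crossval(
    data,
    labels: Sequence,
    folds: int = 4,
    window: tuple[float, float] | None = None,
    seed: int = 0,
    order: Sequence | None = None,
) -> RDM:
    """Cross-validated correlation-distance RDM from trial-wise patterns.

    Trials are stratified into ``folds`` by condition; channels are z-scored
    across trials first; for every condition pair the correlation distance is
    computed between condition means from *disjoint* folds and averaged over
    all ordered fold pairs (which makes the matrix exactly symmetric).
    Cross-validation makes the distance an unbiased but possibly negative
    estimator, so negative entries are retained.  The diagonal is fixed at 0
    by the RDM convention.
    """
    if isinstance(data, EpochArray):
        arr = data.data
        if window is not None:
            t = np.asarray(data.times)
            m = (t >= window[0]) & (t < window[1])
            arr = arr[:, :, m].mean(axis=2)
        else:
            arr = arr.mean(axis=2)
    else:
        arr = np.asarray(data, dtype=float)
    labels = list(labels)
    if arr.shape[0] != len(labels):
        raise InvalidParameterError("one label per trial required")

    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    conds = list(order) if order is not None else sorted(set(labels))
    rng = np.random.default_rng(seed)
    fold_means = np.zeros((folds, len(conds), z.shape[1]))
    for c, cond in enumerate(conds):
        idx = np.array([i for i, l in enumerate(labels) if l == cond])
        if len(idx) == 0:
            raise MissingConditionError(f"no trials for condition {cond!r}")
        if len(idx) < folds:
            raise InsufficientDataError(
                f"condition {cond!r} has {len(idx)} trials; needs >= {folds} for {folds}-fold CV"
            )
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, folds)):
            fold_means[f, c] = z[chunk].mean(axis=0)

    hat = _corr_normalize(fold_means)  # (folds, cond, ch)
    acc = np.zeros((len(conds), len(conds)))
    count = 0
    for f in range(folds):
        for g in range(folds):
            if f == g:
                continue
            acc += 1.0 - hat[f] @ hat[g].T
            count += 1
    d = acc / count
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return RDM(conds, d, allow_negative=True)


def rsa_compare(
    data_rdm: RDM,
    model_rdms: Mapping[str, RDM],
    metric: str = "spearman",
) -> pd.DataFrame:
    """Rank-correlate the data RDM with each model RDM.

    ``spearman`` treats models separately; ``partial_spearman`` partials each
    model on all the others (requires >= 2 models), the competitive variant.
    Ties get average ranks.  Constant model vectors are flagged as undefined.
    """
    for name, m in model_rdms.items():
        if list(m.labels) != list(data_rdm.labels):
            raise ConfigurationError(f"label mismatch between data RDM and model {name!r}")
    dv = data_rdm.vector()
    vecs = {name: m.vector() for name, m in model_rdms.items()}
    rows = []
    if metric == "spearman":
        for name, mv in vecs.items():
            if np.std(mv) == 0:
                warnings.warn(f"model {name!r} RDM vector is constant", stacklevel=2)
                rows.append({"model": name, "r": np.nan, "p": np.nan})
                continue
            r, p = stats.spearmanr(dv, mv)
            rows.append({"model": name, "r": float(r), "p": float(p)})
    elif metric == "partial_spearman":
        if len(vecs) < 2:
            raise InvalidParameterError("partial metric needs at least 2 models")
        import pingouin as pg

        df = pd.DataFrame({"data": dv, **vecs})
        for name in vecs:
            if np.std(vecs[name]) == 0:
                warnings.warn(f"model {name!r} RDM vector is constant", stacklevel=2)
                rows.append({"model": name, "r": np.nan, "p": np.nan})
                continue
            covar = [m for m in vecs if m != name]
            res = pg.partial_corr(data=df, x=name, y="data", covar=covar, method="spearman")
            pcol = "p_val" if "p_val" in res.columns else "p-val"
            rows.append({"model": name, "r": float(res["r"].iloc[0]),
                         "p": float(res[pcol].iloc[0])})
    else:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    return pd.DataFrame(rows)


def rsa_timecourse(
    epochs: EpochArray,
    labels: Sequence,
    model_rdms: Mapping[str, RDM],
    metric: str = "spearman",
    folds: int = 4,
    seed: int = 0,
    window_ms: float = 80.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Model-data rank correlation per non-overlapping window.

    Returns (window centers, long DataFrame with columns window/model/r/p).
    """
    t0 = float(epochs.times[0])
    t1 = t0 + epochs.data.shape[2] * 1000.0 / epochs.sfreq
    windows = window_partition(t0, t1, window_ms)
    wm = window_means(epochs, windows)  # (trials, ch, nwin)
    order = list(model_rdms[next(iter(model_rdms))].labels)
    frames = []
    for w in range(wm.shape[2]):
        drdm = data_rdm_crossval(wm[:, :, w], labels, folds=folds, seed=seed + w, order=order)
        res = rsa_compare(drdm, model_rdms, metric=metric)
        res.insert(0, "window", w)
        frames.append(res)
    return windows.mean(axis=1), pd.concat(frames, ignore_index=True)


def group_significance_pointwise(stat_by_subject: np.ndarray, popmean: float = 0.0,
                                 alternative: str = "greater") -> pd.DataFrame:
    """Per-window one-sample t-test across subjects, no cluster correction.

    Used for the partial-correlation RSA time courses, which are tested at
    each time point independently.
    """
    x = np.asarray(stat_by_subject, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InsufficientDataError("need a (n_subjects >= 2, n_windows) array")
    t, p = stats.ttest_1samp(x, popmean, axis=0, alternative=alternative)
    return pd.DataFrame({"window": np.arange(x.shape[1]), "t": t, "p": p})
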
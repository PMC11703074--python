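"""Time-resolved circularity and its permutation inference.

The epoch is tiled into non-overlapping windows (80 ms by default, so the
-500..+4300 ms epoch yields 60 points).  Within each window, trials are
stratified-resampled (with replacement, preserving per-condition counts),
condition means are pushed through the standardize -> PCA -> project ->
polygon -> circularity pipeline, and the resample mean is the window's value.
Significance comes from a cluster-based permutation test: trial labels are
shuffled within participant, the identical resampling protocol is re-run,
per-window pointwise thresholds are the (1-alpha) null quantiles, and the
cluster-level statistic is the length of the longest supra-threshold run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    IncompatibleSpaceError,
    InsufficientDataError,
    InvalidParameterError,
    MissingConditionError,
    SplitCoverageError,
)
from .geometry import (
    ORDER_CONVENTIONS,
    polygon_circularity,
    standardize_conditions,
    top2_scores,
)
from .simulate import EpochArray

logger = logging.getLogger(__name__)

__all__ = [
    "window_partition",
    "window_means",
    "CircularityTimecourse",
    "Cluster",
    "ClusterSet",
    "SplitResult",
    "timecourse_circularity",
    "permutation_null",
    "cluster_test",
    "combined_error",
    "trial_split_difference",
    "behavior_correlation",
    "motor_relabel",
    "incorrect_goal_relabel",
    "chi2_independence",
]


def window_partition(epoch_start: float, epoch_end: float, window: float) -> np.ndarray:
    """Contiguous non-overlapping (start, end) window bounds in ms.

    Anchored at the epoch start; a trailing partial window is dropped, so
    the count is floor((end - start) / window).
    """
    if window <= 0:
        raise InvalidParameterError("window length must be positive")
    if epoch_end <= epoch_start:
        raise InvalidParameterError("epoch_end must exceed epoch_start")
    n = int(np.floor((epoch_end - epoch_start) / window + 1e-9))
    starts = epoch_start + window * np.arange(n)
    return np.column_stack([starts, starts + window])


def window_means(epochs: EpochArray, windows: np.ndarray) -> np.ndarray:
    """Per-trial, per-channel mean within each window: (trials, ch, n_windows)."""
    t = np.asarray(epochs.times, dtype=float)
    cols = []
    for lo, hi in windows:
        m = (t >= lo - 1e-9) & (t < hi - 1e-9)
        cols.append(epochs.data[:, :, m].mean(axis=2))
    return np.stack(cols, axis=-1)


@dataclass
class CircularityTimecourse:
    window_centers: np.ndarray
    values: np.ndarray
    window_length: float = 80.0

    @property
    def n_windows(self) -> int:
        return len(self.values)


@dataclass
class Cluster:
    start: int  # first window index (inclusive)
    end: int  # last window index (inclusive)
    size: int
    p_value: float
    significant: bool


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    pointwise_threshold: np.ndarray
    cluster_threshold: float
    pointwise_alpha: float = 0.05

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _condition_order(labels: Sequence, order_label: str) -> list:
    conv = ORDER_CONVENTIONS.get(order_label)
    if conv is None:
        return sorted(set(labels))
    return list(conv)


def _group_indices(labels: Sequence, order: Sequence) -> list[np.ndarray]:
    labels = list(labels)
    groups = []
    for cond in order:
        idx = np.array([i for i, l in enumerate(labels) if l == cond], dtype=int)
        if len(idx) == 0:
            raise MissingConditionError(f"no trials for condition {cond!r}")
        groups.append(idx)
    return groups


def _curve(
    wm: np.ndarray,
    groups: list[np.ndarray],
    rng: np.random.Generator | None,
    n_resamples: int,
) -> np.ndarray:
    """Resample-averaged circularity per window from precomputed window means.

    Vertices follow the order of ``groups`` (already the polygon convention).
    ``rng=None`` disables resampling (plain condition means, one pass).
    """
    n_trials, n_ch, n_win = wm.shape
    n_cond = len(groups)
    reps = 1 if rng is None else n_resamples
    cm = np.empty((reps, n_cond, n_ch, n_win))
    for c, idx in enumerate(groups):
        if rng is None:
            cm[0, c] = wm[idx].mean(axis=0)
        else:
            for r in range(reps):
                take = rng.choice(idx, size=len(idx), replace=True)
                cm[r, c] = wm[take].mean(axis=0)
    mats = cm.transpose(0, 3, 1, 2).reshape(reps * n_win, n_cond, n_ch)
    z = standardize_conditions(mats)
    xy = top2_scores(z)
    c_vals = polygon_circularity(xy).reshape(reps, n_win)
    return c_vals.mean(axis=0)


def timecourse_circularity(
    epochs: EpochArray,
    labels: Sequence,
    order_label: str = "goal_square",
    n_resamples: int = 10,
    seed: int = 0,
    window_ms: float = 80.0,
) -> CircularityTimecourse:
    """Stratified-resample-averaged circularity time course for one subject."""
    if n_resamples < 1:
        raise InvalidParameterError("n_resamples must be >= 1")
    t0 = float(epochs.times[0])
    t1 = t0 + epochs.data.shape[2] * 1000.0 / epochs.sfreq
    windows = window_partition(t0, t1, window_ms)
    wm = window_means(epochs, windows)
    order = _condition_order(labels, order_label)
    groups = _group_indices(labels, order)
    rng = np.random.default_rng(seed)
    values = _curve(wm, groups, rng, n_resamples)
    return CircularityTimecourse(windows.mean(axis=1), values, window_ms)


def permutation_null(
    epochs: EpochArray | Sequence[EpochArray],
    labels: Sequence,
    order_label: str = "goal_square",
    n_perm: int = 5000,
    n_resamples: int = 10,
    seed: int = 0,
    window_ms: float = 80.0,
) -> np.ndarray:
    """Label-shuffle null time courses, averaged across participants.

    Trial labels are shuffled independently within each participant; the
    per-participant curve uses the same stratified-resampling protocol as the
    true statistic; the subject average forms one null curve.  Returns an
    (n_perm, n_windows) array.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable tail quantiles", stacklevel=2)
    if isinstance(epochs, EpochArray):
        epochs_list: list[EpochArray] = [epochs]
        labels_list = [list(labels)]
    else:
        epochs_list = list(epochs)
        labels_list = [list(l) for l in labels]
    if len({len(l) for l in labels_list} | {e.n_trials for e, l in zip(epochs_list, labels_list)}) > 2:
        pass  # per-subject trial counts may differ; only each pair must agree
    for e, l in zip(epochs_list, labels_list):
        if e.n_trials != len(l):
            raise MissingConditionError("labels/trials mismatch for a participant")
        if len(set(l)) < 2:
            raise MissingConditionError("need at least 2 distinct labels")

    t0 = float(epochs_list[0].times[0])
    t1 = t0 + epochs_list[0].data.shape[2] * 1000.0 / epochs_list[0].sfreq
    windows = window_partition(t0, t1, window_ms)
    wms = [window_means(e, windows) for e in epochs_list]
    orders = [_condition_order(l, order_label) for l in labels_list]

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(windows)))
    for p in range(n_perm):
        acc = np.zeros(len(windows))
        for wm, labs, order in zip(wms, labels_list, orders):
            perm = rng.permutation(len(labs))
            shuffled = [labs[i] for i in perm]
            groups = _group_indices(shuffled, order)
            acc += _curve(wm, groups, rng, n_resamples)
        null[p] = acc / len(wms)
    return null


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, end) inclusive index pairs."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def _max_run(mask: np.ndarray) -> int:
    runs = _runs(mask)
    return max((e - s + 1 for s, e in runs), default=0)


def cluster_test(
    true_tc: CircularityTimecourse | np.ndarray,
    null_tcs: np.ndarray,
    alpha: float = 0.05,
    pointwise: str = "per_window",
    tail: str = "greater",
) -> ClusterSet:
    """Cluster-based permutation test on a time course.

    Pointwise threshold: per-window (default) or pooled (1 - alpha) quantile
    of the null curves.  Cluster statistic: run length of contiguous
    supra-threshold windows; the null of maximal run lengths over the null
    curves (thresholded identically) gives each observed cluster a
    permutation p-value p = (1 + #{null_max >= size}) / (1 + n_perm).
    """
    values = true_tc.values if isinstance(true_tc, CircularityTimecourse) else np.asarray(true_tc, float)
    null = np.asarray(null_tcs, dtype=float)
    if null.ndim != 2 or null.shape[1] != len(values):
        raise IncompatibleSpaceError("null curves must be (n_perm, n_windows)")
    n_perm = null.shape[0]

    def exceed(curve: np.ndarray, hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
        if tail == "greater":
            return curve > hi
        if tail == "less":
            return curve < lo
        if tail == "two":
            return (curve > hi) | (curve < lo)
        raise InvalidParameterError(f"unknown tail {tail!r}")

    a = alpha / 2 if tail == "two" else alpha
    if pointwise == "per_window":
        hi = np.quantile(null, 1 - a, axis=0)
        lo = np.quantile(null, a, axis=0)
    elif pointwise == "pooled":
        hi = np.full(len(values), np.quantile(null, 1 - a))
        lo = np.full(len(values), np.quantile(null, a))
    else:
        raise InvalidParameterError(f"unknown pointwise rule {pointwise!r}")

    null_max = np.array([_max_run(exceed(null[i], hi, lo)) for i in range(n_perm)])
    cluster_threshold = float(np.quantile(null_max, 0.95)) if n_perm else np.inf

    clusters = []
    for s, e in _runs(exceed(values, hi, lo)):
        size = e - s + 1
        p = (1.0 + np.sum(null_max >= size)) / (1.0 + n_perm)
        clusters.append(Cluster(s, e, size, float(p), bool(p <= alpha)))
    return ClusterSet(clusters, hi if tail != "less" else lo, cluster_threshold, alpha)


# ---------------------------------------------------------------------------
# behavioral analyses
# ---------------------------------------------------------------------------

def combined_error(trials: pd.DataFrame) -> np.ndarray:
    """Sum of z-scored absolute color and size errors, per trial.

    If one error column is constant its z-score is undefined; the other
    component is returned alone (with a warning).
    """
    parts = []
    for col in ("size_error", "color_error"):
        if col not in trials:
            raise InvalidParameterError(f"missing error column {col!r}")
        a = np.abs(np.asarray(trials[col], dtype=float))
        sd = a.std()
        if sd == 0:
            warnings.warn(f"|{col}| has zero variance; excluded from combined error",
                          stacklevel=2)
            continue
        parts.append((a - a.mean()) / sd)
    if not parts:
        return np.zeros(len(trials))
    return np.sum(parts, axis=0)


@dataclass
class SplitResult:
    diff_timecourse: np.ndarray
    good_timecourse: np.ndarray
    bad_timecourse: np.ndarray
    window_centers: np.ndarray
    split_rule: str
    clusters: ClusterSet | None = None

    @property
    def significant_windows(self) -> set[int]:
        if self.clusters is None:
            return set()
        return {
            w for c in self.clusters.significant_clusters for w in range(c.start, c.end + 1)
        }


def _group_rng(seed: int, idx: np.ndarray) -> np.random.Generator:
    """RNG keyed by the trial-index *set*, so a group's resample draws do not
    depend on whether it is called 'good' or 'bad' (exact split symmetry)."""
    idx = np.sort(np.asarray(idx))
    ent = [int(seed), len(idx), int(idx.sum() % (2**31)), int(idx[0]), int(idx[-1])]
    return np.random.default_rng(np.random.SeedSequence(ent))


def _split_curves(
    wm: np.ndarray,
    labels: list,
    order: list,
    sub_idx: np.ndarray,
    seed: int,
    n_resamples: int,
) -> np.ndarray:
    """Circularity curve of a trial subset projected into the all-trials plane."""
    n_trials, n_ch, n_win = wm.shape
    # whole-data subspace per window (no resampling; it is shared by both splits)
    all_groups = _group_indices(labels, order)
    cm_all = np.stack([wm[idx].mean(axis=0) for idx in all_groups])  # (cond, ch, win)
    m_all = cm_all.transpose(2, 0, 1)  # (win, cond, ch)
    mu = m_all.mean(axis=1, keepdims=True)
    sd = m_all.std(axis=1, keepdims=True)
    z_all = np.where(sd > 0, (m_all - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    gram = z_all @ np.swapaxes(z_all, -1, -2)
    w, u = np.linalg.eigh(gram)
    s2 = np.clip(w[..., ::-1][..., :2], 0.0, None)
    uu = u[..., ::-1][..., :2]
    s = np.sqrt(s2)
    inv_s = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    comps = np.swapaxes(z_all, -1, -2) @ (uu * inv_s[..., None, :])  # (win, ch, 2)

    sub_idx = np.sort(np.asarray(sub_idx))  # canonical order: draws depend on
    sub_labels = [labels[i] for i in sub_idx]  # the set, not the split's role
    sub_groups_local = _group_indices(sub_labels, order)
    sub_groups = [sub_idx[g] for g in sub_groups_local]
    rng = _group_rng(seed, sub_idx)
    reps = n_resamples
    acc = np.zeros(n_win)
    for _ in range(reps):
        cm = np.stack([
            wm[rng.choice(idx, size=len(idx), replace=True)].mean(axis=0)
            for idx in sub_groups
        ])  # (cond, ch, win)
        m = cm.transpose(2, 0, 1)
        z = np.where(sd > 0, (m - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        xy = z @ comps
        acc += polygon_circularity(xy)
    return acc / reps


def trial_split_difference(
    epochs: EpochArray,
    labels: Sequence,
    combined_error_values: np.ndarray,
    order_label: str = "goal_square",
    rule: str = "quartile",
    n_perm: int = 500,
    n_resamples: int = 5,
    seed: int = 0,
    window_ms: float = 80.0,
    alpha: float = 0.05,
    tail: str = "two",
) -> SplitResult:
    """Good-minus-bad circularity difference with a label-swap permutation null.

    Good/bad trials are the bottom/top quartiles (or halves) of the combined
    behavioral error.  Both splits are projected into the subspace fitted on
    ALL trials so the comparison is fair; the null swaps good/bad membership
    within condition, preserving per-condition coverage.
    """
    labels = list(labels)
    err = np.asarray(combined_error_values, dtype=float)
    if len(err) != len(labels) or epochs.n_trials != len(labels):
        raise InvalidParameterError("labels, errors and trials must align")
    order = _condition_order(labels, order_label)

    rank = np.argsort(err, kind="stable")
    n = len(err)
    if rule == "quartile":
        k = n // 4
    elif rule == "median":
        k = n // 2
    else:
        raise InvalidParameterError(f"unknown split rule {rule!r}")
    good_idx = rank[:k]
    bad_idx = rank[-k:]

    for name, idx in (("good", good_idx), ("bad", bad_idx)):
        present = {labels[i] for i in idx}
        missing = [c for c in order if c not in present]
        if missing:
            raise SplitCoverageError(
                f"{name} split lacks conditions {missing}; use the median rule"
            )

    t0 = float(epochs.times[0])
    t1 = t0 + epochs.data.shape[2] * 1000.0 / epochs.sfreq
    windows = window_partition(t0, t1, window_ms)
    wm = window_means(epochs, windows)

    good_tc = _split_curves(wm, labels, order, good_idx, seed, n_resamples)
    bad_tc = _split_curves(wm, labels, order, bad_idx, seed, n_resamples)
    diff = good_tc - bad_tc

    # permutation null: reshuffle good/bad membership within condition
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_919]))
    pool = np.concatenate([good_idx, bad_idx])
    pool_by_cond = {}
    n_good_by_cond = {}
    for c in order:
        members = np.array([i for i in pool if labels[i] == c])
        pool_by_cond[c] = members
        n_good_by_cond[c] = int(np.sum([labels[i] == c for i in good_idx]))
    null = np.empty((n_perm, len(windows)))
    for p in range(n_perm):
        g_parts, b_parts = [], []
        for c in order:
            members = rng.permutation(pool_by_cond[c])
            ng = n_good_by_cond[c]
            g_parts.append(members[:ng])
            b_parts.append(members[ng:])
        g = np.concatenate(g_parts)
        b = np.concatenate(b_parts)
        null[p] = (
            _split_curves(wm, labels, order, g, seed + 1 + p, n_resamples)
            - _split_curves(wm, labels, order, b, seed + 1 + p, n_resamples)
        )
    clusters = cluster_test(diff, null, alpha=alpha, tail=tail)
    return SplitResult(diff, good_tc, bad_tc, windows.mean(axis=1), rule, clusters)


def behavior_correlation(
    circularity_by_cell: pd.DataFrame,
    error_by_subject: Sequence[float],
    alternative: str = "two-sided",
    q: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of per-subject circularity with behavioral error.

    One test per column (e.g., epoch x channel-group cell); Benjamini-Hochberg
    adjustment across the tested family.  Constant inputs are flagged and
    excluded from the family.
    """
    err = np.asarray(error_by_subject, dtype=float)
    if len(circularity_by_cell) < 5 or len(err) < 5:
        raise InsufficientDataError("need at least 5 subjects")
    rows = []
    for col in circularity_by_cell.columns:
        x = np.asarray(circularity_by_cell[col], dtype=float)
        if np.std(x) == 0 or np.std(err) == 0:
            rows.append({"cell": col, "r": np.nan, "p": np.nan, "excluded": True})
            continue
        r, p = stats.spearmanr(x, err, alternative=alternative)
        rows.append({"cell": col, "r": float(r), "p": float(p), "excluded": False})
    out = pd.DataFrame(rows)
    tested = ~out["excluded"]
    out["p_fdr"] = np.nan
    if tested.any():
        out.loc[tested, "p_fdr"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] <= q
    return out


def motor_relabel(trials: pd.DataFrame) -> tuple[list[tuple], np.ndarray]:
    """Adjustment-direction labels from the response object trajectory.

    The label is the sign pair of (final - initial) on size and color; trials
    with a zero difference on either feature carry no adjustment direction and
    are excluded (logged).  Returns (labels for kept trials, keep mask).
    """
    for col in ("initial_size", "final_size", "initial_color", "final_color"):
        if col not in trials:
            raise InvalidParameterError(f"missing response-object column {col!r}")
    ds = np.asarray(trials["final_size"], float) - np.asarray(trials["initial_size"], float)
    dc = np.asarray(trials["final_color"], float) - np.asarray(trials["initial_color"], float)
    keep = (ds != 0) & (dc != 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("motor_relabel: %d no-adjustment trials excluded", n_dropped)
    labels = [
        ("bigger" if s > 0 else "smaller", "greener" if c > 0 else "redder")
        for s, c in zip(ds[keep], dc[keep])
    ]
    return labels, keep


def incorrect_goal_relabel(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials whose adjustment direction contradicts the cued goal, relabeled.

    The returned subset carries the *actual* adjustment direction as its goal
    label; an empty frame signals that no incorrect trials exist.
    """
    for col in ("response_dir_size", "response_dir_color"):
        if col not in trials:
            raise InvalidParameterError(f"missing response direction column {col!r}")
    wrong = (trials["response_dir_size"] != trials["goal_size"]) | (
        trials["response_dir_color"] != trials["goal_color"]
    )
    out = trials.loc[wrong].copy()
    if out.empty:
        warnings.warn("no incorrect-adjustment trials in table", stacklevel=2)
        return out
    out["goal_size"] = out["response_dir_size"]
    out["goal_color"] = out["response_dir_color"]
    return out


def chi2_independence(labels_a: Sequence, labels_b: Sequence):
    """Chi-square test of independence between two label sequences."""
    table = pd.crosstab(pd.Series(list(labels_a)), pd.Series(list(labels_b)))
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(dof), table
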
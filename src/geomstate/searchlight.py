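"""Volumetric searchlight circularity and beta-series connectivity.

For every in-mask voxel, the voxels within a 9-mm sphere act as the
"channels" of the condition-geometry pipeline: trial-wise betas are averaged
per condition, standardized, reduced to the top-2 PCs, projected, connected
in the design order, and scored by circularity.  Group inference bootstraps
label-shuffled searchlight maps across subjects into a voxelwise null, then
corrects over space with a max-cluster-size null under face adjacency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidMaskError,
    InvalidParameterError,
    InvalidRoiError,
)
from .geometry import (
    ORDER_CONVENTIONS,
    polygon_circularity,
    standardize_conditions,
    top2_scores,
)
from .simulate import BetaVolume
from .timecourse import _group_indices

logger = logging.getLogger(__name__)

__all__ = [
    "SearchlightMap",
    "GroupCluster",
    "GroupClusterResult",
    "sphere_neighborhoods",
    "searchlight_circularity",
    "group_cluster_correction",
    "roi_robustness",
    "beta_series_fc",
    "fc_brain_behavior",
]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class SearchlightMap:
    """Circularity per in-mask voxel (NaN elsewhere)."""

    values: np.ndarray  # full 3D volume
    sphere_radius: float
    mask: np.ndarray


def _flatten(beta: BetaVolume) -> tuple[np.ndarray, np.ndarray]:
    """In-mask voxel ijk list and the (trials, n_voxels) data matrix."""
    ijk = np.argwhere(beta.mask)
    if len(ijk) == 0:
        raise InvalidMaskError("mask is empty")
    flat = beta.data[beta.mask].T  # (trials, n_voxels)
    return ijk, flat


def sphere_neighborhoods(
    mask: np.ndarray,
    voxel_size: float,
    radius_mm: float = 9.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Indices of in-mask voxels within ``radius_mm`` of each in-mask voxel.

    Distances are center-to-center in mm, radius inclusive; spheres at mask
    edges simply keep their in-mask members.  Returns (neighborhood list,
    in-mask voxel ijk array); neighborhood entries index into that list.
    """
    if radius_mm < voxel_size:
        raise InvalidParameterError("radius must be at least one voxel")
    ijk = np.argwhere(np.asarray(mask, dtype=bool))
    if len(ijk) == 0:
        raise InvalidMaskError("mask is empty")
    tree = cKDTree(ijk * float(voxel_size))
    hoods = tree.query_ball_point(ijk * float(voxel_size), r=radius_mm + 1e-9)
    return [np.asarray(sorted(h), dtype=int) for h in hoods], ijk


def searchlight_circularity(
    beta: BetaVolume,
    labels,
    spheres: list[np.ndarray] | None = None,
    order_label: str = "goal_square",
    radius_mm: float = 9.0,
) -> SearchlightMap:
    """Circularity map: one condition-geometry fit per sphere.

    Condition means over trials are computed once per voxel (averaging
    commutes with sphere gathering), then each sphere's conditions x voxels
    matrix runs through the standard pipeline.  Spheres with fewer than 3
    voxels are set to NaN.
    """
    labels = list(labels)
    ijk, flat = _flatten(beta)
    if flat.shape[0] != len(labels):
        raise InvalidParameterError("one label per trial required")
    if spheres is None:
        spheres, _ = sphere_neighborhoods(beta.mask, beta.voxel_size, radius_mm)

    order = ORDER_CONVENTIONS.get(order_label) or sorted(set(labels))
    groups = _group_indices(labels, order)
    cond_means = np.stack([flat[g].mean(axis=0) for g in groups])  # (ncond, nvox)

    values = np.full(len(spheres), np.nan)
    by_size: dict[int, list[int]] = {}
    for v, nb in enumerate(spheres):
        if len(nb) < 3:
            logger.info("sphere at voxel %d has %d voxels; skipped", v, len(nb))
            continue
        by_size.setdefault(len(nb), []).append(v)
    for size, voxels in by_size.items():
        idx = np.stack([spheres[v] for v in voxels])  # (k, size)
        mats = cond_means[:, idx].transpose(1, 0, 2)  # (k, ncond, size)
        z = standardize_conditions(mats)
        values[np.asarray(voxels)] = polygon_circularity(top2_scores(z))

    vol = np.full(beta.mask.shape, np.nan)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = values
    return SearchlightMap(vol, radius_mm, beta.mask.copy())


@dataclass
class GroupCluster:
    voxels_ijk: np.ndarray
    size: int
    center_of_mass_mm: np.ndarray
    peak_ijk: np.ndarray
    p_value: float
    significant: bool


@dataclass
class GroupClusterResult:
    group_map: np.ndarray
    voxel_threshold: np.ndarray  # full volume of per-voxel thresholds
    cluster_size_threshold: float
    clusters: list[GroupCluster] = field(default_factory=list)
    labeled_volume: np.ndarray | None = None

    @property
    def significant_clusters(self) -> list[GroupCluster]:
        return [c for c in self.clusters if c.significant]


def group_cluster_correction(
    true_maps: list[SearchlightMap],
    permuted_maps: list[list[SearchlightMap]],
    n_bootstrap: int = 10_000,
    voxel_alpha: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
    voxel_size: float = 1.0,
) -> GroupClusterResult:
    """Group cluster correction from per-subject label-shuffle maps.

    The group null is a bootstrap over subjects: each draw averages one
    randomly chosen permuted map per subject.  Voxels where the true group
    mean exceeds the per-voxel (1 - voxel_alpha) null quantile are clustered
    by FACE adjacency; the max-cluster-size distribution over the null draws
    (thresholded identically) calibrates cluster significance.
    """
    if len(true_maps) != len(permuted_maps):
        raise InvalidParameterError("one permuted-map list per subject required")
    usable = [i for i, pm in enumerate(permuted_maps) if len(pm) > 0]
    if len(usable) < len(true_maps):
        warnings.warn("subjects without permuted maps excluded", stacklevel=2)
    if len(usable) < 2:
        raise InsufficientDataError("need at least 2 subjects with permuted maps")
    mask = true_maps[usable[0]].mask
    ijk = np.argwhere(mask)

    def flat(m: SearchlightMap) -> np.ndarray:
        return m.values[mask]

    true_stack = np.stack([flat(true_maps[i]) for i in usable])
    group_true = np.nanmean(true_stack, axis=0)
    perm_flat = [np.stack([flat(m) for m in permuted_maps[i]]) for i in usable]

    rng = np.random.default_rng(seed)
    n_vox = len(ijk)
    null = np.empty((n_bootstrap, n_vox))
    for b in range(n_bootstrap):
        draw = [pf[rng.integers(len(pf))] for pf in perm_flat]
        null[b] = np.nanmean(draw, axis=0)

    thr = np.nanquantile(null, 1 - voxel_alpha, axis=0)

    def clusters_of(values: np.ndarray) -> tuple[np.ndarray, int]:
        vol = np.zeros(mask.shape, dtype=bool)
        supra = values > thr
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.nan_to_num(supra, nan=False)
        labeled, n = ndimage.label(vol, structure=_FACE_STRUCTURE)
        return labeled, n

    null_max = np.zeros(n_bootstrap, dtype=int)
    for b in range(n_bootstrap):
        labeled, n = clusters_of(null[b])
        if n:
            null_max[b] = int(np.bincount(labeled.ravel())[1:].max())
    size_thr = float(np.quantile(null_max, 0.95)) if n_bootstrap else np.inf

    labeled, n = clusters_of(group_true)
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labeled == lab)
        size = len(vox)
        p = (1.0 + np.sum(null_max >= size)) / (1.0 + n_bootstrap)
        in_cluster = labeled[vox[:, 0], vox[:, 1], vox[:, 2]] == lab
        gvol = np.full(mask.shape, -np.inf)
        gvol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.nan_to_num(group_true, nan=-np.inf)
        peak = vox[np.argmax(gvol[vox[:, 0], vox[:, 1], vox[:, 2]])]
        clusters.append(
            GroupCluster(
                voxels_ijk=vox,
                size=size,
                center_of_mass_mm=vox.mean(axis=0) * voxel_size,
                peak_ijk=peak,
                p_value=float(p),
                significant=bool(p <= alpha),
            )
        )
    gmap = np.full(mask.shape, np.nan)
    gmap[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = group_true
    tvol = np.full(mask.shape, np.nan)
    tvol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = thr
    return GroupClusterResult(gmap, tvol, size_thr, clusters, labeled)


def _roi_flat_indices(beta: BetaVolume, roi) -> np.ndarray:
    """Map an ROI given as ijk rows (n, 3) to indices into the in-mask list."""
    ijk = np.argwhere(beta.mask)
    roi = np.asarray(roi)
    if roi.ndim == 2 and roi.shape[1] == 3:
        lut = {tuple(v): i for i, v in enumerate(map(tuple, ijk))}
        try:
            return np.array([lut[tuple(v)] for v in map(tuple, roi)], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise InvalidRoiError(f"ROI voxel {e} outside mask") from e
    return roi.astype(int)


def roi_robustness(
    beta: BetaVolume,
    roi,
    labels,
    order_label: str = "goal_square",
    n_boot: int = 20,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Trial-bootstrap circularity of an ROI and its label-shuffle p-value.

    The estimate averages ``n_boot`` stratified trial-bootstrap replicates
    over all ROI voxels; the null repeats the identical procedure with
    shuffled labels.  Returns (mean circularity, permutation p).
    """
    roi_idx = _roi_flat_indices(beta, roi)
    if len(roi_idx) < 3:
        raise InvalidRoiError("ROI must contain at least 3 voxels")
    labels = list(labels)
    _, flat = _flatten(beta)
    x = flat[:, roi_idx]  # (trials, nvox)
    order = ORDER_CONVENTIONS.get(order_label) or sorted(set(labels))
    rng = np.random.default_rng(seed)

    def estimate(labs) -> float:
        groups = _group_indices(labs, order)
        acc = 0.0
        for _ in range(n_boot):
            cm = np.stack([
                x[rng.choice(g, size=len(g), replace=True)].mean(axis=0) for g in groups
            ])
            acc += float(polygon_circularity(top2_scores(standardize_conditions(cm))))
        return acc / n_boot

    true_c = estimate(labels)
    null = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        null[p] = estimate(shuffled)
    pval = (1.0 + np.sum(null >= true_c)) / (1.0 + n_perm)
    return true_c, float(pval)


def beta_series_fc(beta: BetaVolume, rois: dict[str, np.ndarray]) -> pd.DataFrame:
    """ROI x ROI Pearson correlation of trial-wise mean betas.

    Betas are averaged over each ROI's voxels per trial; the correlation runs
    across trials.  Constant series yield NaN entries (flagged by warning).
    """
    if len(rois) < 2:
        raise InvalidParameterError("need at least 2 ROIs")
    _, flat = _flatten(beta)
    if flat.shape[0] < 3:
        raise InsufficientDataError("need at least 3 trials")
    names = list(rois)
    series = np.column_stack([flat[:, _roi_flat_indices(beta, rois[n])].mean(axis=1)
                              for n in names])
    sds = series.std(axis=0)
    if np.any(sds == 0):
        warnings.warn("constant ROI beta series; correlations undefined", stacklevel=2)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(series.T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def fc_brain_behavior(
    fc_by_subject: list[pd.DataFrame],
    behavior,
    family: list[tuple[str, str]],
    bayes: bool = True,
    q: float = 0.05,
) -> pd.DataFrame:
    """Spearman of each declared connection with a per-subject measure.

    ``family`` declares the connection set tested (e.g., the 9 goal-goal or
    12 goal-stimulus pairs); BH adjustment runs within that family.  BF10 is
    the default JZS correlation Bayes factor (optional column).
    """
    y = np.asarray(behavior, dtype=float)
    if len(fc_by_subject) != len(y) or len(y) < 5:
        raise InsufficientDataError("need paired FC matrices and behavior for >= 5 subjects")
    for a, b in family:
        for m in fc_by_subject:
            if a not in m.index or b not in m.columns:
                raise ConfigurationError(f"connection ({a}, {b}) missing from an FC matrix")
    rows = []
    n = len(y)
    for a, b in family:
        x = np.array([m.loc[a, b] for m in fc_by_subject], dtype=float)
        r, p = stats.spearmanr(x, y)
        row = {"roi_a": a, "roi_b": b, "r": float(r), "p": float(p)}
        if bayes:
            import pingouin as pg

            row["bf10"] = float(pg.bayesfactor_pearson(r, n))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] <= q
    return out
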
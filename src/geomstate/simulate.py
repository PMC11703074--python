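"""Synthetic task data with planted, known geometry.

Every downstream stage (subspace fitting, circularity time courses, cluster
permutation inference, RSA, coherence, searchlight) is validated by parameter
recovery, so this module is first-class tested code: it emulates the working
memory task design — a counterbalanced 4-goal x 3x3-stimulus factorial
(18 repetitions => 648 trials in 12 blocks), epochs from -500 to +4300 ms at
250 Hz, and a latent 2D square goal geometry plus 3x3 stimulus grid mixed
linearly into channels (or voxels) under additive Gaussian noise.

Signal model: for trial i with condition c and latent plane coordinates
u_c in R^2, the clean channel signal is  gain_i * a(t) * M @ u_c  with M a
channels x 2 mixing matrix with orthonormal columns and a(t) a piecewise
constant activation profile over the task epochs.  Under this model PCA on
standardized condition means provably recovers the planted plane, so the
analytic circularity of the planted polygon is the ground truth for the whole
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GeometryPlacementError,
    InvalidParameterError,
    InvalidSpecError,
    MissingConditionError,
)
from .geometry import GOAL_ORDER

__all__ = [
    "EPOCH_BOUNDS_MS",
    "FRONTAL_CHANNELS",
    "CENTRAL_CHANNELS",
    "POSTERIOR_CHANNELS",
    "DesignSpec",
    "ColorSpaceSpec",
    "PlantedGeometry",
    "EpochArray",
    "BetaVolume",
    "color_space",
    "generate_design",
    "goal_square_coords",
    "stimulus_grid_coords",
    "random_mixing",
    "epoch_activation",
    "default_channel_layout",
    "generate_epochs",
    "generate_behavior",
    "generate_beta_volumes",
    "goal_labels",
    "stimulus_labels",
    "stimulus_hex_subset",
]

# Task epoch boundaries in ms relative to goal-cue onset.
EPOCH_BOUNDS_MS: dict[str, tuple[float, float]] = {
    "goal_cue": (0.0, 400.0),
    "delay1": (400.0, 1700.0),
    "sample": (1700.0, 2300.0),
    "delay2": (2300.0, 3800.0),
    "response": (3800.0, 4300.0),
}

# Extended 10-20 channel groups (16 frontal / 26 central / 17 posterior).
FRONTAL_CHANNELS = [
    "Fp1", "Fz", "F3", "F7", "F4", "F8", "Fp2", "AF7",
    "AF3", "AFz", "F1", "F5", "F6", "AF8", "AF4", "F2",
]
CENTRAL_CHANNELS = [
    "FC5", "FC1", "C3", "T7", "CP5", "CP1", "CP6", "CP2", "Cz", "C4",
    "T8", "FC6", "FC2", "FT7", "FC3", "C1", "C5", "TP7", "CP3", "CPz",
    "CP4", "TP8", "C6", "C2", "FC4", "FT8",
]
POSTERIOR_CHANNELS = [
    "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8", "P1",
    "P5", "PO7", "PO3", "POz", "PO4", "PO8", "P6", "P2",
]

_GOAL_LEVELS = [
    ("bigger", "redder"),
    ("bigger", "greener"),
    ("smaller", "redder"),
    ("smaller", "greener"),
]


@dataclass(frozen=True)
class DesignSpec:
    """Factorial task design: goals x size bins x color bins x repetitions."""

    n_goals: int = 4
    size_bins: int = 3
    color_bins: int = 3
    reps_per_cell: int = 18
    n_blocks: int = 12

    @property
    def n_trials(self) -> int:
        return self.n_goals * self.size_bins * self.color_bins * self.reps_per_cell

    def validate(self) -> None:
        for name in ("n_goals", "size_bins", "color_bins", "reps_per_cell", "n_blocks"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.n_goals != 4:
            raise InvalidSpecError("the goal factor is the 2x2 size-by-color cross (4 goals)")


@dataclass(frozen=True)
class ColorSpaceSpec:
    """Color-morph ladder: raw rendered variants minus discarded extremes."""

    n_raw_variants: int = 150
    n_discarded_extremes: int = 30

    @property
    def usable_steps(self) -> int:
        return self.n_raw_variants - self.n_discarded_extremes


def color_space(spec: ColorSpaceSpec) -> int:
    """Number of usable color-adjustment steps."""
    if spec.n_discarded_extremes >= spec.n_raw_variants:
        raise InvalidSpecError("cannot discard all (or more) color variants")
    return spec.usable_steps


def generate_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Counterbalanced trial table: every goal x stimulus cell exactly
    ``reps_per_cell`` times, in a seeded random order.

    The response object starts at a random continuous value and is adjusted
    to the goal-consistent target, so the *direction* of motor adjustment is
    (by design) nearly independent of the goal — the substrate for the
    motor-control analysis.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for (gs, gc), sb, cb, rep in product(
        _GOAL_LEVELS, range(1, spec.size_bins + 1), range(1, spec.color_bins + 1),
        range(spec.reps_per_cell),
    ):
        rows.append((gs, gc, sb, cb))
    df = pd.DataFrame(rows, columns=["goal_size", "goal_color", "size_bin", "color_bin"])
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    n = len(df)
    df.insert(0, "trial_id", np.arange(n))
    df.insert(1, "block", np.arange(n) * spec.n_blocks // n)

    sdir = np.where(df["goal_size"] == "bigger", 1, -1)
    cdir = np.where(df["goal_color"] == "greener", 1, -1)  # color axis: red -> green
    df["response_size_bin"] = np.clip(df["size_bin"] + sdir, 1, spec.size_bins)
    df["response_color_bin"] = np.clip(df["color_bin"] + cdir, 1, spec.color_bins)
    df["response_dir_size"] = df["goal_size"]
    df["response_dir_color"] = df["goal_color"]

    # continuous response-object trajectory (size in arbitrary units 0-100,
    # color in morph steps 0-120); initial values uniform over the range
    df["initial_size"] = rng.uniform(5.0, 95.0, n)
    df["initial_color"] = rng.uniform(5.0, 115.0, n)
    df["final_size"] = 25.0 * df["response_size_bin"]
    df["final_color"] = 30.0 * df["response_color_bin"]

    df["size_error"] = 0.0
    df["color_error"] = 0.0
    return df


# ---------------------------------------------------------------------------
# planted geometries
# ---------------------------------------------------------------------------

@dataclass
class PlantedGeometry:
    """Latent 2D condition layout, channel mixing, and activation profile.

    ``coords`` maps condition label -> (x, y); ``mixing`` is channels x 2 with
    unit-norm (orthonormal) columns; ``activation`` is a gain profile over
    time — either an array aligned with the epoch samples, a mapping of task
    epoch name -> gain (piecewise constant), or a mapping of channel-group
    name -> either of those (to activate e.g. frontal channels early and
    posterior channels late).  ``label`` names the trial-table columns that
    carry the condition ("goal" or "stimulus"), or is a callable on the table.
    """

    coords: Mapping[tuple, tuple[float, float]]
    mixing: np.ndarray | None = None
    activation: object = field(default_factory=lambda: {"delay1": 1.0})
    label: str | Callable = "goal"
    snr: float | None = None

    def labels_for(self, trials: pd.DataFrame) -> list:
        if callable(self.label):
            return list(self.label(trials))
        if self.label == "goal":
            return list(zip(trials["goal_size"], trials["goal_color"]))
        if self.label == "stimulus":
            return list(zip(trials["size_bin"].astype(int), trials["color_bin"].astype(int)))
        raise InvalidSpecError(f"unknown label source {self.label!r}")


def goal_square_coords(side: float = 2.0) -> dict[tuple, tuple[float, float]]:
    """Square goal layout of side ``side``, vertices in the design walk order."""
    h = side / 2.0
    layout = [(h, h), (h, -h), (-h, -h), (-h, h)]
    return {cond: xy for cond, xy in zip(GOAL_ORDER, layout)}


def stimulus_grid_coords(spacing: float = 1.0) -> dict[tuple, tuple[float, float]]:
    """3x3 stimulus grid: (size_bin, color_bin) -> spaced lattice coordinates."""
    return {
        (s, c): (spacing * (s - 2), spacing * (c - 2))
        for s in (1, 2, 3)
        for c in (1, 2, 3)
    }


def random_mixing(
    n_channels: int,
    rng: np.random.Generator,
    equal_gain: bool = True,
) -> np.ndarray:
    """Channels x 2 mixing with orthonormal columns.

    With ``equal_gain`` (default), every channel's loading vector has the same
    magnitude and the loading angles are equally spaced with a random global
    rotation and a random channel permutation.  Equal per-channel signal power
    matters: the analysis z-scores each channel across conditions, and only
    an equal-gain mixing passes through that standardization undistorted, so
    the planted polygon's analytic circularity is recovered exactly in the
    noise-free limit.  ``equal_gain=False`` draws an unconstrained random
    orthonormal pair (QR of a Gaussian matrix) instead.
    """
    if not equal_gain:
        q, _ = np.linalg.qr(rng.standard_normal((n_channels, 2)))
        return q
    theta = rng.uniform(0, np.pi) + np.pi * np.arange(n_channels) / n_channels
    m = np.column_stack([np.cos(theta), np.sin(theta)]) / np.sqrt(n_channels / 2.0)
    return m[rng.permutation(n_channels)]


def epoch_activation(
    times: np.ndarray,
    gains: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]] = EPOCH_BOUNDS_MS,
) -> np.ndarray:
    """Piecewise-constant activation profile from task-epoch gains."""
    act = np.zeros_like(np.asarray(times, dtype=float))
    for name, g in gains.items():
        lo, hi = bounds[name]
        act[(times >= lo) & (times < hi)] = g
    return act


def default_channel_layout(n_channels: int) -> tuple[list[str], dict[str, np.ndarray]]:
    """Channel names and frontal/central/posterior group indices.

    With 59 channels the extended 10-20 names are used; otherwise three
    synthetic groups in the same 16/26/17 proportions.
    """
    if n_channels == 59:
        names = FRONTAL_CHANNELS + CENTRAL_CHANNELS + POSTERIOR_CHANNELS
        sizes = [16, 26, 17]
    else:
        names = [f"ch{i:03d}" for i in range(n_channels)]
        nf = max(1, round(n_channels * 16 / 59))
        nc = max(1, round(n_channels * 26 / 59))
        nf = min(nf, n_channels - 2)
        nc = min(nc, n_channels - nf - 1)
        sizes = [nf, nc, n_channels - nf - nc]
    edges = np.cumsum([0] + sizes)
    groups = {
        g: np.arange(edges[i], edges[i + 1])
        for i, g in enumerate(("frontal", "central", "posterior"))
    }
    return names, groups


@dataclass
class EpochArray:
    """Epoched multichannel data: trials x channels x samples."""

    data: np.ndarray
    times: np.ndarray  # ms relative to goal-cue onset
    sfreq: float
    ch_names: list[str]
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, group_or_names) -> "EpochArray":
        """Restrict to a named channel group or an explicit name list."""
        if isinstance(group_or_names, str):
            idx = np.asarray(self.groups[group_or_names])
        else:
            idx = np.array([self.ch_names.index(n) for n in group_or_names])
        return EpochArray(
            data=self.data[:, idx],
            times=self.times,
            sfreq=self.sfreq,
            ch_names=[self.ch_names[i] for i in idx],
            groups={},
        )

    def select_trials(self, mask_or_index) -> "EpochArray":
        return EpochArray(
            data=self.data[np.asarray(mask_or_index)],
            times=self.times,
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            groups=dict(self.groups),
        )


def _activation_array(
    geometry: PlantedGeometry,
    times: np.ndarray,
    n_channels: int,
    groups: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Resolve a geometry's activation spec to a (channels, samples) gain."""
    act = geometry.activation
    if callable(act):
        act = act(times)
    if isinstance(act, Mapping):
        keys = set(act.keys())
        if keys and keys <= set(groups.keys()):
            out = np.zeros((n_channels, len(times)))
            for g, sub in act.items():
                prof = sub(times) if callable(sub) else sub
                if isinstance(prof, Mapping):
                    prof = epoch_activation(times, prof)
                out[np.asarray(groups[g])] = np.asarray(prof, dtype=float)
            return out
        prof = epoch_activation(times, act)
        return np.broadcast_to(prof, (n_channels, len(times)))
    prof = np.asarray(act, dtype=float)
    if prof.ndim == 1:
        return np.broadcast_to(prof, (n_channels, len(times)))
    return prof


def generate_epochs(
    trials: pd.DataFrame,
    geometries: PlantedGeometry | Sequence[PlantedGeometry],
    n_channels: int = 59,
    sfreq: float = 250.0,
    t_start: float = -500.0,
    t_end: float = 4300.0,
    noise_sd: float = 1.0,
    trial_gain: np.ndarray | None = None,
    seed: int = 0,
) -> EpochArray:
    """Mix planted geometries into channels and add i.i.d. Gaussian noise.

    Each trial's clean signal is ``gain_i * a(ch, t) * (mixing @ coords[label_i])``
    summed over the planted geometries.  Geometries without a mixing matrix
    get a random orthonormal one drawn from the seed.
    """
    if t_end <= t_start:
        raise InvalidParameterError("t_end must exceed t_start")
    if sfreq <= 0:
        raise InvalidParameterError("sfreq must be positive")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if isinstance(geometries, PlantedGeometry):
        geometries = [geometries]

    n_samples = int(round((t_end - t_start) * sfreq / 1000.0))
    times = t_start + np.arange(n_samples) * 1000.0 / sfreq
    n_trials = len(trials)
    ch_names, groups = default_channel_layout(n_channels)

    ss = np.random.SeedSequence(seed)
    rng_noise, rng_mix = [np.random.default_rng(s) for s in ss.spawn(2)]
    data = rng_noise.normal(0.0, noise_sd, size=(n_trials, n_channels, n_samples))

    gain = np.ones(n_trials) if trial_gain is None else np.asarray(trial_gain, dtype=float)
    if gain.shape != (n_trials,):
        raise InvalidParameterError("trial_gain must have one entry per trial")

    for geom in geometries:
        mixing = geom.mixing
        if mixing is None:
            # per-group equal-gain blocks: analyses restricted to one channel
            # group then still see an exact (undistorted) planted polygon
            mixing = np.empty((n_channels, 2))
            for idx in groups.values():
                mixing[np.asarray(idx)] = random_mixing(len(idx), rng_mix) * np.sqrt(
                    len(idx) / n_channels
                )
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape != (n_channels, 2):
            raise InvalidSpecError("mixing must be n_channels x 2")
        labels = geom.labels_for(trials)
        missing = {l for l in labels if l not in geom.coords}
        if missing:
            raise MissingConditionError(f"no planted coordinates for conditions {sorted(missing)}")
        latent = np.array([geom.coords[l] for l in labels])  # (trials, 2)
        chan_sig = latent @ mixing.T  # (trials, channels)
        act = _activation_array(geom, times, n_channels, groups)  # (ch, ns)
        data += gain[:, None, None] * chan_sig[:, :, None] * act[None, :, :]

    return EpochArray(data=data, times=times, sfreq=sfreq, ch_names=ch_names, groups=groups)


def generate_behavior(
    trials: pd.DataFrame,
    geometry_strength_per_trial: np.ndarray,
    coupling: float,
    noise_sd: float,
    seed: int,
    lapse_rate: float = 0.0,
) -> pd.DataFrame:
    """Draw behavioral errors negatively coupled to planted geometry strength.

    The per-trial error scale is ``noise_sd * exp(-coupling * z(strength))``:
    stronger planted geometry shrinks the error spread, so with coupling > 0
    the bottom quartile of |error| carries the strongest geometry (and with
    coupling = 0 errors are independent of strength).  ``lapse_rate`` flips
    each response direction independently with that probability, producing
    the incorrect-goal trials used by the relabeling control.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    strength = np.asarray(geometry_strength_per_trial, dtype=float)
    if strength.shape != (len(trials),):
        raise InvalidParameterError("strength vector must have one entry per trial")
    rng = np.random.default_rng(seed)
    sdv = strength.std()
    z = (strength - strength.mean()) / sdv if sdv > 0 else np.zeros_like(strength)
    scale = np.exp(-coupling * z)

    out = trials.copy()
    out["size_error"] = rng.normal(0.0, noise_sd, len(out)) * scale
    out["color_error"] = rng.normal(0.0, noise_sd, len(out)) * scale

    if lapse_rate > 0:
        flip_s = rng.random(len(out)) < lapse_rate
        flip_c = rng.random(len(out)) < lapse_rate
        swap_s = {"bigger": "smaller", "smaller": "bigger"}
        swap_c = {"redder": "greener", "greener": "redder"}
        out.loc[flip_s, "response_dir_size"] = out.loc[flip_s, "response_dir_size"].map(swap_s)
        out.loc[flip_c, "response_dir_color"] = out.loc[flip_c, "response_dir_color"].map(swap_c)
        sdir = np.where(out["response_dir_size"] == "bigger", 1, -1)
        cdir = np.where(out["response_dir_color"] == "greener", 1, -1)
        out["response_size_bin"] = np.clip(out["size_bin"] + sdir, 1, out["size_bin"].max())
        out["response_color_bin"] = np.clip(out["color_bin"] + cdir, 1, out["color_bin"].max())
        out["final_size"] = 25.0 * out["response_size_bin"]
        out["final_color"] = 30.0 * out["response_color_bin"]
    return out


def goal_labels(trials: pd.DataFrame) -> list[tuple]:
    """Per-trial (goal_size, goal_color) condition labels."""
    return list(zip(trials["goal_size"], trials["goal_color"]))


def stimulus_labels(trials: pd.DataFrame) -> list[tuple]:
    """Per-trial (size_bin, color_bin) stimulus labels (full 3x3 grid)."""
    return list(zip(trials["size_bin"].astype(int), trials["color_bin"].astype(int)))


def stimulus_hex_subset(trials: pd.DataFrame) -> tuple[np.ndarray, list[tuple]]:
    """Trials and labels for the 6-vertex stimulus polygon.

    The middle color bin is dropped so the remaining 3-size x 2-color grid
    forms a closed hexagonal walk.  Returns (boolean keep mask, labels of the
    kept trials).
    """
    keep = (trials["color_bin"] != 2).to_numpy()
    sub = trials.loc[keep]
    return keep, list(zip(sub["size_bin"].astype(int), sub["color_bin"].astype(int)))


# ---------------------------------------------------------------------------
# volumetric betas
# ---------------------------------------------------------------------------

@dataclass
class BetaVolume:
    """Trial-wise beta maps: x * y * z * trials, plus mask and voxel size."""

    data: np.ndarray
    mask: np.ndarray
    voxel_size: float
    affine: np.ndarray
    planted_roi: np.ndarray | None = None  # (n, 3) ijk of planted voxels

    @property
    def n_trials(self) -> int:
        return self.data.shape[-1]


def generate_beta_volumes(
    trials: pd.DataFrame,
    geometry: PlantedGeometry,
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    voxel_size: float = 3.0,
    roi_center_mm: tuple[float, float, float] | None = None,
    roi_radius_mm: float = 9.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> BetaVolume:
    """Per-trial volumes: planted geometry inside a spherical ROI, noise outside."""
    if voxel_size <= 0:
        raise InvalidParameterError("voxel_size must be positive")
    grid_shape = tuple(int(g) for g in grid_shape)
    extent = (np.array(grid_shape) - 1) * voxel_size
    center = np.array(roi_center_mm if roi_center_mm is not None else extent / 2.0, dtype=float)
    if np.any(center - roi_radius_mm < -1e-9) or np.any(center + roi_radius_mm > extent + 1e-9):
        raise GeometryPlacementError("planted ROI sphere does not fit inside the grid")

    ijk = np.indices(grid_shape).reshape(3, -1).T
    mm = ijk * voxel_size
    inside = np.linalg.norm(mm - center, axis=1) <= roi_radius_mm + 1e-9
    roi_ijk = ijk[inside]
    n_roi = len(roi_ijk)

    ss = np.random.SeedSequence(seed)
    rng_noise, rng_mix = [np.random.default_rng(s) for s in ss.spawn(2)]
    labels = geometry.labels_for(trials)
    missing = {l for l in labels if l not in geometry.coords}
    if missing:
        raise MissingConditionError(f"no planted coordinates for conditions {sorted(missing)}")
    mixing = geometry.mixing
    if mixing is None or np.asarray(mixing).shape[0] != n_roi:
        mixing = random_mixing(n_roi, rng_mix)
    latent = np.array([geometry.coords[l] for l in labels])  # (trials, 2)
    signal = latent @ np.asarray(mixing, dtype=float).T  # (trials, n_roi)

    n_trials = len(trials)
    data = rng_noise.normal(0.0, noise_sd, size=grid_shape + (n_trials,))
    data[roi_ijk[:, 0], roi_ijk[:, 1], roi_ijk[:, 2], :] += signal.T

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    mask = np.ones(grid_shape, dtype=bool)
    return BetaVolume(data=data, mask=mask, voxel_size=voxel_size, affine=affine,
                      planted_roi=roi_ijk)
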
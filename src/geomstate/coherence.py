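"""Seed-to-posterior phase coupling via the weighted phase lag index.

Cross-spectra between a frontal midline seed (Fz by default) and each
posterior channel are estimated per epoch by complex Morlet wavelet
convolution (1-12 Hz, 5 cycles), and combined across epochs into

    wPLI = |E[Im S]| / E[|Im S|]

which discounts zero-lag (volume-conduction-like) coupling because such
coupling leaves Im S symmetric around zero.  Per-pair wPLI maps are averaged
over the posterior targets, baseline-corrected per frequency, and tested
across subjects with a one-tailed sign-flip cluster permutation test in the
time-frequency plane; significant clusters restricted to the theta band
(4-7 Hz) become masks whose mean coupling per subject is correlated with
geometry strength and behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientDataError,
    InvalidFrequencyError,
    InvalidMaskError,
    InvalidParameterError,
    InvalidWindowError,
)
from .simulate import EpochArray

__all__ = [
    "THETA_BAND",
    "DELTA_BAND",
    "CoherenceMap",
    "CoherenceCluster",
    "epoch_cross_spectra",
    "wpli",
    "seed_target_wpli",
    "baseline_correct",
    "coherence_cluster_test",
    "cluster_masked_strength",
    "coherence_geometry_correlation",
]

THETA_BAND = (4.0, 7.0)
DELTA_BAND = (1.0, 3.0)
DEFAULT_FREQS = np.arange(1.0, 13.0)  # 1-12 Hz in 1-Hz steps


@dataclass
class CoherenceMap:
    """Frequency x time wPLI between a seed and a set of target channels."""

    freqs: np.ndarray
    times: np.ndarray  # ms
    wpli: np.ndarray  # (n_freqs, n_times), in [0, 1]
    seed_channel: str = ""
    target_channels: list[str] = field(default_factory=list)


@dataclass
class CoherenceCluster:
    """Significant time-frequency cluster and its theta-band restriction."""

    mask: np.ndarray  # boolean (n_freqs, n_times)
    p_value: float
    freq_range: tuple[float, float]
    time_range: tuple[float, float]
    theta_submask: np.ndarray
    significant: bool


def epoch_cross_spectra(
    epochs: EpochArray,
    seed_channel: str,
    target_channels: list[str],
    freqs: np.ndarray = DEFAULT_FREQS,
    wavelet_cycles: float = 5.0,
    decim: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch complex cross-spectra seed x target via Morlet convolution.

    Returns ``(cross, freqs, times)`` with ``cross`` of shape
    (n_epochs, n_targets, n_freqs, n_times); the cross-spectrum is
    W_seed * conj(W_target), so its phase is the seed-minus-target phase lag.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=float)
    nyquist = epochs.sfreq / 2.0
    if np.any(freqs >= nyquist):
        raise InvalidFrequencyError(f"frequencies must be below Nyquist ({nyquist} Hz)")
    if np.any(freqs <= 0):
        raise InvalidFrequencyError("frequencies must be positive")
    if seed_channel in target_channels:
        raise InvalidParameterError("seed channel cannot be one of the targets")

    picks = [seed_channel] + list(target_channels)
    idx = [epochs.ch_names.index(c) for c in picks]
    data = epochs.data[:, idx, :]
    # cap cycles at freq/2 (standard low-frequency taper) so the slowest
    # wavelets still fit inside the epoch
    n_cycles = np.minimum(float(wavelet_cycles), np.maximum(1.0, freqs / 2.0))
    w = tfr_array_morlet(
        data, sfreq=epochs.sfreq, freqs=freqs, n_cycles=n_cycles,
        output="complex", decim=decim, verbose="error",
    )
    cross = w[:, :1] * np.conj(w[:, 1:])
    times = np.asarray(epochs.times, dtype=float)[::decim][: cross.shape[-1]]
    return cross, freqs, times


def wpli(cross: np.ndarray) -> np.ndarray:
    """Weighted phase lag index across epochs: |E[Im S]| / E[|Im S|].

    ``cross`` is (n_epochs, ..., n_freqs, n_times); the epoch axis collapses.
    Cells where E[|Im S|] = 0 (no imaginary energy at all) are set to 0.
    """
    cross = np.asarray(cross)
    if cross.shape[0] < 2:
        raise InsufficientDataError("wPLI needs at least 2 epochs")
    im = cross.imag
    num = np.abs(im.mean(axis=0))
    den = np.abs(im).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, 0.0)


def seed_target_wpli(
    epochs: EpochArray,
    seed_channel: str = "Fz",
    target_channels: list[str] | None = None,
    freqs: np.ndarray = DEFAULT_FREQS,
    wavelet_cycles: float = 5.0,
    decim: int = 1,
) -> CoherenceMap:
    """wPLI map between the seed and each target, averaged over targets.

    Per the analysis convention, the per-pair wPLI is computed first and the
    average over posterior targets taken afterwards.
    """
    if target_channels is None:
        posterior = epochs.groups.get("posterior")
        if posterior is None:
            raise InvalidParameterError("no posterior group; pass target_channels")
        target_channels = [epochs.ch_names[i] for i in posterior]
    cross, freqs, times = epoch_cross_spectra(
        epochs, seed_channel, target_channels, freqs, wavelet_cycles, decim
    )
    per_pair = wpli(cross)  # (n_targets, n_freqs, n_times)
    return CoherenceMap(freqs, times, per_pair.mean(axis=0), seed_channel,
                        list(target_channels))


def baseline_correct(cmap: CoherenceMap, baseline_window: tuple[float, float]) -> np.ndarray:
    """Subtract the per-frequency baseline mean; values then live in [-1, 1]."""
    lo, hi = baseline_window
    m = (cmap.times >= lo) & (cmap.times < hi)
    if not m.any():
        raise InvalidWindowError(f"baseline window {baseline_window} outside epoch")
    return cmap.wpli - cmap.wpli[:, m].mean(axis=1, keepdims=True)


def coherence_cluster_test(
    maps: list[CoherenceMap],
    baseline_window: tuple[float, float] = (-500.0, 0.0),
    alpha: float = 0.05,
    n_perm: int = 1024,
    seed: int = 0,
) -> tuple[list[CoherenceCluster], np.ndarray]:
    """One-sample, one-tailed sign-flip cluster test on baseline-corrected maps.

    Returns the cluster list (each with its theta-band submask) and the
    (n_subjects, n_freqs, n_times) baseline-corrected stack.
    """
    from mne.stats import permutation_cluster_1samp_test

    if len(maps) < 5:
        raise InsufficientDataError("cluster test needs at least 5 subjects")
    x = np.stack([baseline_correct(m, baseline_window) for m in maps])
    _, clusters, pvals, _ = permutation_cluster_1samp_test(
        x, n_permutations=n_perm, tail=1, out_type="mask", seed=seed, verbose="error",
    )
    freqs, times = maps[0].freqs, maps[0].times
    theta = (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])
    out = []
    for mask, p in zip(clusters, pvals):
        mask = np.asarray(mask, dtype=bool)
        fsel = mask.any(axis=1)
        tsel = mask.any(axis=0)
        out.append(
            CoherenceCluster(
                mask=mask,
                p_value=float(p),
                freq_range=(float(freqs[fsel].min()), float(freqs[fsel].max())),
                time_range=(float(times[tsel].min()), float(times[tsel].max())),
                theta_submask=mask & theta[:, None],
                significant=bool(p <= alpha),
            )
        )
    return out, x


def cluster_masked_strength(map_bc: np.ndarray, mask: np.ndarray) -> float:
    """Mean baseline-corrected coupling over the masked time-frequency cells."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidMaskError("empty cluster mask")
    return float(np.asarray(map_bc, dtype=float)[mask].mean())


def coherence_geometry_correlation(
    strengths,
    circularity_by_epoch: pd.DataFrame,
    alternative: str = "greater",
    q: float = 0.05,
) -> pd.DataFrame:
    """One-tailed Spearman between subject coupling strength and circularity.

    One test per column (task epoch); BH adjustment within the family.  The
    same path serves the delta-band (1-3 Hz) control when the caller computes
    strengths from a delta mask.
    """
    s = np.asarray(strengths, dtype=float)
    if len(s) < 5 or len(circularity_by_epoch) != len(s):
        raise InsufficientDataError("need paired vectors for at least 5 subjects")
    rows = []
    for col in circularity_by_epoch.columns:
        r, p = stats.spearmanr(s, circularity_by_epoch[col], alternative=alternative)
        rows.append({"epoch": col, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] <= q
    return out
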
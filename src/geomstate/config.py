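"""Analysis configuration and the full-scale vs scaled-down presets.

The ``paper_faithful`` preset carries the full-scale inference parameters
(5,000 permutations, 10 resamples, 10,000 bootstraps, 100 label shuffles per
subject); ``scaled_down`` is the continuous-testing scale (500 / 5 / 500 /
20).  A preset fully determines every defaulted numeric
parameter, and each pipeline run writes the resolved configuration beside
its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PRESETS", "AnalysisConfig"]

PRESETS: dict[str, dict] = {
    "paper_faithful": dict(n_perm=5000, n_resamples=10, n_bootstrap=10_000, n_label_shuffles=100),
    "scaled_down": dict(n_perm=500, n_resamples=5, n_bootstrap=500, n_label_shuffles=20),
}


@dataclass
class AnalysisConfig:
    seed: int = 0
    preset: str = "scaled_down"
    # epoch / windowing (ms relative to goal-cue onset)
    epoch_start: float = -500.0
    epoch_end: float = 4300.0
    window_ms: float = 80.0
    sfreq: float = 250.0
    # generator
    n_channels: int = 59
    reps_per_cell: int = 18
    noise_sd: float = 1.0
    signal_gain: float = 1.0
    coupling: float = 0.0
    # inference (None -> filled from preset)
    n_perm: int | None = None
    n_resamples: int | None = None
    n_bootstrap: int | None = None
    n_label_shuffles: int | None = None
    alpha: float = 0.05
    voxel_alpha: float = 0.01
    fdr_q: float = 0.05
    # coherence
    coherence_band: tuple[float, float] = (4.0, 7.0)
    coherence_baseline: tuple[float, float] = (-500.0, 0.0)
    wavelet_cycles: float = 5.0
    # searchlight
    searchlight_radius_mm: float = 9.0
    voxel_size_mm: float = 3.0
    # bookkeeping
    out_dir: str = "geomstate_out"
    fdr_families: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ConfigurationError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )
        for key, val in PRESETS[self.preset].items():
            if getattr(self, key) is None:
                setattr(self, key, val)
        bad = [k for k in ("alpha", "voxel_alpha", "fdr_q") if not 0 < getattr(self, k) < 1]
        if bad:
            raise ConfigurationError(f"levels must lie in (0, 1): {bad}")
        if self.epoch_end <= self.epoch_start or self.window_ms <= 0:
            raise ConfigurationError("invalid epoch bounds or window length")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coherence_band"] = list(self.coherence_band)
        d["coherence_baseline"] = list(self.coherence_baseline)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        for key in ("coherence_band", "coherence_baseline"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)
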
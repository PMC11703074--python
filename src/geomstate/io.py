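"""Readers and writers for the pipeline's on-disk formats.

Trial tables travel as TSV, epochs as HDF5 (datasets ``/data`` and
``/times``, attributes ``sfreq``, ``ch_names`` and JSON-encoded channel
groups), beta volumes as 4D NIfTI (x, y, z, trial) plus a 3D mask whose
affine encodes the voxel size, and results as JSON/TSV.  Round trips are
exact for labels and integers and at float64 precision for data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .simulate import BetaVolume, EpochArray

__all__ = [
    "TRIAL_COLUMNS",
    "write_trials",
    "read_trials",
    "write_epochs",
    "read_epochs",
    "write_beta_volume",
    "read_beta_volume",
    "write_json",
    "read_json",
    "write_timecourse_tsv",
    "sha256_of",
]

# Canonical leading columns of a serialized trial table (extra columns are
# preserved after these).
TRIAL_COLUMNS = [
    "trial_id", "block", "goal_size", "goal_color", "size_bin", "color_bin",
    "response_size_bin", "response_color_bin", "size_error", "color_error",
]


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ConfigurationError(f"trial table missing columns {missing}")
    ordered = TRIAL_COLUMNS + [c for c in trials.columns if c not in TRIAL_COLUMNS]
    trials[ordered].to_csv(path, sep="\t", index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trial file {path} missing columns {missing}")
    for col in ("trial_id", "block", "size_bin", "color_bin",
                "response_size_bin", "response_color_bin"):
        df[col] = df[col].astype(int)
    return df


def write_epochs(epochs: EpochArray, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["ch_names"] = json.dumps(list(epochs.ch_names))
        f.attrs["groups"] = json.dumps({k: np.asarray(v).tolist() for k, v in epochs.groups.items()})
    return path


def read_epochs(path: str | Path) -> EpochArray:
    with h5py.File(path, "r") as f:
        if "data" not in f or "times" not in f:
            raise ConfigurationError(f"{path} is not an epochs file (missing /data or /times)")
        data = f["data"][()]
        times = f["times"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = json.loads(f.attrs["ch_names"])
        groups = {k: np.asarray(v, dtype=int) for k, v in json.loads(f.attrs["groups"]).items()}
    return EpochArray(data=data, times=times, sfreq=sfreq, ch_names=ch_names, groups=groups)


def write_beta_volume(beta: BetaVolume, data_path: str | Path, mask_path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(beta.data.astype(np.float64), beta.affine), str(data_path))
    nib.save(nib.Nifti1Image(beta.mask.astype(np.uint8), beta.affine), str(mask_path))


def read_beta_volume(data_path: str | Path, mask_path: str | Path) -> BetaVolume:
    import nibabel as nib

    img = nib.load(str(data_path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ConfigurationError("beta volume must be 4D (x, y, z, trial)")
    affine = img.affine
    voxel_size = float(np.abs(affine[0, 0]))
    return BetaVolume(
        data=data,
        mask=np.asarray(mask_img.dataobj) > 0,
        voxel_size=voxel_size,
        affine=affine,
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_timecourse_tsv(window_centers, values, path: str | Path,
                         extra: dict | None = None) -> Path:
    df = pd.DataFrame({"time_ms": np.asarray(window_centers), "circularity": np.asarray(values)})
    for k, v in (extra or {}).items():
        df[k] = np.asarray(v)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
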
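"""On-disk formats: per-trial CSVs with a manifest, and HDF5 pattern datasets.

Trial layout: one CSV per trial with a ``time_s`` column plus the 36
channel columns named ``<location>_<acc|gyr>_<v|ml|ap>``, and a
``manifest.csv`` (participant_id, surface, trial_index, file).  The same
layout serves the synthetic generator's output and externally converted
recordings.

Dataset layout: one HDF5 group per combination (``comb_XX``) holding
``patterns`` (N, 6n, 400) and ``labels`` (N integer surface codes), with
seed / augment_factor / comb_num attributes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .core import (
    IMUTrial,
    SurfaceClass,
    WalkPattern,
    WalkPatternDataset,
    all_channels,
    get_combination,
)

__all__ = [
    "write_trials",
    "read_trials",
    "save_dataset",
    "load_dataset",
    "save_report_json",
]

_CHANNEL_COLUMNS = [ch.short_name for ch in all_channels()]


def write_trials(trials: Sequence[IMUTrial], out_dir) -> Path:
    """Write trial CSVs plus manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for trial in trials:
        name = (
            f"p{trial.participant_id:02d}_{trial.surface.value}"
            f"_t{trial.trial_index}.csv"
        )
        t = np.arange(trial.n_samples) / trial.sample_rate
        df = pd.DataFrame(trial.samples.T, columns=_CHANNEL_COLUMNS)
        df.insert(0, "time_s", t)
        df.to_csv(out_dir / name, index=False, float_format="%.6f")
        manifest.append(
            {
                "participant_id": trial.participant_id,
                "surface": trial.surface.value,
                "trial_index": trial.trial_index,
                "file": name,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(manifest).to_csv(manifest_path, index=False)
    return manifest_path


def read_trials(trial_dir) -> list[IMUTrial]:
    """Read a trial directory written by :func:`write_trials`."""
    trial_dir = Path(trial_dir)
    manifest = pd.read_csv(trial_dir / "manifest.csv")
    trials = []
    for row in manifest.itertuples():
        df = pd.read_csv(trial_dir / row.file)
        missing = [c for c in _CHANNEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{row.file} missing channel columns: {missing[:3]}...")
        dt = np.diff(df["time_s"].to_numpy()[:2])
        rate = 1.0 / dt[0] if len(dt) else 100.0
        trials.append(
            IMUTrial(
                participant_id=int(row.participant_id),
                surface=SurfaceClass(row.surface),
                trial_index=int(row.trial_index),
                samples=df[_CHANNEL_COLUMNS].to_numpy().T,
                sample_rate=float(round(rate)),
            )
        )
    return trials


def save_dataset(
    path, dataset: WalkPatternDataset, seed: int | None = None, augment_factor: int = 0
) -> None:
    """Append one combination's patterns to an HDF5 container."""
    X, y = dataset.stack(dtype=np.float32)
    with h5py.File(path, "a") as fh:
        name = f"comb_{dataset.combination.comb_num:02d}"
        if name in fh:
            del fh[name]
        grp = fh.create_group(name)
        grp.create_dataset("patterns", data=X)
        grp.create_dataset("labels", data=y)
        grp.attrs["comb_num"] = dataset.combination.comb_num
        grp.attrs["augment_factor"] = augment_factor
        if seed is not None:
            grp.attrs["seed"] = seed
        aug = np.array([p.augmented for p in dataset.patterns], dtype=bool)
        meta = np.array(
            [
                (p.participant_id, p.trial_index, p.augmentation_index)
                for p in dataset.patterns
            ],
            dtype=np.int64,
        )
        grp.create_dataset("augmented", data=aug)
        grp.create_dataset("source", data=meta)


def load_dataset(path, comb_num: int) -> WalkPatternDataset:
    """Load one combination's patterns back from an HDF5 container."""
    combination = get_combination(comb_num)
    surfaces = list(SurfaceClass)
    with h5py.File(path, "r") as fh:
        grp = fh[f"comb_{comb_num:02d}"]
        X = grp["patterns"][...]
        y = grp["labels"][...]
        aug = grp["augmented"][...]
        meta = grp["source"][...]
    patterns = [
        WalkPattern(
            combination=combination,
            surface=surfaces[int(lab)],
            matrix=X[i].astype(np.float64),
            participant_id=int(meta[i, 0]),
            trial_index=int(meta[i, 1]),
            augmented=bool(aug[i]),
            augmentation_index=int(meta[i, 2]),
        )
        for i, lab in enumerate(y)
    ]
    return WalkPatternDataset(combination=combination, patterns=patterns)


def save_report_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
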
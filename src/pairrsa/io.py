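"""Readers and writers: HDF5 epoch containers with JSON sidecars, CSV
layouts and design tables, forward models, and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet, ForwardModel, TrialInfo

__all__ = [
    "FormatError",
    "write_epochs",
    "read_epochs",
    "read_epochs_fif",
    "write_layout_csv",
    "read_layout_csv",
    "write_forward",
    "read_forward",
    "load_config",
    "RunManifest",
    "sha256_of_file",
]


class FormatError(RuntimeError):
    """Container/sidecar inconsistency, naming the offending field."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_epochs(epochs: EpochSet, path) -> None:
    """HDF5 container (data, times) plus JSON sidecar (sensor ids, trial
    metadata, participant). Round-trips bit-exactly."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
    sidecar = dict(
        participant=epochs.participant,
        sensor_ids=list(epochs.sensor_ids),
        trials=[asdict(t) for t in epochs.trials],
    )
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_epochs(path) -> EpochSet:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar {sidecar_file.name}")
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
    sidecar = json.loads(sidecar_file.read_text())
    trials = [TrialInfo(**t) for t in sidecar["trials"]]
    if len(trials) != data.shape[0]:
        raise FormatError(
            f"trials: sidecar lists {len(trials)} trials, data holds {data.shape[0]}"
        )
    if len(sidecar["sensor_ids"]) != data.shape[1]:
        raise FormatError(
            f"sensor_ids: sidecar lists {len(sidecar['sensor_ids'])} sensors, "
            f"data holds {data.shape[1]}"
        )
    return EpochSet(
        data=data,
        times=times,
        sensor_ids=sidecar["sensor_ids"],
        trials=trials,
        participant=sidecar.get("participant", 0),
    )


def read_epochs_fif(path) -> EpochSet:
    """Import an MNE epochs FIF file (metadata-limited: event codes become
    pair ids; expectancy/category default and should be re-attached from a
    design table)."""
    import mne  # deferred: optional heavy dependency

    ep = mne.read_epochs(path, preload=True, verbose="error")
    data = ep.get_data(copy=True)
    trials = [
        TrialInfo(
            sentence_id=i,
            pair_id=int(code),
            member_index=1,
            expectancy="expected",
            category="noun",
        )
        for i, code in enumerate(ep.events[:, 2])
    ]
    return EpochSet(
        data=data, times=ep.times.copy(), sensor_ids=list(ep.ch_names), trials=trials
    )


def write_layout_csv(positions: np.ndarray, path, sensor_ids=None) -> None:
    positions = np.asarray(positions, dtype=float)
    ids = sensor_ids or [f"MEG{i:03d}" for i in range(len(positions))]
    pd.DataFrame(
        dict(id=ids, x=positions[:, 0], y=positions[:, 1], z=positions[:, 2])
    ).to_csv(path, index=False)


def read_layout_csv(path) -> tuple[np.ndarray, list[str]]:
    t = pd.read_csv(path)
    return t[["x", "y", "z"]].to_numpy(dtype=float), t["id"].astype(str).tolist()


def write_forward(fm: ForwardModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("grid_positions", data=fm.grid_positions)
        f.create_dataset("gain", data=fm.gain)
        f.attrs["grid_spacing"] = fm.grid_spacing
        if fm.sensor_positions is not None:
            f.create_dataset("sensor_positions", data=fm.sensor_positions)


def read_forward(path) -> ForwardModel:
    with h5py.File(path, "r") as f:
        sp = f["sensor_positions"][()] if "sensor_positions" in f else None
        return ForwardModel(
            grid_positions=f["grid_positions"][()],
            gain=f["gain"][()],
            grid_spacing=float(f.attrs["grid_spacing"]),
            sensor_positions=sp,
        )


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise FormatError("config file must hold a mapping")
    return cfg


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class RunManifest:
    """Traceability record: config snapshot + hash, seeds, per-stage
    outputs with checksums and timestamps."""

    def __init__(self, config: dict, seed: int) -> None:
        self.config = config
        self.seed = seed
        self.stages: list[dict] = []

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def add_stage(self, name: str, outputs: dict[str, str] | None = None,
                  info: dict | None = None) -> None:
        checksums = {}
        for label, p in (outputs or {}).items():
            checksums[label] = dict(path=str(p), sha256=sha256_of_file(p))
        self.stages.append(
            dict(name=name, timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                 outputs=checksums, info=info or {})
        )

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                dict(config=self.config, config_hash=self.config_hash,
                     seed=self.seed, stages=self.stages),
                indent=1, default=str,
            )
        )
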
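"""Trajectory containers, tabular exports and run manifests.

Ensembles are stored in one HDF5 file with a group per trajectory (cargo
path, per-motor flags and positions, config snapshot and seed embedded as
metadata) plus a lossless per-trajectory CSV export.  Every analysis output
written by the experiment driver is traceable to a JSON run manifest with
checksums of the files it produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import Trajectory
from .params import ModelConfig, config_from_dict, config_to_dict


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Flat table: t, x_c, per-motor attached flag and position, counts."""
    data = {"t": traj.t, "x_c": traj.x}
    if traj.has_motor_state:
        for i in range(traj.motor_x.shape[1]):
            data[f"attached_{i}"] = traj.attached[:, i].astype(int)
            data[f"x_{i}"] = traj.motor_x[:, i]
        data["n_f"] = traj.n_f
        data["n_b"] = traj.n_b
        data["q_f"] = traj.q_f
        data["q_b"] = traj.q_b
    return pd.DataFrame(data)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def read_timeseries_csv(path, t_col: str = "t", x_col: str = "x_c") -> Trajectory:
    """Load a plain (time, position) table as an analysis-ready trajectory.

    Falls back to the first two columns when the named ones are absent;
    motor-state-resolved analyses are unavailable on such input.
    """
    df = pd.read_csv(path)
    if t_col in df.columns and x_col in df.columns:
        t, x = df[t_col], df[x_col]
    else:
        t, x = df.iloc[:, 0], df.iloc[:, 1]
    return Trajectory.from_timeseries(np.asarray(t, float), np.asarray(x, float))


def _write_traj_group(g: h5py.Group, traj: Trajectory) -> None:
    g.create_dataset("t", data=traj.t)
    g.create_dataset("x_c", data=traj.x)
    if traj.has_motor_state:
        g.create_dataset("attached", data=traj.attached.astype(np.uint8))
        g.create_dataset("motor_x", data=traj.motor_x)
        g.create_dataset("polarity", data=traj.polarity)
    g.attrs["termination"] = traj.termination
    if traj.seed is not None:
        g.attrs["seed"] = int(traj.seed)
    if traj.config is not None:
        g.attrs["config"] = yaml.safe_dump(config_to_dict(traj.config))


def _read_traj_group(g: h5py.Group) -> Trajectory:
    cfg = None
    if "config" in g.attrs:
        cfg = config_from_dict(yaml.safe_load(g.attrs["config"]))
    att = g["attached"][...].astype(bool) if "attached" in g else None
    return Trajectory(
        t=g["t"][...], x=g["x_c"][...],
        attached=att,
        motor_x=g["motor_x"][...] if "motor_x" in g else None,
        polarity=g["polarity"][...] if "polarity" in g else None,
        config=cfg,
        seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
        termination=str(g.attrs.get("termination", "external")),
    )


def save_ensemble(trajs: List[Trajectory], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_traj"] = len(trajs)
        f.attrs["format_version"] = 1
        for i, tr in enumerate(trajs):
            _write_traj_group(f.create_group(f"traj_{i:05d}"), tr)


def load_ensemble(path) -> List[Trajectory]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            out.append(_read_traj_group(f[name]))
    return out


# ---------------------------------------------------------------------------
# run manifests


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageRecord:
    name: str
    inputs: List[str]
    outputs: List[str]
    checksums: dict
    timestamp: str
    failed: bool = False


@dataclass
class RunManifest:
    """Provenance record of one experiment run."""

    config: dict
    seeds: List[int]
    version: str = __version__
    stages: List[StageRecord] = field(default_factory=list)

    def add_stage(self, name: str, inputs: List[str], outputs: List[str],
                  failed: bool = False) -> None:
        checksums = {str(p): file_checksum(p)
                     for p in outputs if Path(p).is_file()}
        self.stages.append(StageRecord(
            name=name, inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs], checksums=checksums,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"), failed=failed))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        stages = [StageRecord(**s) for s in d.pop("stages", [])]
        return cls(stages=stages, **d)
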
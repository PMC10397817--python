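"""Artifact input/output: HDF5 field snapshots, CSV metrics tables and
YAML config round-tripping.

Every run directory receives:

- ``config.yaml``  — the exact resolved configuration (lossless round-trip)
- ``metrics.csv``  — one row per accepted step (fixed column names)
- ``fields.h5``    — mesh coordinates plus all recorded field snapshots
"""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd
import yaml

from .formation import FormationConfig
from .params import InteractionParams, LocusWell
from .stepping import StepControls
from .trajectory import METRIC_COLUMNS, Trajectory
from .transcription import TranscriptionConfig


# ---------------------------------------------------------------------------
# config <-> dict
# ---------------------------------------------------------------------------

def _params_to_dict(p: InteractionParams) -> dict:
    return {"chiP": p.chiP, "chiR": p.chiR, "chiPR": p.chiPR,
            "nP": p.nP, "nR": p.nR, "nM": p.nM, "kappa": p.kappa}


def _controls_to_dict(c: StepControls) -> dict:
    return {"dt0": c.dt0, "dt_max": c.dt_max, "grow_every": c.grow_every,
            "delta_max": c.delta_max, "steady_tol": c.steady_tol,
            "n_steps": c.n_steps, "t_max": c.t_max,
            "snapshot_stride": c.snapshot_stride}


def config_to_dict(config) -> dict:
    """Serialize a formation or transcription config to plain types."""
    if not isinstance(config, (FormationConfig, TranscriptionConfig)):
        raise TypeError(f"unsupported config type {type(config).__name__}")
    common = {
        "params": _params_to_dict(config.params),
        "controls": _controls_to_dict(config.controls),
        "radius": config.radius, "spacing": config.spacing,
        "phiPavg": config.phiPavg, "DP": config.DP,
        "bl_well": config.bl_well.to_dict(),
    }
    if isinstance(config, FormationConfig):
        return {"kind": "formation", **common,
                "rl_well": config.rl_well.to_dict(),
                "DR": config.DR, "phiRavg": config.phiRavg}
    if isinstance(config, TranscriptionConfig):
        return {"kind": "transcription", **common,
                "rl_center": list(config.rl_center),
                "rl_sigma": config.rl_sigma,
                "DR": config.DR, "DM": config.DM,
                "kM": config.kM, "kR": config.kR,
                "kdM": config.kdM, "kdR": config.kdR}
    raise TypeError(f"unsupported config type {type(config).__name__}")


def config_from_dict(d: dict):
    """Inverse of :func:`config_to_dict`."""
    d = dict(d)
    kind = d.pop("kind")
    if kind not in ("formation", "transcription"):
        raise ValueError(f"unsupported config kind {kind!r}")
    params = InteractionParams(**d.pop("params"))
    controls = StepControls(**d.pop("controls"))
    d["bl_well"] = LocusWell.from_dict(d["bl_well"])
    if kind == "formation":
        d["rl_well"] = LocusWell.from_dict(d["rl_well"])
        return FormationConfig(params=params, controls=controls, **d)
    if kind == "transcription":
        d["rl_center"] = tuple(d["rl_center"])
        return TranscriptionConfig(params=params, controls=controls, **d)
    raise ValueError(f"unsupported config kind {kind!r}")


def save_config(config, path) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=True))


def load_config(path):
    return config_from_dict(
        yaml.safe_load(pathlib.Path(path).read_text()))


# ---------------------------------------------------------------------------
# trajectory artifacts
# ---------------------------------------------------------------------------

def save_metrics(trajectory: Trajectory, path) -> None:
    trajectory.metrics.to_csv(path, index=False,
                              columns=METRIC_COLUMNS)


def load_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_fields(trajectory: Trajectory, path) -> None:
    """Write mesh coordinates and every snapshot to HDF5."""
    with h5py.File(path, "w") as f:
        mesh = trajectory.mesh
        g = f.create_group("mesh")
        g.create_dataset("x", data=mesh.x)
        g.create_dataset("y", data=mesh.y)
        g.attrs["radius"] = mesh.radius
        g.attrs["spacing"] = mesh.spacing
        snaps = f.create_group("snapshots")
        snaps.attrs["times"] = np.array(
            [t for t, _ in trajectory.snapshots])
        for i, (t, fields) in enumerate(trajectory.snapshots):
            grp = snaps.create_group(f"{i:05d}")
            grp.attrs["t"] = t
            for name, arr in fields.items():
                grp.create_dataset(name, data=arr)
        f.attrs["phi_light"] = trajectory.phi_light
        f.attrs["termination"] = trajectory.termination


def load_fields(path) -> list[tuple[float, dict]]:
    """Read back the snapshot list written by :func:`save_fields`."""
    out = []
    with h5py.File(path, "r") as f:
        snaps = f["snapshots"]
        for key in sorted(snaps.keys()):
            grp = snaps[key]
            fields = {name: np.asarray(grp[name]) for name in grp}
            out.append((float(grp.attrs["t"]), fields))
    return out


def save_run(trajectory: Trajectory, outdir) -> pathlib.Path:
    """Write the standard artifact set for one run; returns the directory."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if trajectory.config is not None:
        save_config(trajectory.config, outdir / "config.yaml")
    save_metrics(trajectory, outdir / "metrics.csv")
    save_fields(trajectory, outdir / "fields.h5")
    return outdir
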
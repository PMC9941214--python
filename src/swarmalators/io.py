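"""Configuration files, trajectory serialization, and provenance.

Configs are flat YAML with three nested sections mirroring the run
contract::

    params:      # ModelParams fields
      J: 1.0
      K: 1.0
    frequencies: # FrequencySpec fields
      kind: F2
    schedule:    # RunSchedule fields
      dt: 0.1
      T: 1000

Unknown keys and out-of-range values are rejected with the offending key
path in the message; an empty config yields the reference defaults
(A = B = 1, dt = 0.1, T = 1000, N = 500, Omega = 3).

Trajectories round-trip through either a plain CSV (one row per agent per
frame, 17-significant-digit text) or a compressed NumPy container (``.npz``,
bit-exact, with the full configuration embedded as YAML).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .integrator import RunSchedule, Trajectory
from .model import SwarmState
from .params import FrequencySpec, ModelParams

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_curve",
]

_CSV_COLUMNS = ["t", "id", "x", "y", "theta", "theta_unwrapped", "phi_unwrapped", "omega", "c"]


@dataclass(frozen=True)
class RunConfig:
    """A full run configuration (model + frequencies + numerical protocol)."""

    params: ModelParams = ModelParams()
    frequencies: FrequencySpec = FrequencySpec()
    schedule: RunSchedule = RunSchedule()


def _build_section(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            raise ValueError(f"unknown config key '{path}.{key}'")
    if cls is ModelParams and "sigma" in data and data["sigma"] in ("inf", ".inf", None):
        data = dict(data, sigma=math.inf)
    try:
        obj = cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value under '{path}': {exc}") from exc
    if cls is ModelParams:
        if not -1.0 <= obj.J <= 1.0:
            raise ValueError(f"invalid value under '{path}.J': J must lie in [-1, 1], got {obj.J}")
        if not -1.0 <= obj.K <= 2.0:
            raise ValueError(f"invalid value under '{path}.K': K must lie in [-1, 2], got {obj.K}")
    return obj


def config_from_dict(data: dict) -> RunConfig:
    if data is None:
        data = {}
    known = {"params", "frequencies", "schedule"}
    for key in data:
        if key not in known:
            raise ValueError(f"unknown config section '{key}' (expected one of {sorted(known)})")
    return RunConfig(
        params=_build_section(ModelParams, dict(data.get("params") or {}), "params"),
        frequencies=_build_section(FrequencySpec, dict(data.get("frequencies") or {}), "frequencies"),
        schedule=_build_section(RunSchedule, dict(data.get("schedule") or {}), "schedule"),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    out = {
        "params": dataclasses.asdict(cfg.params),
        "frequencies": dataclasses.asdict(cfg.frequencies),
        "schedule": dataclasses.asdict(cfg.schedule),
    }
    if math.isinf(out["params"]["sigma"]):
        out["params"]["sigma"] = ".inf"
    if out["frequencies"]["values"] is not None:
        out["frequencies"]["values"] = list(out["frequencies"]["values"])
    return out


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def _config_of(traj: Trajectory) -> RunConfig | None:
    if traj.params is None or traj.spec is None or traj.schedule is None:
        return None
    return RunConfig(params=traj.params, frequencies=traj.spec, schedule=traj.schedule)


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "csv") -> None:
    """Serialize a trajectory as CSV (text) or npz (bit-exact arrays)."""
    path = Path(path)
    if format == "csv":
        rows = []
        ids = np.arange(traj.n_agents)
        for frame in traj.frames:
            rows.append(
                pd.DataFrame(
                    {
                        "t": frame.t,
                        "id": ids,
                        "x": frame.pos[:, 0],
                        "y": frame.pos[:, 1],
                        "theta": frame.phase,
                        "theta_unwrapped": frame.phase_unwrapped,
                        "phi_unwrapped": frame.angle_unwrapped,
                        "omega": frame.omega,
                        "c": frame.c,
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    elif format == "npz":
        cfg = _config_of(traj)
        np.savez_compressed(
            path,
            times=traj.times,
            pos=traj.positions,
            phase=traj.phases,
            phase_unwrapped=traj.phases_unwrapped,
            angle_unwrapped=traj.angles_unwrapped,
            omega=traj.frames[0].omega,
            c=traj.frames[0].c,
            R=traj.frames[0].R,
            config=np.array(yaml.safe_dump(config_to_dict(cfg)) if cfg else ""),
        )
    else:
        raise ValueError(f"unknown trajectory format {format!r} (expected 'csv' or 'npz')")


def _frames_from_arrays(times, pos, phase, phase_u, angle_u, omega, c, radii) -> list[SwarmState]:
    return [
        SwarmState(
            pos=pos[k],
            phase=phase[k],
            omega=omega,
            c=c,
            R=radii,
            t=float(times[k]),
            phase_unwrapped=phase_u[k],
            angle_unwrapped=angle_u[k],
        )
        for k in range(len(times))
    ]


def read_trajectory(path: str | Path) -> Trajectory:
    """Load a trajectory written by :func:`write_trajectory` (format inferred
    from the suffix).  CSV rows may arrive in any order; frames are keyed by
    (t, id)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            cfg_text = str(data["config"])
            cfg = config_from_dict(yaml.safe_load(cfg_text)) if cfg_text.strip() else None
            radii = data["R"]
            frames = _frames_from_arrays(
                data["times"],
                data["pos"],
                data["phase"],
                data["phase_unwrapped"],
                data["angle_unwrapped"],
                data["omega"],
                data["c"],
                radii,
            )
        return Trajectory(
            frames=frames,
            params=cfg.params if cfg else None,
            spec=cfg.frequencies if cfg else None,
            schedule=cfg.schedule if cfg else None,
        )
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV is missing column(s): {', '.join(missing)}")
    df = df.sort_values(["t", "id"], kind="mergesort")
    first = df[df.t == df.t.iloc[0]]
    omega = first.omega.to_numpy()
    c = first.c.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        radii = np.where(omega != 0, c / omega, 0.0)
    times = np.array(sorted(df.t.unique()))
    n = len(first)
    grouped = {col: df[col].to_numpy().reshape(len(times), n) for col in df.columns}
    pos = np.stack([grouped["x"], grouped["y"]], axis=-1)
    frames = _frames_from_arrays(
        times, pos, grouped["theta"], grouped["theta_unwrapped"], grouped["phi_unwrapped"], omega, c, radii
    )
    return Trajectory(frames=frames)


def write_curve(curve, path: str | Path) -> None:
    """Columnar CSV export for a BinnedCurve."""
    curve.to_frame().to_csv(path, index=False, float_format="%.17g")
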
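"""Delimited-text readers/writers and the run manifest.

Trajectory files are CSV with a header and columns ``traj_id,x,y[,t]``, one
vertex per row, vertices grouped and ordered per trajectory.  Specimen
tables are CSV with one row per beetle.  All floating output is written at 6
significant digits so result files diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, TimeOrderError
from .trajectory import TrajectoryPath

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_specimens",
    "write_table",
    "write_manifest",
]

TRAJ_REQUIRED = ("traj_id", "x", "y")
FLOAT_FORMAT = "%.6g"


def read_trajectories(path, frame_interval: float = 1.0) -> list[TrajectoryPath]:
    """Read a trajectory CSV into a list of :class:`TrajectoryPath`.

    Vertices are grouped by ``traj_id`` preserving file order.  Missing
    timestamps get ``t_i = i * frame_interval``.  Malformed rows raise with
    their line numbers; unordered timestamps raise naming the trajectory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    for col in ("x", "y") + (("t",) if "t" in df.columns else ()):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +2: header and 1-based
            raise SchemaError(f"{path.name}: non-numeric {col!r} at line(s) {lines}")
        df[col] = pd.to_numeric(df[col])
    if df[["x", "y"]].isna().any().any():
        lines = (df.index[df[["x", "y"]].isna().any(axis=1)] + 2).tolist()
        raise SchemaError(f"{path.name}: missing coordinate at line(s) {lines}")

    paths = []
    for tid, grp in df.groupby("traj_id", sort=False):
        t = grp["t"].to_numpy(float) if "t" in grp.columns else None
        if t is not None and np.any(np.diff(t) <= 0):
            raise TimeOrderError(f"trajectory {tid!r}: timestamps not strictly increasing")
        paths.append(TrajectoryPath.from_xy(
            str(tid), grp["x"].to_numpy(float), grp["y"].to_numpy(float),
            t=t, frame_interval=frame_interval,
        ))
    return paths


def write_trajectories(paths, out) -> Path:
    """Write trajectories at full precision (data files must round-trip
    exactly; only derived report tables are rounded to 6 significant digits)."""
    out = Path(out)
    frames = [
        pd.DataFrame({"traj_id": p.id, "x": p.vertices[:, 0],
                      "y": p.vertices[:, 1], "t": p.times})
        for p in paths
    ]
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    return out


def read_specimens(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("id", "location"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def write_table(df: pd.DataFrame, out) -> Path:
    out = Path(out)
    df.to_csv(out, index=False, float_format=FLOAT_FORMAT)
    return out


def write_manifest(out_dir, command: str, seed: int, config: dict,
                   inputs=(), outputs=()) -> Path:
    """Write the run manifest: command, config hash, seed, paths, version.

    Exactly one manifest per output directory; reruns with identical
    manifest inputs reproduce identical result files.
    """
    from . import __version__

    out_dir = Path(out_dir)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
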
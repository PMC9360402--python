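"""Reading and writing the package's delimited-text formats.

* trajectory CSV: ``t,x,y,heading,speed`` plus a JSON sidecar holding the
  circuit parameters and seed;
* track tables: ``fly,trial,condition,t,x,y,orientation`` with an optional
  JSON arena sidecar (``{"x": [lo, hi], "y": [lo, hi]}``);
* response tables: ``fly,trial,direction,phase,response``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .circuit import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_tracks",
           "read_tracks", "write_responses", "read_responses",
           "read_arena", "write_arena"]

TRACK_COLUMNS = ["fly", "trial", "condition", "t", "x", "y", "orientation"]
RESPONSE_COLUMNS = ["fly", "trial", "direction", "phase", "response"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def write_trajectory(traj: Trajectory, path: str | Path,
                     sidecar: dict | None = None) -> None:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    meta = dict(traj.meta)
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["t", "x", "y", "heading", "speed"], "trajectory file")
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return Trajectory(t=df["t"].to_numpy(), x=df["x"].to_numpy(),
                      y=df["y"].to_numpy(), heading=df["heading"].to_numpy(),
                      speed=df["speed"].to_numpy(), meta=meta)


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    _require(tracks, TRACK_COLUMNS, "track table")
    tracks[TRACK_COLUMNS].to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRACK_COLUMNS, "track table")
    return df


def write_arena(arena: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: list(v) for k, v in arena.items()}))


def read_arena(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    return {k: tuple(v) for k, v in d.items()}


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    _require(responses, RESPONSE_COLUMNS, "response table")
    responses[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, RESPONSE_COLUMNS, "response table")
    return df
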
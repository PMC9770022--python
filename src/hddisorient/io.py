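"""Session directory layout: plain-text files per recorded session.

    session-dir/
      tracking.csv        t, red_x, red_y, green_x, green_y
      spikes_<cellid>.csv t
      session.yaml        metadata (protocol, phase times, truth block)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import SpikeTrain, SyntheticSession
from .tracking import TrackingSeries

__all__ = ["write_session", "read_session"]


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_session(session: SyntheticSession, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tr = session.tracking
    pd.DataFrame(
        {
            "t": tr.t,
            "red_x": tr.red_xy[:, 0],
            "red_y": tr.red_xy[:, 1],
            "green_x": tr.green_xy[:, 0],
            "green_y": tr.green_xy[:, 1],
        }
    ).to_csv(path / "tracking.csv", index=False)
    for st in session.spikes:
        pd.DataFrame({"t": st.t}).to_csv(path / f"spikes_{st.cell_id}.csv", index=False)
    meta = {
        "protocol": _plain(tr.meta.get("protocol", {})),
        "phase_times": _plain(tr.meta.get("phase_times")),
        "truth": {
            "cells": [_plain(vars(c)) for c in session.cell_specs],
        },
    }
    with open(path / "session.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_session(path):
    """Read a session directory back as (tracking, {cell_id: SpikeTrain},
    metadata dict)."""
    path = Path(path)
    df = pd.read_csv(path / "tracking.csv")
    with open(path / "session.yaml") as fh:
        meta = yaml.safe_load(fh)
    tracking = TrackingSeries(
        df["t"].to_numpy(),
        df[["red_x", "red_y"]].to_numpy(),
        df[["green_x", "green_y"]].to_numpy(),
        meta={k: v for k, v in meta.items() if k != "truth"},
    )
    t0, t1 = float(df["t"].iloc[0]), float(meta["phase_times"][-1])
    spikes = {}
    for f in sorted(path.glob("spikes_*.csv")):
        cell_id = f.stem.removeprefix("spikes_")
        t = pd.read_csv(f)["t"].to_numpy()
        spikes[cell_id] = SpikeTrain(t, t0, t1, cell_id)
    return tracking, spikes, meta
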
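"""Plain-text serialization of sessions, tables and ground truth.

Canonical on-disk forms are columnar text tables (tab-separated, one header
line) plus JSON sidecars; an HDF5 container writer is available when h5py is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .synth import GroundTruth
from .types import PositionTrace, RippleEvent, UnitSpikeTrain

__all__ = [
    "write_spikes", "read_spikes", "write_position", "read_position",
    "write_lfp", "read_lfp", "write_ground_truth", "read_ground_truth",
    "ripple_events_frame", "write_session_h5",
]


def write_spikes(path, units: Sequence[UnitSpikeTrain]) -> None:
    rows = [(u.unit_id, t, u.hemisphere) for u in units for t in u.spike_times]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s", "hemisphere"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_spikes(path) -> List[UnitSpikeTrain]:
    df = pd.read_csv(path, sep="\t")
    units = []
    for uid, grp in df.groupby("unit_id", sort=True):
        units.append(UnitSpikeTrain(unit_id=int(uid),
                                    hemisphere=str(grp["hemisphere"].iloc[0]),
                                    spike_times=np.unique(grp["time_s"].to_numpy())))
    return units


def write_position(path, position: PositionTrace) -> None:
    pd.DataFrame({"time_s": position.times, "x_cm": position.x}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_position(path, track_length: float = 150.0) -> PositionTrace:
    from .placefields import position_trace
    df = pd.read_csv(path, sep="\t")
    return position_trace(df["time_s"].to_numpy(), df["x_cm"].to_numpy(),
                          track_length=track_length)


def write_lfp(path, times: np.ndarray, mv: np.ndarray) -> None:
    pd.DataFrame({"time_s": times, "mV": mv}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_lfp(path):
    df = pd.read_csv(path, sep="\t")
    return df["time_s"].to_numpy(), df["mV"].to_numpy()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = dict(
        field_centers=_jsonable(truth.field_centers),
        field_width=truth.field_width,
        peak_rate=truth.peak_rate,
        assembly_members=[list(m) for m in truth.assembly_members],
        ripple_intervals=_jsonable(truth.ripple_intervals),
        ripple_midpoints=_jsonable(truth.ripple_midpoints),
        replay_events=_jsonable(truth.replay_events),
    )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        field_centers=None if d["field_centers"] is None else np.asarray(d["field_centers"]),
        field_width=d["field_width"], peak_rate=d["peak_rate"],
        assembly_members=[tuple(m) for m in d["assembly_members"]],
        ripple_intervals={k: np.asarray(v) for k, v in d["ripple_intervals"].items()},
        ripple_midpoints={k: np.asarray(v) for k, v in d["ripple_midpoints"].items()},
        replay_events=d["replay_events"])


def ripple_events_frame(events: Sequence[RippleEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(event_id=e.event_id, hemisphere=e.hemisphere, t_start=e.t_start,
             t_stop=e.t_stop, t_peak=e.t_peak, midpoint=e.midpoint,
             amplitude_mv=e.amplitude_mv, duration_ms=e.duration_ms,
             peak_freq_hz=e.peak_freq_hz)
        for e in events])


def write_session_h5(path, position: PositionTrace, units: Sequence[UnitSpikeTrain],
                     lfp: dict | None = None) -> None:
    """Optional single-file HDF5 container (requires h5py)."""
    import h5py
    with h5py.File(path, "w") as f:
        g = f.create_group("position")
        g.create_dataset("time_s", data=position.times)
        g.create_dataset("x_cm", data=position.x)
        gs = f.create_group("spikes")
        for u in units:
            d = gs.create_dataset(f"unit_{u.unit_id:04d}", data=u.spike_times)
            d.attrs["hemisphere"] = u.hemisphere
        if lfp:
            gl = f.create_group("lfp")
            for h, (t, v) in lfp.items():
                gh = gl.create_group(h)
                gh.create_dataset("time_s", data=t)
                gh.create_dataset("mV", data=v)
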
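"""File formats: trajectory tables, event logs, audio, configs, manifests.

The trajectory CSV dialect is fixed: comma-separated, UTF-8, '.' decimal,
header ``frame,time_s,fly_id,x_mm,y_mm,valid``.  An HDF5 mirror of the same
content is available for large recordings.  Every run directory carries a
provenance manifest with the configuration echo, a configuration hash, the
seed and package versions, so re-running with the same config reproduces
simulate/score outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .events import ChainEvent, ChaseEvent
from .trajectories import TrajectorySet

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_events",
    "read_events",
    "write_wav",
    "read_wav",
    "write_manifest",
    "config_hash",
    "load_config",
]

TRAJECTORY_COLUMNS = ["frame", "time_s", "fly_id", "x_mm", "y_mm", "valid"]


def write_trajectories(path, traj: TrajectorySet) -> None:
    """Write a TrajectorySet to CSV (or HDF5 when the suffix is .h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_h5(path, traj)
        return
    df = traj.to_dataframe()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# frame_rate={traj.frame_rate!r} roi_id={traj.roi_id}\n")
        df.to_csv(fh, index=False)


def read_trajectories(path, frame_rate: float | None = None) -> TrajectorySet:
    """Read a TrajectorySet written by :func:`write_trajectories`.

    A malformed header raises :class:`ParseError` naming the missing column.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_h5(path)
    roi_id = 0
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(
                kv.split("=", 1) for kv in first.lstrip("#").split() if "=" in kv
            )
            frame_rate = float(meta.get("frame_rate", frame_rate or 0)) or frame_rate
            roi_id = int(meta.get("roi_id", 0))
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    for col in ("frame", "fly_id", "x_mm", "y_mm"):
        if col not in df.columns:
            raise ParseError(f"trajectory file {path} is missing column {col!r}")
    if frame_rate is None:
        if "time_s" in df.columns and df["frame"].max() > 0:
            sub = df[df["frame"] > 0]
            frame_rate = float((sub["frame"] / sub["time_s"]).iloc[0])
        else:
            raise ParseError("frame rate not recoverable; pass frame_rate explicitly")
    return TrajectorySet.from_dataframe(df, frame_rate=frame_rate, roi_id=roi_id)


def _write_h5(path: Path, traj: TrajectorySet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("valid", data=traj.valid)
        f.create_dataset("fly_ids", data=traj.fly_ids)
        f.attrs["frame_rate"] = traj.frame_rate
        f.attrs["roi_id"] = traj.roi_id


def _read_h5(path: Path) -> TrajectorySet:
    import h5py

    with h5py.File(path, "r") as f:
        return TrajectorySet(
            positions=f["positions"][...],
            valid=f["valid"][...],
            fly_ids=f["fly_ids"][...],
            frame_rate=float(f.attrs["frame_rate"]),
            roi_id=int(f.attrs["roi_id"]),
        )


# ----------------------------------------------------------------------
# events
# ----------------------------------------------------------------------

def write_events(path, events, frame_rate: float) -> None:
    """Write chase/chain events as CSV (type, members, start_s, end_s) or JSON."""
    rows = []
    for ev in events:
        if isinstance(ev, ChaseEvent):
            rows.append(
                {
                    "event_type": "chase",
                    "members": f"{ev.chaser};{ev.target}",
                    "start_s": ev.start / frame_rate,
                    "end_s": ev.end / frame_rate,
                    "start_frame": ev.start,
                    "end_frame": ev.end,
                }
            )
        elif isinstance(ev, ChainEvent):
            rows.append(
                {
                    "event_type": "chain",
                    "members": ";".join(str(m) for m in ev.members),
                    "start_s": ev.start / frame_rate,
                    "end_s": ev.end / frame_rate,
                    "start_frame": ev.start,
                    "end_frame": ev.end,
                }
            )
        else:
            raise TypeError(f"unknown event type {type(ev)!r}")
    path = Path(path)
    df = pd.DataFrame(
        rows,
        columns=["event_type", "members", "start_s", "end_s", "start_frame", "end_frame"],
    )
    if path.suffix.lower() == ".json":
        path.write_text(df.to_json(orient="records", indent=2), encoding="utf-8")
    else:
        df.to_csv(path, index=False)


def read_events(path, frame_rate: float) -> list[ChaseEvent | ChainEvent]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    out: list[ChaseEvent | ChainEvent] = []
    for _, r in df.iterrows():
        members = [int(m) for m in str(r["members"]).split(";")]
        start = int(r.get("start_frame", round(r["start_s"] * frame_rate)))
        end = int(r.get("end_frame", round(r["end_s"] * frame_rate)))
        if r["event_type"] == "chase":
            out.append(ChaseEvent(chaser=members[0], target=members[1], start=start, end=end))
        else:
            out.append(ChainEvent(members=tuple(members), start=start, end=end))
    return out


# ----------------------------------------------------------------------
# audio
# ----------------------------------------------------------------------

def write_wav(path, wave: np.ndarray, sample_rate: float) -> None:
    from scipy.io import wavfile

    wavfile.write(path, int(sample_rate), wave.astype(np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.dtype.kind == "i":  # pragma: no cover - float32 written by this package
        data = data / np.iinfo(data.dtype).max
    if data.ndim > 1:
        data = data.mean(axis=1)
    return data, float(fs)


# ----------------------------------------------------------------------
# configuration and provenance
# ----------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return getattr(obj, "__name__", repr(obj))
    return obj


def config_hash(config: Any) -> str:
    """SHA-256 of the canonical JSON form of a configuration object."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path, config: Any, seed: int | None = None, extra: dict | None = None) -> None:
    """Write the provenance manifest: config echo + hash, seed, versions.

    Timestamps are deliberately excluded so identical runs produce
    byte-identical manifests.
    """
    import flycourt

    payload = {
        "package": "flycourt",
        "version": flycourt.__version__,
        "numpy": np.__version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": _jsonable(config),
    }
    if extra:
        payload.update(_jsonable(extra))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError("configuration file must contain a mapping")
    return cfg
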
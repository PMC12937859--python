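"""Readers and writers for recordings, events, labels and decision traces.

Recordings travel either as an HDF5 container (dataset ``/signal`` of shape
channels x samples, attributes ``fs`` and ``channel_ids``) or as a flat
binary file (int16 or float32, channel-major) with a JSON sidecar
``{fs, n_channels, dtype, scale_uV}``. Events, labels and traces are plain
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import LfpRecording
from .labeling import TrialEvents
from .cascade import DecisionTrace

__all__ = [
    "write_recording_h5", "read_recording_h5",
    "write_recording_flat", "read_recording_flat",
    "write_events_csv", "read_events_csv",
    "write_labels_csv", "read_labels_csv",
    "write_gate_trace_csv", "write_decision_trace_csv", "read_decision_trace_csv",
]


def write_recording_h5(rec: LfpRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=rec.samples)
        d.attrs["fs"] = rec.fs
        d.attrs["channel_ids"] = [c.encode() for c in rec.channel_ids]


def read_recording_h5(path: str | Path) -> LfpRecording:
    with h5py.File(path, "r") as f:
        d = f["signal"]
        ids = [c.decode() if isinstance(c, bytes) else str(c)
               for c in d.attrs["channel_ids"]]
        return LfpRecording(samples=d[...], fs=float(d.attrs["fs"]), channel_ids=ids)


def write_recording_flat(rec: LfpRecording, path: str | Path,
                         dtype: str = "float32", scale_uV: float = 1.0) -> None:
    """Channel-major flat binary + JSON sidecar. With int16, samples are
    stored as round(x / scale_uV)."""
    path = Path(path)
    if dtype == "int16":
        data = np.rint(rec.samples / scale_uV).astype(np.int16)
    elif dtype == "float32":
        data = (rec.samples / scale_uV).astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    data.tofile(path)
    sidecar = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "dtype": dtype,
        "scale_uV": scale_uV,
        "channel_ids": rec.channel_ids,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_recording_flat(path: str | Path) -> LfpRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = np.fromfile(path, dtype=sidecar["dtype"])
    nch = int(sidecar["n_channels"])
    samples = raw.reshape(nch, -1).astype(np.float64) * float(sidecar["scale_uV"])
    return LfpRecording(samples=samples, fs=float(sidecar["fs"]),
                        channel_ids=list(sidecar.get("channel_ids") or []))


def write_events_csv(events: TrialEvents, path: str | Path) -> None:
    df = pd.DataFrame({
        "trial_id": np.arange(events.n_trials),
        "t_release_s": events.t_release,
        "t_trial_end_s": events.t_trial_end,
    })
    header = f"# t_pre_s={events.t_pre}\n"
    Path(path).write_text(header + df.to_csv(index=False))


def read_events_csv(path: str | Path) -> TrialEvents:
    text = Path(path).read_text().splitlines()
    t_pre = None
    if text and text[0].startswith("#"):
        t_pre = float(text[0].split("=", 1)[1])
        text = text[1:]
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(text)))
    kwargs = {"t_pre": t_pre} if t_pre is not None else {}
    return TrialEvents(df["t_release_s"].to_numpy(),
                       df["t_trial_end_s"].to_numpy(), **kwargs)


def write_labels_csv(labels: np.ndarray, t_end: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({
        "window_index": np.arange(len(labels)),
        "t_end_s": t_end,
        "state": labels,
    }).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gate_trace_csv(strengths: np.ndarray, flags: np.ndarray,
                         path: str | Path) -> None:
    """Level-1 gate decision trace: one row per evaluation step."""
    pd.DataFrame({
        "step_index": np.arange(len(flags)),
        "strength": strengths,
        "flag": flags.astype(int),
        "state": np.where(flags, "S1+", "S0"),
    }).to_csv(path, index=False)


def write_decision_trace_csv(trace: DecisionTrace, path: str | Path) -> None:
    pd.DataFrame({
        "window_index": np.arange(trace.stage.size),
        "stage": trace.stage,
        "gate_flag": trace.gate_flags.astype(int),
        "p1": trace.p1,
        "p2": trace.p2,
        "bits": trace.bits,
    }).to_csv(path, index=False)


def read_decision_trace_csv(path: str | Path) -> DecisionTrace:
    df = pd.read_csv(path)
    return DecisionTrace(
        stage=df["stage"].to_numpy(dtype="<U16"),
        bits=df["bits"].to_numpy(dtype=float),
        gate_flags=df["gate_flag"].to_numpy(dtype=bool),
        p1=df["p1"].to_numpy(dtype=float),
        p2=df["p2"].to_numpy(dtype=float),
    )
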
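"""HDF5/TSV/YAML interchange.

Sessions are stored as HDF5 with one group per subject:

    /subjects/<id>/trials            TSV-encoded trial table (UTF-8 string)
    /subjects/<id>/<locking>/data    trials x channels x samples
        attrs: fs, window_ms, baseline_ms, channels, locking

Ground-truth generator settings travel as YAML.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import ProspectParams
from .containers import EpochsContainer
from .synthetic import GroundTruth, SyntheticSession

__all__ = [
    "save_sessions",
    "load_sessions",
    "save_epochs",
    "load_epochs",
    "save_recording",
    "load_recording",
    "truth_from_yaml",
    "truth_to_yaml",
]


def save_recording(path, recording) -> None:
    """Continuous multichannel data to HDF5 (channels x samples + events)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=recording.data, compression="gzip")
        d.attrs["fs"] = recording.fs
        d.attrs["roles"] = [str(r) for r in recording.channel_roles]
        d.attrs["channels"] = [str(c) for c in recording.channel_names]
        ev = f.create_group("events")
        ev.create_dataset("sample", data=recording.events["sample"].to_numpy(dtype=int))
        ev.create_dataset("code", data=recording.events["code"].to_numpy(dtype=int))


def load_recording(path):
    from .containers import ContinuousRecording

    with h5py.File(path, "r") as f:
        d = f["data"]
        events = pd.DataFrame({
            "sample": f["events/sample"][()],
            "code": f["events/code"][()],
        })
        return ContinuousRecording(
            data=d[()],
            fs=float(d.attrs["fs"]),
            channel_roles=[str(r) for r in d.attrs["roles"]],
            events=events,
            channel_names=[str(c) for c in d.attrs["channels"]],
        )


def save_epochs(group: h5py.Group, epochs: EpochsContainer) -> None:
    d = group.create_dataset("data", data=epochs.data, compression="gzip")
    d.attrs["fs"] = epochs.fs
    d.attrs["window_ms"] = epochs.window_ms
    d.attrs["baseline_ms"] = epochs.baseline_ms if epochs.baseline_ms else (np.nan, np.nan)
    d.attrs["channels"] = [str(c) for c in epochs.channel_names]
    d.attrs["locking"] = epochs.locking
    group.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids))
    group.create_dataset("rejected", data=epochs.rejected)


def load_epochs(group: h5py.Group) -> EpochsContainer:
    d = group["data"]
    baseline = tuple(d.attrs["baseline_ms"])
    if np.any(np.isnan(baseline)):
        baseline = None
    return EpochsContainer(
        data=d[()],
        fs=float(d.attrs["fs"]),
        window_ms=tuple(d.attrs["window_ms"]),
        locking=str(d.attrs["locking"]),
        baseline_ms=baseline,
        trial_ids=group["trial_ids"][()],
        channel_names=[str(c) for c in d.attrs["channels"]],
        rejected=group["rejected"][()],
    )


def save_sessions(path, sessions: dict[str, SyntheticSession]) -> None:
    """Write per-subject trial tables and epochs to one HDF5 file."""
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for sid, sess in sessions.items():
            g = root.create_group(str(sid))
            buf = _io.StringIO()
            sess.trials.to_csv(buf, sep="\t", index=False)
            g.create_dataset("trials", data=buf.getvalue())
            for locking, ep in sess.epochs.items():
                save_epochs(g.create_group(locking), ep)


def load_sessions(path) -> dict[str, SyntheticSession]:
    out: dict[str, SyntheticSession] = {}
    with h5py.File(path, "r") as f:
        for sid, g in f["subjects"].items():
            trials = pd.read_csv(_io.StringIO(g["trials"][()].decode()), sep="\t")
            epochs = {
                name: load_epochs(sub)
                for name, sub in g.items()
                if isinstance(sub, h5py.Group)
            }
            out[sid] = SyntheticSession(trials=trials, epochs=epochs, truth=GroundTruth())
    return out


def truth_to_yaml(truth: GroundTruth) -> str:
    d = asdict(truth)
    d["prospect"] = {k: v for k, v in d["prospect"].items()}
    return yaml.safe_dump(d, sort_keys=False)


def truth_from_yaml(text_or_path) -> GroundTruth:
    """Ground truth from YAML text or a file path."""
    try:
        with open(text_or_path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, ValueError):
        raw = yaml.safe_load(text_or_path)
    prospect = raw.pop("prospect", {})
    return GroundTruth(prospect=ProspectParams(**prospect), **raw)
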
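"""Session container I/O: HDF5 (one group per trial) and per-channel CSV."""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd

from .render import Channel, TrialSignalSet
from .study import SessionDataset

__all__ = [
    "write_session_hdf5",
    "read_session_hdf5",
    "write_trial_csv",
    "read_channel_csv",
]


def write_session_hdf5(session: SessionDataset, path: str | pathlib.Path) -> None:
    """One group per trial, one dataset per channel with fs/units attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["subject"] = session.subject
        f.attrs["condition"] = session.condition
        f.attrs["start_time"] = session.start_time
        f.attrs["pain_ratings"] = session.pain_ratings
        f.attrs["cortisol_samples"] = session.cortisol_samples
        for trial_set in session.trials:
            g = f.create_group(f"trial{trial_set.trial}")
            for name, ch in trial_set.channels().items():
                d = g.create_dataset(name, data=ch.data)
                d.attrs["fs"] = ch.fs
                d.attrs["units"] = ch.units
            g.attrs["eeg_channels"] = list(trial_set.eeg_channels)


def read_session_hdf5(path: str | pathlib.Path) -> SessionDataset:
    with h5py.File(path, "r") as f:
        trials = []
        for key in sorted(k for k in f.keys() if k.startswith("trial")):
            g = f[key]

            def ch(name: str) -> Channel:
                d = g[name]
                return Channel(d[()], float(d.attrs["fs"]), str(d.attrs["units"]))

            trials.append(
                TrialSignalSet(
                    trial=int(key.removeprefix("trial")),
                    ecg=ch("ecg"),
                    dzdt=ch("dzdt"),
                    z0=ch("z0"),
                    bp=ch("bp"),
                    pupil_left=ch("pupil_left"),
                    pupil_right=ch("pupil_right"),
                    eeg=ch("eeg"),
                    eeg_channels=tuple(
                        c.decode() if isinstance(c, bytes) else str(c)
                        for c in g.attrs["eeg_channels"]
                    ),
                )
            )
        return SessionDataset(
            subject=str(f.attrs["subject"]),
            condition=str(f.attrs["condition"]),
            start_time=str(f.attrs["start_time"]),
            trials=trials,
            pain_ratings=[int(p) for p in f.attrs["pain_ratings"]],
            cortisol_samples=[float(c) for c in f.attrs["cortisol_samples"]],
        )


def write_trial_csv(trial_set: TrialSignalSet, outdir: str | pathlib.Path) -> None:
    """Per-channel CSV files (time_s, value); EEG gets one column per channel."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ch in trial_set.channels().items():
        if ch.data.ndim == 2:
            t = np.arange(ch.data.shape[1]) / ch.fs
            df = pd.DataFrame(ch.data.T, columns=list(trial_set.eeg_channels))
            df.insert(0, "time_s", t)
        else:
            t = np.arange(ch.data.size) / ch.fs
            df = pd.DataFrame({"time_s": t, "value": ch.data})
        df.to_csv(outdir / f"trial{trial_set.trial}_{name}.csv", index=False)


def read_channel_csv(path: str | pathlib.Path) -> tuple[np.ndarray, float]:
    """Read a (time_s, value) CSV; returns (values, fs)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return df["value"].to_numpy(), fs
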
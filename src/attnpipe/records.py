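"""In-memory containers for continuous EEG records and epoch sets, with HDF5 I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class Record:
    """A continuous multichannel voltage record.

    data: (n_channels, n_samples) in microvolts; events: one row per marker
    with integer ``sample``, ``time`` (s), ``kind`` ("cue" or "stim") and
    ``trial_index`` into the generating schedule.
    """

    data: np.ndarray
    srate: float
    channel_names: list[str]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("record data must be (channels, samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def copy(self) -> "Record":
        return Record(self.data.copy(), self.srate, list(self.channel_names),
                      self.events.copy())

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=1)
            f.attrs["srate"] = self.srate
            f.create_dataset("channel_names",
                             data=np.array(self.channel_names, dtype="S16"))
            ev = f.create_group("events")
            ev.create_dataset("sample", data=self.events["sample"].to_numpy(np.int64))
            ev.create_dataset("time", data=self.events["time"].to_numpy(float))
            ev.create_dataset("kind", data=self.events["kind"].astype(str).to_numpy(dtype="S8"))
            ev.create_dataset("trial_index", data=self.events["trial_index"].to_numpy(np.int64))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Record":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            srate = float(f.attrs["srate"])
            names = [n.decode() for n in f["channel_names"][()]]
            events = pd.DataFrame({
                "sample": f["events/sample"][()],
                "time": f["events/time"][()],
                "kind": [k.decode() for k in f["events/kind"][()]],
                "trial_index": f["events/trial_index"][()],
            })
        return cls(data, srate, names, events)


@dataclass
class EpochSet:
    """Epoched voltage data.

    data: (n_trials, n_channels, n_samples) in microvolts; ``times`` is the
    common axis in seconds relative to the lock event (``lock`` is "cue" or
    "target"); ``trial_meta`` has one row per retained trial;
    ``rejection_mask`` is indexed by *original* trial and True where a trial
    has been rejected.
    """

    data: np.ndarray
    srate: float
    times: np.ndarray
    lock: str
    channel_names: list[str]
    trial_meta: pd.DataFrame
    rejection_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, samples)")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times length must match data samples")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta must have one row per retained trial")
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(self.data.shape[0], dtype=bool)
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.srate, rtol=1e-6)):
            raise ValueError("times must increase uniformly at 1/srate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.srate, self.times.copy(), self.lock,
                        list(self.channel_names), self.trial_meta.copy(),
                        self.rejection_mask.copy())

    def select_channels(self, names: list[str]) -> "EpochSet":
        from .montage import channel_indices
        idx = channel_indices(names, self.channel_names)
        return EpochSet(self.data[:, idx, :], self.srate, self.times.copy(), self.lock,
                        list(names), self.trial_meta.copy(), self.rejection_mask.copy())

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(self.data[mask], self.srate, self.times.copy(), self.lock,
                        list(self.channel_names),
                        self.trial_meta.loc[mask].reset_index(drop=True),
                        self.rejection_mask.copy())

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", compression_opts=1)
            f.attrs["srate"] = self.srate
            f.attrs["lock"] = self.lock
            f.create_dataset("times", data=self.times)
            f.create_dataset("channel_names",
                             data=np.array(self.channel_names, dtype="S16"))
            f.create_dataset("rejection_mask", data=self.rejection_mask)
            meta = f.create_group("trial_meta")
            for col in self.trial_meta.columns:
                vals = self.trial_meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S32")
                meta.create_dataset(col, data=vals)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            meta = {}
            for col in f["trial_meta"]:
                vals = f["trial_meta"][col][()]
                if vals.dtype.kind == "S":
                    vals = np.array([v.decode() for v in vals])
                meta[col] = vals
            return cls(
                data=f["data"][()],
                srate=float(f.attrs["srate"]),
                times=f["times"][()],
                lock=str(f.attrs["lock"]),
                channel_names=[n.decode() for n in f["channel_names"][()]],
                trial_meta=pd.DataFrame(meta),
                rejection_mask=f["rejection_mask"][()].astype(bool),
            )
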
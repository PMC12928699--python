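"""Epoch container and its HDF5 on-disk format.

An :class:`EpochSet` holds stimulus-locked multichannel epochs as a
``(trials, sensors, time)`` array plus a per-trial label table and a uniform
time axis.  On disk the layout is:

* ``/data``   -- float64 dataset, trials x sensors x time
* ``/times``  -- float64 dataset, seconds relative to stimulus onset
* ``/labels/<column>`` -- one dataset per label column (strings UTF-8)
* ``/meta``   -- group whose attrs carry ``format_version``, ``sample_rate``
  and any extra JSON-serialisable metadata

Unknown extra metadata is preserved; files with a major format version the
reader does not understand raise :class:`FormatError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet", "FormatError", "read_epochs", "write_epochs"]

FORMAT_VERSION = 1


class FormatError(IOError):
    """File does not conform to the epoch container layout."""


@dataclass
class EpochSet:
    """Trials x sensors x time epochs with per-trial labels.

    Attributes
    ----------
    data : ndarray (trials, sensors, time)
        Sensor amplitudes (microvolts for real data; arbitrary in simulation).
    times : ndarray (time,)
        Strictly increasing, uniform time axis in seconds (0 = stimulus onset).
    sample_rate : float
        Sampling rate in Hz.
    labels : DataFrame
        One row per trial; standard columns are ``participant``,
        ``condition`` (A/V/AV), ``location_deg``, ``block``, ``trial`` and the
        boolean ``kept`` flag.
    meta : dict
        Free-form JSON-serialisable metadata.
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sensors, time)")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("time axis length must match data's last axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError("time axis must be strictly increasing and uniform")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if "kept" not in self.labels.columns:
            self.labels = self.labels.assign(kept=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask) -> "EpochSet":
        """Subset trials by a boolean mask or index array."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool or mask.dtype.kind in "iu"
            else self.labels[mask].reset_index(drop=True),
        )

    def kept(self) -> "EpochSet":
        """Only trials whose ``kept`` flag is True."""
        return self.select(self.labels["kept"].to_numpy())


def write_epochs(epochs: EpochSet, path: str) -> None:
    """Write an :class:`EpochSet` losslessly (float64 bit-exact) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, dtype="f8")
        f.create_dataset("times", data=epochs.times, dtype="f8")
        lab = f.create_group("labels")
        lab.attrs["columns"] = json.dumps(list(epochs.labels.columns))
        for col in epochs.labels.columns:
            vals = epochs.labels[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                lab.create_dataset(col, data=np.array([str(v) for v in vals], dtype="S"))
            else:
                lab.create_dataset(col, data=vals)
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["sample_rate"] = float(epochs.sample_rate)
        meta.attrs["extra"] = json.dumps(epochs.meta)


def read_epochs(path: str) -> EpochSet:
    """Read an epoch container written by :func:`write_epochs`."""
    try:
        with h5py.File(path, "r") as f:
            for key in ("data", "times", "labels", "meta"):
                if key not in f:
                    raise FormatError(f"{path}: missing required group/dataset '{key}'")
            version = int(f["meta"].attrs.get("format_version", -1))
            if version > FORMAT_VERSION:
                raise FormatError(
                    f"{path}: format version {version} newer than supported {FORMAT_VERSION}"
                )
            data = f["data"][()]
            times = f["times"][()]
            sample_rate = float(f["meta"].attrs["sample_rate"])
            meta = json.loads(f["meta"].attrs.get("extra", "{}"))
            lab = f["labels"]
            columns = json.loads(lab.attrs["columns"])
            frame = {}
            for col in columns:
                vals = lab[col][()]
                if vals.dtype.kind == "S":
                    vals = np.array([v.decode() for v in vals])
                frame[col] = vals
            labels = pd.DataFrame(frame, columns=columns)
    except OSError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not a readable epoch container ({exc})") from exc
    if "kept" in labels.columns:
        labels["kept"] = labels["kept"].astype(bool)
    return EpochSet(data=data, times=times, sample_rate=sample_rate, labels=labels, meta=meta)
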
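"""Shared containers for evenly sampled traces, spike trains and event tables.

These are deliberately small, NumPy-backed value objects.  All analysis
modules exchange data through them, and each knows how to round-trip
itself through plain-text CSV (and HDF5 for long traces), so every file
the pipeline writes can be re-read by the module that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "UniformTimeSeries",
    "SpikeTrain",
    "EventTable",
    "PSTH",
]


@dataclass(frozen=True)
class UniformTimeSeries:
    """Evenly sampled signal (photometry, firing rate, value or TD trace).

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds (> 0).
    values : ndarray
        Sample values; finite floats.
    units : str
        Free-form unit label.  Labels ending in ``"!noiso"`` mark channels
        that must never be isosbestic-corrected (used for dopamine-sensor
        signals, whose isosbestic wavelength is unknown).
    """

    t0: float
    dt: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if vals.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n - 1)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "UniformTimeSeries":
        return replace(self, values=np.asarray(values, float),
                       units=self.units if units is None else units)

    def index_of(self, t: float) -> int:
        """Nearest sample index of time ``t`` (clipped to the trace)."""
        return int(np.clip(round((t - self.t0) / self.dt), 0, self.n - 1))

    # ---- I/O -----------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, units: str = "") -> "UniformTimeSeries":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer dt")
        dt = float(np.median(np.diff(t)))
        return cls(t0=float(t[0]), dt=dt, values=df["value"].to_numpy(float), units=units)

    def to_hdf5(self, path, name: str = "trace") -> None:
        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            ds = f.create_dataset(name, data=self.values)
            ds.attrs["t0"] = self.t0
            ds.attrs["dt"] = self.dt
            ds.attrs["units"] = self.units

    @classmethod
    def from_hdf5(cls, path, name: str = "trace") -> "UniformTimeSeries":
        with h5py.File(path, "r") as f:
            ds = f[name]
            return cls(t0=float(ds.attrs["t0"]), dt=float(ds.attrs["dt"]),
                       values=ds[...], units=str(ds.attrs.get("units", "")))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) of one unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("spike times must be nondecreasing")
        if t.size and t[0] < 0:
            raise ValueError("spike times must be nonnegative")

    @property
    def n(self) -> int:
        return self.times.size

    def count_in(self, start: float, stop: float) -> int:
        return int(np.searchsorted(self.times, stop) - np.searchsorted(self.times, start))


def spike_trains_to_csv(trains: list[SpikeTrain], path) -> None:
    rows = [(tr.unit_id, t) for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(path, index=False)


def spike_trains_from_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    out = []
    for uid, grp in df.groupby("unit_id", sort=True):
        out.append(SpikeTrain(unit_id=str(uid), times=np.sort(grp["spike_time_s"].to_numpy(float))))
    return out


@dataclass(frozen=True)
class EventTable:
    """Labelled event times, sorted ascending."""

    event_type: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        labels = np.asarray(self.event_type, dtype=object)
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "times", t[order])
        object.__setattr__(self, "event_type", labels[order])
        if labels.shape != t.shape:
            raise ValueError("event_type and times must have equal length")

    @classmethod
    def from_times(cls, times, event_type: str = "event") -> "EventTable":
        times = np.asarray(times, float)
        return cls(event_type=np.array([event_type] * times.size, dtype=object), times=times)

    @property
    def n(self) -> int:
        return self.times.size

    def of_type(self, label: str) -> np.ndarray:
        return self.times[self.event_type == label]

    def to_csv(self, path) -> None:
        pd.DataFrame({"event_type": self.event_type, "time_s": self.times}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        df = pd.read_csv(path)
        return cls(event_type=df["event_type"].to_numpy(object), times=df["time_s"].to_numpy(float))


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged event-aligned response with across-trial SEM."""

    window: tuple[float, float]
    bin_dt: float
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    units: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, float)
        s = np.asarray(self.sem, float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sem", s)
        if m.shape != s.shape:
            raise ValueError("mean and sem must have equal shape")
        if np.any(s < 0):
            raise ValueError("sem must be nonnegative")

    @property
    def lags(self) -> np.ndarray:
        return self.window[0] + self.bin_dt * np.arange(self.mean.size)

    def as_timeseries(self) -> UniformTimeSeries:
        return UniformTimeSeries(t0=self.window[0], dt=self.bin_dt, values=self.mean, units=self.units)

    def to_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write(f"# window_s={self.window[0]},{self.window[1]}\n")
            f.write(f"# bin_dt_s={self.bin_dt}\n")
            f.write(f"# n_trials={self.n_trials}\n")
            pd.DataFrame({"lag_s": self.lags, "mean": self.mean, "sem": self.sem}).to_csv(f, index=False)

    @classmethod
    def from_csv(cls, path) -> "PSTH":
        meta = {}
        with open(path) as f:
            for line in f:
                if not line.startswith("#"):
                    break
                key, val = line[1:].strip().split("=", 1)
                meta[key] = val
        df = pd.read_csv(path, comment="#")
        w0, w1 = (float(x) for x in meta["window_s"].split(","))
        return cls(window=(w0, w1), bin_dt=float(meta["bin_dt_s"]),
                   mean=df["mean"].to_numpy(float), sem=df["sem"].to_numpy(float),
                   n_trials=int(meta["n_trials"]))
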
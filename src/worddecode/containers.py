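"""In-memory containers for continuous and epoched EEG plus HDF5 storage.

Epoched data live in a trials x channels x samples float array with a
pandas trial table aligned on the first axis.  The on-disk container is a
plain HDF5 file with dataset ``/data``, a ``/meta`` group holding one
dataset per trial-table column, and root attributes ``sfreq``, ``tmin_ms``
and ``tmax_ms``.  Sample windows are half-open ``[tmin, tmax)`` throughout
the package, 0-based, with time in ms relative to word onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochedDataset", "ContinuousRecording"]


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording with stimulus events.

    ``events`` is a DataFrame with at least columns ``sample`` (onset sample
    index) and ``word_form``; any further columns are carried into epoch
    metadata unchanged.
    """

    data: np.ndarray  # channels x samples, microvolt
    sampling_rate: float
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be channels x samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.events) and (
            (self.events["sample"] < 0).any()
            or (self.events["sample"] >= self.data.shape[1]).any()
        ):
            raise ValueError("event samples outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedDataset:
    """Single-subject epoched EEG: trials x channels x samples plus metadata."""

    data: np.ndarray
    meta: pd.DataFrame
    sampling_rate: float
    tmin_ms: float
    tmax_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be trials x channels x samples")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.meta)}) do not match trials "
                f"({self.data.shape[0]})"
            )
        expected = round((self.tmax_ms - self.tmin_ms) / 1000.0 * self.sampling_rate)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"expected {expected} samples for [{self.tmin_ms}, {self.tmax_ms}) ms "
                f"at {self.sampling_rate} Hz, got {self.data.shape[2]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time of each sample (ms, onset = 0); half-open [tmin, tmax)."""
        step = 1000.0 / self.sampling_rate
        return self.tmin_ms + step * np.arange(self.n_samples)

    def sample_at(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` (must align with the sample grid)."""
        idx = (t_ms - self.tmin_ms) * self.sampling_rate / 1000.0
        if not np.isclose(idx, round(idx)):
            raise ValueError(f"{t_ms} ms is not on the sample grid")
        i = int(round(idx))
        if not 0 <= i <= self.n_samples:
            raise ValueError(f"{t_ms} ms outside the epoch")
        return i

    def select(self, index: np.ndarray) -> "EpochedDataset":
        """Subset of trials (boolean mask or integer index), metadata aligned."""
        index = np.asarray(index)
        return EpochedDataset(
            data=self.data[index],
            meta=self.meta.iloc[index].reset_index(drop=True),
            sampling_rate=self.sampling_rate,
            tmin_ms=self.tmin_ms,
            tmax_ms=self.tmax_ms,
        )

    def copy_with(self, data: np.ndarray) -> "EpochedDataset":
        return EpochedDataset(
            data=data,
            meta=self.meta.copy(),
            sampling_rate=self.sampling_rate,
            tmin_ms=self.tmin_ms,
            tmax_ms=self.tmax_ms,
        )

    # -- HDF5 container -----------------------------------------------------

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", shuffle=True)
            grp = f.create_group("meta")
            for col in self.meta.columns:
                values = self.meta[col].to_numpy()
                if values.dtype == object or values.dtype.kind == "U":
                    grp.create_dataset(
                        col, data=[str(v) for v in values],
                        dtype=h5py.string_dtype("utf-8"),
                    )
                else:
                    grp.create_dataset(col, data=values)
            grp.attrs["columns"] = list(self.meta.columns)
            f.attrs["sfreq"] = self.sampling_rate
            f.attrs["tmin_ms"] = self.tmin_ms
            f.attrs["tmax_ms"] = self.tmax_ms

    @classmethod
    def load_h5(cls, path: str | Path) -> "EpochedDataset":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            cols = list(f["meta"].attrs["columns"])
            meta = {}
            for col in cols:
                values = f["meta"][col][()]
                if values.dtype.kind in ("O", "S"):
                    values = np.array([v.decode() if isinstance(v, bytes) else v
                                       for v in values])
                meta[col] = values
            return cls(
                data=data,
                meta=pd.DataFrame(meta, columns=cols),
                sampling_rate=float(f.attrs["sfreq"]),
                tmin_ms=float(f.attrs["tmin_ms"]),
                tmax_ms=float(f.attrs["tmax_ms"]),
            )
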
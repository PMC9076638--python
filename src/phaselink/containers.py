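"""In-memory containers shared across stages, with HDF5/TSV round-trips.

The central object is :class:`EpochedSourceData`: source-level EEG epochs
(trials x sources x samples) together with their alignment metadata. Epochs
are cut +/-2.5 s around a cue so that wavelet edge artifacts never reach the
analysis windows; the ``alignment`` field records whether time zero is the
transition cue (stimulus-locked) or the per-condition median transition
latency (response-locked).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

SOURCE_LABELS = ("LSM1", "RSM1", "OCC")


@dataclass
class EpochedSourceData:
    """Epoched source-level time series.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_sources, n_samples)
        Source signals in arbitrary amplitude units.
    time_s : ndarray, shape (n_samples,)
        Time axis in seconds relative to the alignment event.
    fs : float
        Sampling rate in Hz (250 Hz throughout the pipeline).
    alignment : {"stimulus", "response"}
    source_labels : tuple of str
    trial_table : DataFrame or None
        Per-trial metadata (trial_index, cue_type, mode_after, ...).
    """

    data: np.ndarray
    time_s: np.ndarray
    fs: float
    alignment: str = "stimulus"
    source_labels: tuple = SOURCE_LABELS
    trial_table: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, source, sample)")
        if self.data.shape[2] != self.time_s.size:
            raise ValueError("time axis does not match data")
        if self.alignment not in ("stimulus", "response"):
            raise ValueError(f"unknown alignment {self.alignment!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def source_index(self, label: str) -> int:
        return list(self.source_labels).index(label)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32),
                             track_times=False)
            f.create_dataset("time_s", data=self.time_s, track_times=False)
            f.attrs["fs"] = self.fs
            f.attrs["alignment"] = self.alignment
            f.attrs["source_labels"] = list(self.source_labels)
            if self.trial_table is not None:
                g = f.create_group("trial_table")
                for col in self.trial_table.columns:
                    vals = self.trial_table[col].to_numpy()
                    if vals.dtype == object:
                        vals = vals.astype("S")
                    g.create_dataset(col, data=vals, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "EpochedSourceData":
        with h5py.File(path, "r") as f:
            table = None
            if "trial_table" in f:
                cols = {}
                for col in f["trial_table"]:
                    v = f["trial_table"][col][...]
                    if v.dtype.kind == "S":
                        v = v.astype(str)
                    cols[col] = v
                table = pd.DataFrame(cols)
            return cls(
                data=f["data"][...].astype(np.float64),
                time_s=f["time_s"][...],
                fs=float(f.attrs["fs"]),
                alignment=str(f.attrs["alignment"]),
                source_labels=tuple(str(s) for s in f.attrs["source_labels"]),
                trial_table=table,
            )


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8 TSV with stable float formatting.

    A fixed '%.8g' format keeps repeated runs byte-identical.
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_tsv(path) -> pd.DataFrame:
    # leading '#' lines carry run metadata (config hash)
    return pd.read_csv(path, sep="\t", comment="#")
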
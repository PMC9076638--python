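"""Inter-site phase clustering (ISPC) and single-trial phase lags.

ISPC at frequency f and time t is the modulus of the mean complex
exponential of the phase-angle differences between two sources,

    ISPC_f(t) = | n^-1 sum_k exp(i (phi_x,k - phi_y,k)) |,

clustered over the n trials at each time point of a 50 Hz grid (phase time
courses computed at 250 Hz are kept at every 5th sample). ISPC is 1 for a
perfectly consistent lag of any size -- it is invariant to the lag itself --
and falls to ~0.886/sqrt(n) for uniformly random lags. A windowed
over-time variant (clustering the n time points of a single trial) is also
provided.

The module also baseline-corrects ISPC maps against the -500..-200 ms
pre-cue window, re-aligns epochs response-locked (+/-260 ms around the
per-condition median transition latency), and extracts the single-trial
band-pooled phase lag that the circular phase-behavior analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

from ._utils import circ_mean_resultant, wrap_angle
from .containers import EpochedSourceData

DOWNSAMPLE_STEP = 5  # 250 Hz -> 50 Hz
BANDS = {"low_beta": (15.0, 22.0), "high_beta": (25.0, 30.0)}


@dataclass
class ISPCMap:
    values: np.ndarray  # [freq, time]
    freqs_hz: np.ndarray
    time_s: np.ndarray
    variant: str = "raw"  # raw / baseline_subtracted / z
    pair: tuple = ("LSM1", "RSM1")
    alignment: str = "stimulus"
    n_trials: int = 0

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values, track_times=False)
            f.create_dataset("freqs_hz", data=self.freqs_hz, track_times=False)
            f.create_dataset("time_s", data=self.time_s, track_times=False)
            f.attrs.update({"variant": self.variant,
                            "pair": list(self.pair),
                            "alignment": self.alignment,
                            "n_trials": self.n_trials})

    @classmethod
    def from_hdf5(cls, path) -> "ISPCMap":
        with h5py.File(path, "r") as f:
            return cls(values=f["values"][...], freqs_hz=f["freqs_hz"][...],
                       time_s=f["time_s"][...],
                       variant=str(f.attrs["variant"]),
                       pair=tuple(str(p) for p in f.attrs["pair"]),
                       alignment=str(f.attrs["alignment"]),
                       n_trials=int(f.attrs["n_trials"]))


def ispc(phases_a: np.ndarray, phases_b: np.ndarray,
         freqs_hz: np.ndarray | None = None,
         time_s: np.ndarray | None = None,
         downsample_step: int = DOWNSAMPLE_STEP,
         pair: tuple = ("LSM1", "RSM1"),
         alignment: str = "stimulus") -> ISPCMap:
    """ISPC over trials on the downsampled time grid.

    ``phases_a``/``phases_b`` are [trial, freq, time] (or [trial, time] for
    a single frequency) phase angles in radians.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase arrays must have equal shapes")
    if a.ndim == 2:
        a, b = a[:, None, :], b[:, None, :]
    if a.shape[0] < 2:
        raise ValueError("ISPC over trials is undefined for a single trial")
    a = a[..., ::downsample_step]
    b = b[..., ::downsample_step]
    vals = np.abs(np.mean(np.exp(1j * (a - b)), axis=0))
    if freqs_hz is None:
        freqs_hz = np.arange(vals.shape[0], dtype=float)
    if time_s is None:
        time_s = np.arange(vals.shape[1], dtype=float)
    else:
        time_s = np.asarray(time_s, dtype=float)[::downsample_step]
    return ISPCMap(values=vals, freqs_hz=np.asarray(freqs_hz, dtype=float),
                   time_s=time_s, variant="raw", pair=pair,
                   alignment=alignment, n_trials=a.shape[0])


def ispc_over_time(phases_a: np.ndarray, phases_b: np.ndarray,
                   window: int | None = None) -> np.ndarray:
    """Literal over-time reading: cluster the time points of each trial.

    Returns [trial, freq] (full-epoch window) or [trial, freq, time] when a
    sliding ``window`` length in samples is given.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    z = np.exp(1j * (a - b))
    if window is None:
        return np.abs(z.mean(axis=-1))
    c = np.cumsum(z, axis=-1)
    c = np.concatenate([np.zeros_like(c[..., :1]), c], axis=-1)
    out = np.abs(c[..., window:] - c[..., :-window]) / window
    return out


def baseline_subtract(m: ISPCMap, baseline: "ISPCMap | tuple" = (-0.5, -0.2)
                      ) -> ISPCMap:
    """Subtract the per-frequency baseline-mean ISPC.

    ``baseline`` is either a time window (s) evaluated on ``m`` itself or a
    separate ISPCMap (e.g. computed from the pre-start pause) whose
    frequency axis must match.
    """
    if isinstance(baseline, ISPCMap):
        if not np.allclose(baseline.freqs_hz, m.freqs_hz):
            raise ValueError("frequency axes differ")
        base = baseline.values.mean(axis=1)
    else:
        sel = (m.time_s >= baseline[0]) & (m.time_s <= baseline[1])
        if not sel.any():
            raise ValueError("baseline window outside the map")
        base = m.values[:, sel].mean(axis=1)
    return replace(m, values=m.values - base[:, None],
                   variant="baseline_subtracted")


def response_lock(epochs: EpochedSourceData, latencies_ms: pd.DataFrame,
                  half_window_s: float = 0.26) -> EpochedSourceData:
    """Re-align epochs to the per-condition median transition latency.

    ``latencies_ms`` needs columns trial_index, transition_mode, latency_ms
    (failed trials, latency NaN, are dropped). Each surviving trial is
    re-windowed to +/-``half_window_s`` around the median latency of its
    own transition mode (even counts: midpoint of the central pair). Trials
    whose window would leave the epoch are dropped.
    """
    lat = latencies_ms.dropna(subset=["latency_ms"])
    med = lat.groupby("transition_mode")["latency_ms"].median()
    table = epochs.trial_table
    if table is None:
        raise ValueError("epochs carry no trial table")
    n_out = int(round(2 * half_window_s * epochs.fs)) + 1
    kept_rows, kept_data, new_t0 = [], [], []
    lat_by_trial = dict(zip(lat["trial_index"], lat["transition_mode"]))
    for i, (_, row) in enumerate(table.iterrows()):
        tid = row["trial_index"]
        if tid not in lat_by_trial:
            continue
        center_s = med[lat_by_trial[tid]] / 1000.0
        i0 = int(round((center_s - half_window_s - epochs.time_s[0])
                       * epochs.fs))
        if i0 < 0 or i0 + n_out > epochs.data.shape[2]:
            continue  # window exceeds epoch bounds
        kept_rows.append(row)
        kept_data.append(epochs.data[i, :, i0:i0 + n_out])
        new_t0.append(center_s)
    if not kept_data:
        raise ValueError("no trial survived response-locking")
    time_s = np.arange(n_out) / epochs.fs - half_window_s
    return EpochedSourceData(data=np.stack(kept_data), time_s=time_s,
                             fs=epochs.fs, alignment="response",
                             source_labels=epochs.source_labels,
                             trial_table=pd.DataFrame(kept_rows).reset_index(drop=True))


@dataclass
class PhaseTrial:
    """One trial's band-pooled interhemispheric phase lag and its sequel.

    The unit of the single-trial circular analyses: the lag at the trial's
    own time of transition (or at the baseline control point, start cue
    minus 300 ms) paired with the error fraction that followed.
    """

    trial_id: int
    band: str
    lag_rad: float  # wrapped to (-pi, pi]
    alignment_time_ms: float
    subsequent_error: float
    subject: str = ""
    group: str = ""
    transition_mode: str = ""
    condition: str = "transition"  # transition / baseline_control


def phase_trial_frame(trials: list) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in trials])


def band_indices(freqs_hz: np.ndarray, band) -> np.ndarray:
    if isinstance(band, str):
        band = BANDS[band]
    idx = np.where((freqs_hz >= band[0]) & (freqs_hz <= band[1]))[0]
    if idx.size == 0:
        raise ValueError(f"no frequency bins inside band {band}")
    return idx


def extract_phase_lag(phases_a: np.ndarray, phases_b: np.ndarray,
                      freqs_hz: np.ndarray, time_s: np.ndarray,
                      band, at_time_s: float,
                      edge_mask: np.ndarray | None = None) -> float:
    """Band-pooled phase lag of one trial at one time point.

    ``phases_a``/``phases_b`` are [freq, time] for the trial. The lag is
    the circular mean over the band's frequency bins of (phi_a - phi_b) at
    the sample nearest ``at_time_s`` -- circular, because the bin lags are
    wrapped angles (bins at +170 deg and -170 deg pool to 180 deg, not 0).
    """
    ti = int(np.argmin(np.abs(time_s - at_time_s)))
    fi = band_indices(freqs_hz, band)
    if edge_mask is not None and edge_mask[fi, ti].any():
        raise ValueError(f"time {at_time_s:g} s lies in the masked edge region")
    d = wrap_angle(phases_a[fi, ti] - phases_b[fi, ti])
    mean, _ = circ_mean_resultant(d)
    return wrap_angle(mean)
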
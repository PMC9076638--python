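"""Synthetic motor-state transition experiment with known ground truth.

Real recordings from this paradigm (bimanual in-phase/anti-phase tapping
with cued transitions, EEG source signals from left/right sensorimotor and
occipital cortex, MRS-derived GABA+ levels) cannot be redistributed, so this
module generates the whole experiment from scratch:

* :func:`generate_schedule` -- the cue stream of a session: start cues,
  continuation/switching transition cues (~1:5 ratio), 3000 ms pauses,
  jittered 5000-8000 ms inter-stimulus intervals, and a thumb reaction-time
  probe that replaces any cue with 5 % probability and is always followed by
  a pause 1000 ms later.
* :func:`generate_tap_stream` -- paced tap pairs that switch pattern after a
  gamma-distributed transition latency, with configurable error injection.
* :func:`generate_sources` -- band-limited coupled oscillations embedded in
  1/f-plus-white noise; the cross-source phase lag is drawn per trial from a
  von Mises distribution and may step at the transition, which is exactly
  the structure inter-site phase clustering measures downstream.
* :func:`generate_cohort` -- subject-level tables produced by a known
  moderated-mediation process (outcome and mediator regressions with
  exGaussian residuals), plus group-structured GABA+ and tissue fractions.

Every stream is keyed by (seed, subject, trial) so any piece of the dataset
can be regenerated in isolation, bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._utils import keyed_rng, sample_von_mises, wrap_angle
from .containers import EpochedSourceData, SOURCE_LABELS

PAUSE_MS = 3000.0
TRT_PAUSE_LATENCY_MS = 1000.0
ISI_RANGE_MS = (5000.0, 8000.0)


# ---------------------------------------------------------------------------
# Event schedule
# ---------------------------------------------------------------------------

@dataclass
class EventSchedule:
    """Ordered cue stream of one session.

    ``events`` has columns: event_type (start/continue/switch/pause/tRT),
    onset_ms, side (left/right/none), trial_index.
    """

    events: pd.DataFrame
    session_length_ms: float

    def counts(self) -> dict:
        return self.events["event_type"].value_counts().to_dict()

    def transition_trials(self) -> pd.DataFrame:
        """Per-trial table of transition cues with the cued tapping mode."""
        ev = self.events
        trans = ev[ev["event_type"].isin(["continue", "switch"])]
        return trans.reset_index(drop=True)

    def validate(self) -> None:
        ev = self.events
        onsets = ev["onset_ms"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        types = ev["event_type"].to_numpy()
        for i, t in enumerate(types[:-1]):
            if t == "tRT":
                nxt = ev.iloc[i + 1]
                if nxt["event_type"] != "pause" or not np.isclose(
                        nxt["onset_ms"] - ev.iloc[i]["onset_ms"],
                        TRT_PAUSE_LATENCY_MS):
                    raise ValueError("tRT must be followed by a pause at "
                                     f"{TRT_PAUSE_LATENCY_MS:g} ms latency")
        # ISIs of non-pause events, measured from the end of any preceding
        # pause (pauses freeze the cue clock for their 3000 ms duration)
        clock = None
        for _, row in ev.iterrows():
            if row["event_type"] == "pause":
                clock = row["onset_ms"] + PAUSE_MS
                continue
            if clock is not None:
                isi = row["onset_ms"] - clock
                if not (ISI_RANGE_MS[0] - 1e-9 <= isi <= ISI_RANGE_MS[1] + 1e-9):
                    raise ValueError(f"ISI {isi:g} ms outside {ISI_RANGE_MS}")
            clock = row["onset_ms"]


def generate_schedule(n_trials: int, p_trt: float = 0.05,
                      switch_ratio: float = 5.0, seed: int = 0) -> EventSchedule:
    """Generate the paradigm's cue stream.

    Each trial is [start cue, ISI, transition cue, ISI, pause]; the
    transition cue is 'switch' with probability switch_ratio/(1+switch_ratio)
    (continuation:switching ~ 1:5 at the default) and every non-pause cue
    slot is replaced by a thumb-RT probe with probability ``p_trt``. A probe
    is followed by a pause 1000 ms later, after which the trial resumes.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 <= p_trt < 1):
        raise ValueError("p_trt must lie in [0, 1)")
    if switch_ratio <= 0:
        raise ValueError("switch_ratio must be > 0")

    rng = keyed_rng(seed, "schedule")
    p_switch = switch_ratio / (1.0 + switch_ratio)
    rows = []
    t = float(rng.uniform(*ISI_RANGE_MS))
    mode = "in_phase"  # tapping mode entering the first trial

    def emit(etype, onset, side, trial):
        rows.append((etype, onset, side, trial))

    for trial in range(n_trials):
        for slot in ("start", "transition"):
            if rng.uniform() < p_trt:
                side = "left" if rng.uniform() < 0.5 else "right"
                emit("tRT", t, side, trial)
                emit("pause", t + TRT_PAUSE_LATENCY_MS, "none", trial)
                t = t + TRT_PAUSE_LATENCY_MS + PAUSE_MS + rng.uniform(*ISI_RANGE_MS)
                continue
            if slot == "start":
                emit("start", t, "none", trial)
            else:
                if rng.uniform() < p_switch:
                    emit("switch", t, "none", trial)
                    mode = "anti_phase" if mode == "in_phase" else "in_phase"
                else:
                    emit("continue", t, "none", trial)
            t += rng.uniform(*ISI_RANGE_MS)
        emit("pause", t, "none", trial)
        t = t + PAUSE_MS + rng.uniform(*ISI_RANGE_MS)

    ev = pd.DataFrame(rows, columns=["event_type", "onset_ms", "side",
                                     "trial_index"])
    # annotate transition cues with the cued (post-cue) tapping mode
    ev["mode_after"] = ""
    mode = "in_phase"
    for i in ev.index:
        et = ev.at[i, "event_type"]
        if et == "switch":
            mode = "anti_phase" if mode == "in_phase" else "in_phase"
            ev.at[i, "mode_after"] = mode
        elif et == "continue":
            ev.at[i, "mode_after"] = mode
    return EventSchedule(events=ev, session_length_ms=t)


# ---------------------------------------------------------------------------
# Tap stream
# ---------------------------------------------------------------------------

@dataclass
class TapParams:
    """Subject-level tapping model.

    tap_freq_hz is the paced tapping rate; transition latency is
    gamma(shape, scale_ms) unless ``fixed_latency_ms`` overrides it.
    Error injection: ``pair_error_rate`` flips individual post-transition
    pairs into the wrong pattern, ``p_failed`` makes whole trials fully
    erroneous, ``always_wrong`` forces every pair wrong (for failed-trial
    plumbing tests).
    """

    tap_freq_hz: float = 1.6
    latency_shape: float = 9.0
    latency_scale_ms: float = 60.0
    fixed_latency_ms: float | None = None
    pair_error_rate: float = 0.0
    p_failed: float = 0.0
    always_wrong: bool = False
    tap_jitter_ms: float = 3.0
    trt_rt_shape: float = 4.0
    trt_rt_scale_ms: float = 40.0
    trt_rt_shift_ms: float = 150.0


_MODE_FINGERS = {
    # two equivalent realizations per mode, alternated between beats
    "in_phase": ((("L", "index"), ("R", "index")),
                 (("L", "middle"), ("R", "middle"))),
    "anti_phase": ((("L", "index"), ("R", "middle")),
                   (("L", "middle"), ("R", "index"))),
}


def _other_mode(mode: str) -> str:
    return "anti_phase" if mode == "in_phase" else "in_phase"


def generate_tap_stream(schedule: EventSchedule, params: TapParams,
                        seed: int = 0, window_ms: float = 2500.0):
    """Simulate the tap stream for one subject.

    Returns ``(taps, trial_truth)``: a tap table (time_ms, hand, finger) and
    the per-trial ground truth (true latency, planted error bookkeeping).
    Tapping is emitted around every transition cue: the pre-cue pattern
    continues until cue + latency, then the cued pattern takes over; the
    first post-latency pair falls exactly at cue + latency so a noise-free
    stream round-trips the latency through the behavioral scorer.
    """
    if schedule.events.empty:
        raise ValueError("empty schedule")
    if params.tap_freq_hz <= 0:
        raise ValueError("tap_freq_hz must be > 0")

    period = 1000.0 / params.tap_freq_hz
    taps = []
    truth_rows = []
    trans = schedule.transition_trials()
    for _, cue in trans.iterrows():
        trial = int(cue["trial_index"])
        rng = keyed_rng(seed, "taps", trial)
        cue_t = float(cue["onset_ms"])
        mode_after = cue["mode_after"]
        mode_before = _other_mode(mode_after) if cue["event_type"] == "switch" \
            else mode_after
        if params.fixed_latency_ms is not None:
            latency = float(params.fixed_latency_ms)
        else:
            latency = float(rng.gamma(params.latency_shape,
                                      params.latency_scale_ms))
        failed = bool(params.always_wrong or rng.uniform() < params.p_failed)

        # beat grid anchored at cue + latency
        pre_beats = np.arange(cue_t + latency - period, cue_t, -period)[::-1]
        post_beats = np.arange(cue_t + latency, cue_t + window_ms, period)
        n_err = 0
        n_pairs = 0
        for k, beat in enumerate(np.concatenate([pre_beats, post_beats])):
            is_post = beat >= cue_t + latency - 1e-9
            if failed:
                pair_mode = _other_mode(mode_after)
            elif not is_post:
                pair_mode = mode_before
            else:
                if k > len(pre_beats) and rng.uniform() < params.pair_error_rate:
                    pair_mode = _other_mode(mode_after)
                else:
                    pair_mode = mode_after
            variant = _MODE_FINGERS[pair_mode][k % 2]
            jitter = rng.normal(0.0, params.tap_jitter_ms, size=2)
            if 0.0 <= beat - cue_t < 2000.0:
                n_pairs += 1
                if pair_mode != mode_after:
                    n_err += 1
            for (hand, finger), dj in zip(variant, jitter):
                taps.append((beat + dj, hand, finger))
        truth_rows.append({
            "trial_index": trial, "cue_onset_ms": cue_t,
            "cue_type": cue["event_type"], "mode_after": mode_after,
            "true_latency_ms": np.nan if failed else latency,
            "failed": failed,
            "true_error_fraction": 1.0 if failed else
            (n_err / n_pairs if n_pairs else np.nan),
        })

    # thumb RT probe responses
    trt = schedule.events[schedule.events["event_type"] == "tRT"]
    for _, ev in trt.iterrows():
        rng = keyed_rng(seed, "trt", int(ev["trial_index"]))
        rt = params.trt_rt_shift_ms + rng.gamma(params.trt_rt_shape,
                                                params.trt_rt_scale_ms)
        hand = "L" if ev["side"] == "left" else "R"
        taps.append((float(ev["onset_ms"]) + rt, hand, "thumb"))

    tap_df = pd.DataFrame(taps, columns=["time_ms", "hand", "finger"])
    tap_df = tap_df.sort_values("time_ms", kind="stable").reset_index(drop=True)
    return tap_df, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Coupled oscillatory sources
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Cross-source phase-coupling ground truth for one source pair.

    The per-trial phase lag is drawn from a von Mises distribution with
    mean ``mean_lag_rad`` and concentration ``kappa`` (kappa = 0 gives
    uniform lags, i.e. no coupling; kappa -> inf a deterministic lag).
    ``post_lag_rad``/``step_time_s`` optionally step the lag at the
    transition to emulate peri-transition coupling modulation. ``snr`` is
    the oscillation-to-noise power ratio.
    """

    band_hz: tuple = (15.0, 22.0)
    mean_lag_rad: float = 0.0
    kappa: float = 8.0
    snr: float = 1.0
    post_lag_rad: float | None = None
    step_time_s: float = 0.0
    kappa_pre: float | None = None  # pre-step concentration; defaults to kappa

    def __post_init__(self):
        if self.kappa < 0 or (self.kappa_pre is not None and self.kappa_pre < 0):
            raise ValueError("kappa must be >= 0")
        if not (2.0 <= self.band_hz[0] < self.band_hz[1] <= 40.0):
            raise ValueError("band must lie within [2, 40] Hz")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec = spec / np.sqrt(freqs)
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _background(rng: np.random.Generator, n: int,
                pink_fraction: float = 0.8) -> np.ndarray:
    """Standard EEG noise surrogate: pink plus white, unit variance."""
    x = (np.sqrt(pink_fraction) * _pink_noise(rng, n)
         + np.sqrt(1 - pink_fraction) * rng.standard_normal(n))
    return x / np.std(x)


def generate_sources(schedule_or_ntrials, coupling: CouplingSpec,
                     fs: float = 250.0, epoch_window_s: tuple = (-2.5, 2.5),
                     seed: int = 0, occ_coupling: CouplingSpec | None = None,
                     ) -> EpochedSourceData:
    """Generate epoched three-source signals (LSM1, RSM1, OCC).

    LSM1 carries a band-limited oscillation; RSM1 carries the same
    oscillation shifted by the per-trial von Mises lag (optionally stepping
    at the transition); OCC is an independent oscillation unless
    ``occ_coupling`` couples it to LSM1. All three ride on 1/f + white
    noise scaled to the requested SNR.
    """
    f_hi = coupling.band_hz[1]
    if fs < 2 * f_hi:
        raise ValueError(f"fs={fs:g} Hz aliases the {f_hi:g} Hz band edge")
    if epoch_window_s[0] > -2.5 + 1e-9 or epoch_window_s[1] < 2.5 - 1e-9:
        raise ValueError("epoch window must cover [-2.5, +2.5] s")

    if isinstance(schedule_or_ntrials, EventSchedule):
        trials = schedule_or_ntrials.transition_trials()
        trial_ids = trials["trial_index"].to_numpy()
        table = trials
    else:
        n = int(schedule_or_ntrials)
        trial_ids = np.arange(n)
        table = pd.DataFrame({"trial_index": trial_ids,
                              "cue_type": "switch",
                              "mode_after": "in_phase"})

    n_samp = int(round((epoch_window_s[1] - epoch_window_s[0]) * fs)) + 1
    time_s = epoch_window_s[0] + np.arange(n_samp) / fs
    f0 = float(np.sqrt(coupling.band_hz[0] * coupling.band_hz[1]))
    amp = np.sqrt(2.0 * coupling.snr)  # unit-variance noise; A^2/2 = snr

    data = np.empty((len(trial_ids), 3, n_samp))
    for i, trial in enumerate(trial_ids):
        rng = keyed_rng(seed, "sources", int(trial))
        phi0 = rng.uniform(0, 2 * np.pi)
        kpre = coupling.kappa if coupling.kappa_pre is None else coupling.kappa_pre
        lag = sample_von_mises(rng, coupling.mean_lag_rad, kpre, None)
        lag_t = np.full(n_samp, float(lag))
        if coupling.post_lag_rad is not None:
            post = sample_von_mises(rng, coupling.post_lag_rad,
                                    coupling.kappa, None)
            lag_t[time_s >= coupling.step_time_s] = post
        phase_l = 2 * np.pi * f0 * time_s + phi0
        osc_l = amp * np.cos(phase_l)
        osc_r = amp * np.cos(phase_l - lag_t)
        if occ_coupling is not None:
            lag_o = sample_von_mises(rng, occ_coupling.mean_lag_rad,
                                     occ_coupling.kappa, None)
            osc_o = amp * np.cos(phase_l - lag_o)
        else:
            phi_o = rng.uniform(0, 2 * np.pi)
            osc_o = amp * np.cos(2 * np.pi * f0 * time_s + phi_o)
        for s, osc in enumerate((osc_l, osc_r, osc_o)):
            data[i, s] = osc + _background(keyed_rng(seed, "noise", int(trial), s),
                                           n_samp)

    return EpochedSourceData(data=data, time_s=time_s, fs=fs,
                             alignment="stimulus",
                             source_labels=SOURCE_LABELS,
                             trial_table=table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Cohort with known moderated-mediation structure
# ---------------------------------------------------------------------------

@dataclass
class MediationCoefficients:
    """Ground-truth path coefficients of the data-generating process.

    Outcome model: Y = i1 + c1*X + c2*W + c3*X*W + b1*M + b2*M*W + e1
    Mediator model: M = i2 + a1*X + a2*W + a3*X*W + e2
    """

    a1: float = 0.5
    a2: float = 0.0
    a3: float = 0.0
    b1: float = -0.4
    b2: float = 0.0
    c1: float = 0.2
    c2: float = 0.0
    c3: float = 0.0
    i1: float = 0.0
    i2: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything needed to regenerate a cohort bit-identically."""

    coefficients: MediationCoefficients
    n_young: int
    n_older: int
    sigma1: float = 0.5
    beta1: float = 0.0  # exponential (exGaussian) tail of the outcome noise
    sigma2: float = 0.5
    beta2: float = 0.0
    gaba_young_mean: float = 3.0
    gaba_older_offset: float = -0.3  # sensorimotor voxels only
    gaba_sd: float = 0.35
    seed: int = 0

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as f:
            json.dump(d, f, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            d = json.load(f)
        d["coefficients"] = MediationCoefficients(**d["coefficients"])
        return cls(**d)


def _exgauss_noise(rng, sigma, beta, size):
    e = sigma * rng.standard_normal(size)
    if beta > 0:
        e = e + rng.exponential(beta, size)
    return e


def generate_cohort(n_young: int, n_older: int,
                    truth: GroundTruth | None = None,
                    seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a subject-level cohort table from known coefficients.

    Columns: subject, group, W (centered group code, young = -0.5,
    older = +0.5), X (connectivity summary, standard normal), M (mediator),
    Y (behavioral outcome) -- generated exactly by the outcome/mediator
    regressions -- plus group-structured GABA+ per voxel and voxel tissue
    fractions for the MRS-preparation stage.
    """
    if n_young < 2 or n_older < 2:
        raise ValueError("need >= 2 subjects per group")
    if truth is None:
        truth = GroundTruth(coefficients=MediationCoefficients(),
                            n_young=n_young, n_older=n_older, seed=seed)
    c = truth.coefficients
    for name, v in c.as_dict().items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite coefficient {name}")

    n = n_young + n_older
    rng = keyed_rng(seed, "cohort")
    group = np.array(["young"] * n_young + ["older"] * n_older)
    w = np.where(group == "young", -0.5, 0.5)
    x = rng.standard_normal(n)
    e2 = _exgauss_noise(rng, truth.sigma2, truth.beta2, n)
    m = c.i2 + c.a1 * x + c.a2 * w + c.a3 * x * w + e2
    e1 = _exgauss_noise(rng, truth.sigma1, truth.beta1, n)
    y = (c.i1 + c.c1 * x + c.c2 * w + c.c3 * x * w
         + c.b1 * m + c.b2 * m * w + e1)

    gaba = {}
    for voxel in ("left_sm1", "right_sm1", "occ"):
        mu = np.full(n, truth.gaba_young_mean)
        if voxel != "occ":
            mu = mu + np.where(group == "older", truth.gaba_older_offset, 0.0)
        gaba[f"gaba_{voxel}"] = mu + truth.gaba_sd * rng.standard_normal(n)

    # voxel tissue fractions (Dirichlet-ish around a sensorimotor mix)
    base = np.array([0.38, 0.47, 0.15])
    frac = rng.dirichlet(base * 120, size=n)
    df = pd.DataFrame({
        "subject": [f"S{i:03d}" for i in range(n)],
        "group": group, "W": w, "X": x, "M": m, "Y": y,
        **gaba,
        "fGM": frac[:, 0], "fWM": frac[:, 1], "fCSF": frac[:, 2],
    })
    return df, truth
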
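"""Behavioral outcome coding for cued motor-state transitions.

A transition trial is scored in the 2000 ms window after the transition
cue. Tap pairs (one left-hand and one right-hand tap close in time) are
classified as in-phase (homologous fingers), anti-phase (index-middle
across hands) or error (thumb press, unsynchronized or unpaired taps).
From the pairs in the window, three outcomes follow:

* error rate -- fraction of pairs not matching the cued mode;
* hurdle code -- failed (100 % errors), fully_correct (0 %), or partial,
  the three-part split used because the bounded error-rate outcome is
  zero-inflated at both ends (failed trials are excluded from all latency
  and partial-error analyses);
* transition latency -- time from cue onset to the first pair matching the
  cued mode (undefined for failed trials).

Thumb reaction times are trimmed with a 100 ms lower cut-off and a
within-group mean + 3 SD upper cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_MS = 2000.0
VALID_FINGERS = {"index", "middle", "thumb"}


@dataclass
class TrialBehavior:
    trial_id: int
    transition_mode: str  # into_IP / into_AP
    latency_ms: float  # nan when failed
    error_fraction: float
    hurdle_code: str  # failed / fully_correct / partial
    n_pairs: int


def classify_tap_pair(tap_l, tap_r, sync_tolerance_ms: float) -> str:
    """Classify one candidate pair of taps.

    ``tap_l``/``tap_r`` are (time_ms, finger) tuples for the left and right
    hand. Thumb presses and pairs outside the synchrony tolerance are
    errors, never exceptions.
    """
    (t_l, f_l), (t_r, f_r) = tap_l, tap_r
    if f_l not in VALID_FINGERS or f_r not in VALID_FINGERS:
        raise ValueError(f"unknown finger in pair: {f_l!r}, {f_r!r}")
    if f_l == "thumb" or f_r == "thumb":
        return "error"
    if abs(t_l - t_r) > sync_tolerance_ms:
        return "error"
    if f_l == f_r:
        return "in_phase"
    return "anti_phase"


def pair_taps(taps: pd.DataFrame, sync_tolerance_ms: float):
    """Greedy nearest-in-time pairing of opposite-hand taps.

    Returns a list of (time_ms, classification) with unpaired taps counted
    as error 'pairs'; pair time is the mean of the two tap times.
    """
    left = taps[taps["hand"] == "L"].sort_values("time_ms")
    right = taps[taps["hand"] == "R"].sort_values("time_ms")
    l_list = list(left[["time_ms", "finger"]].itertuples(index=False, name=None))
    r_list = list(right[["time_ms", "finger"]].itertuples(index=False, name=None))
    pairs = []
    used_r = np.zeros(len(r_list), dtype=bool)
    for t_l, f_l in l_list:
        best, best_dt = None, np.inf
        for j, (t_r, _) in enumerate(r_list):
            if used_r[j]:
                continue
            dt = abs(t_l - t_r)
            if dt < best_dt:
                best, best_dt = j, dt
        if best is not None and best_dt <= sync_tolerance_ms:
            used_r[best] = True
            t_r, f_r = r_list[best]
            cls = classify_tap_pair((t_l, f_l), (t_r, f_r), sync_tolerance_ms)
            pairs.append(((t_l + t_r) / 2.0, cls))
        else:
            pairs.append((t_l, "error"))
    for j, (t_r, _) in enumerate(r_list):
        if not used_r[j]:
            pairs.append((t_r, "error"))
    pairs.sort(key=lambda p: p[0])
    return pairs


def score_transition(taps: pd.DataFrame, cue_time_ms: float, cued_mode: str,
                     trial_id: int = 0, window_ms: float = WINDOW_MS,
                     sync_tolerance_ms: float | None = None,
                     tap_freq_hz: float = 1.6) -> TrialBehavior | None:
    """Score one transition trial.

    ``cued_mode`` is 'in_phase' or 'anti_phase'. The synchrony tolerance
    defaults to 25 % of the inter-tap interval. Returns None (trial flagged
    missing) when no tap pair falls inside the window.
    """
    if cued_mode not in ("in_phase", "anti_phase"):
        raise ValueError(f"unknown cued mode {cued_mode!r}")
    if sync_tolerance_ms is None:
        sync_tolerance_ms = 0.25 * 1000.0 / tap_freq_hz
    in_win = taps[(taps["time_ms"] >= cue_time_ms)
                  & (taps["time_ms"] < cue_time_ms + window_ms)]
    pairs = pair_taps(in_win, sync_tolerance_ms)
    if not pairs:
        return None
    n_err = sum(1 for _, cls in pairs if cls != cued_mode)
    error_fraction = n_err / len(pairs)
    latency = np.nan
    for t, cls in pairs:
        if cls == cued_mode:
            latency = t - cue_time_ms
            break
    if error_fraction == 1.0:
        code = "failed"
    elif error_fraction == 0.0:
        code = "fully_correct"
    else:
        code = "partial"
    mode_label = "into_IP" if cued_mode == "in_phase" else "into_AP"
    return TrialBehavior(trial_id=trial_id, transition_mode=mode_label,
                         latency_ms=latency, error_fraction=error_fraction,
                         hurdle_code=code, n_pairs=len(pairs))


def score_trials(taps: pd.DataFrame, trials: pd.DataFrame,
                 **kwargs) -> pd.DataFrame:
    """Score every transition cue in ``trials`` (cue_onset_ms, mode_after).

    The trial-number covariate ``n_trial_centered`` is added for the
    regression stages.
    """
    rows = []
    for _, tr in trials.iterrows():
        tb = score_transition(taps, float(tr["cue_onset_ms"]),
                              tr["mode_after"],
                              trial_id=int(tr["trial_index"]), **kwargs)
        if tb is None:
            continue
        rows.append(vars(tb))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["n_trial_centered"] = df["trial_id"] - df["trial_id"].mean()
    return df


def split_hurdle(scored: pd.DataFrame):
    """Partition scored trials into (failed, fully_correct, partial).

    The three sets are disjoint and exhaustive; failed trials must be
    removed before any latency or cumulative-error analysis. Partial error
    fractions already lie in the open interval (0, 1), the support of the
    beta family used for them downstream.
    """
    failed = scored[scored["hurdle_code"] == "failed"]
    correct = scored[scored["hurdle_code"] == "fully_correct"]
    partial = scored[scored["hurdle_code"] == "partial"]
    return failed, correct, partial


def trim_trt(rts_ms, lower_ms: float = 100.0, sd_mult: float = 3.0):
    """Trim thumb reaction times of one group.

    Removes rt < ``lower_ms`` first, then rt above the group
    mean + ``sd_mult`` * SD computed on the lower-trimmed values (values
    exactly at the cut-off survive, so a zero-SD group passes unchanged).
    """
    rts = np.asarray(rts_ms, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT list")
    kept = rts[rts >= lower_ms]
    if kept.size == 0:
        import warnings
        warnings.warn("all RTs below the lower cut-off", stacklevel=2)
        return kept
    hi = kept.mean() + sd_mult * kept.std(ddof=1 if kept.size > 1 else 0)
    out = kept[kept <= hi]
    if out.size == 0:
        import warnings
        warnings.warn("trimming removed every RT", stacklevel=2)
    return out


def trim_trt_by_group(rts_ms, groups):
    """Apply trim_trt within each group; returns (trimmed_rts, groups)."""
    rts = np.asarray(rts_ms, dtype=float)
    groups = np.asarray(groups)
    out_r, out_g = [], []
    for g in pd.unique(groups):
        t = trim_trt(rts[groups == g])
        out_r.append(t)
        out_g.append(np.full(t.size, g))
    return np.concatenate(out_r), np.concatenate(out_g)
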
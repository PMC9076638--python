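"""End-to-end orchestration: simulate -> behavior -> spectral -> ISPC ->
cluster statistics -> circular statistics -> mediation.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
a master seed; identical config + seed reproduces every result table
byte-for-byte. The output bundle is

    <out>/config.yaml          archived configuration (with its hash)
    <out>/data/                cohort/behavior tables, example epochs (HDF5)
    <out>/results/             TSV/JSON result tables, z maps (HDF5)
    <out>/logs/run.log         stage log

Every result table embeds the config hash in a leading comment line.
Completed stages are skipped on rerun when their recorded config hash
matches (content-hash gating); any stage failure aborts the run with the
stage and subject context in the exception.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import circstats as cst
from . import clusterstats as cls
from . import connectivity as con
from . import gabaprep
from . import mediation as med
from . import spectral as spc
from . import synthetic as syn

log = logging.getLogger("phaselink")

STAGES = ("simulate", "behavior", "connectivity", "clusters",
          "circstats", "mediation")


@dataclass
class RunConfig:
    """All stage parameters; defaults follow the analysis conventions
    (250 Hz sampling, 50 Hz ISPC grid, 2-40 Hz / 50-step wavelet bank,
    -500..-200 ms baseline, +/-260 ms response window, 0.05 alpha,
    15-22 / 25-30 Hz bands, 89 % HDI), with problem sizes set to the
    packaged demo scale."""

    seed: int = 0
    stages: tuple = STAGES
    # cohort / paradigm
    n_young: int = 12
    n_older: int = 12
    n_trials: int = 60
    p_trt: float = 0.05
    switch_ratio: float = 5.0
    # signals
    fs: float = 250.0
    epoch_window_s: tuple = (-2.5, 2.5)
    coupling_band_hz: tuple = (15.0, 22.0)
    coupling_kappa_young: float = 4.0
    coupling_kappa_older: float = 1.0
    coupling_snr: float = 1.0
    # spectral / ISPC
    bank_fmin: float = 2.0
    bank_fmax: float = 40.0
    bank_n: int = 50
    fwhm_start_ms: float = 400.0
    fwhm_end_ms: float = 104.0
    ispc_fmin: float = 5.0
    downsample_step: int = 5
    toi_s: tuple = (0.0, 2.0)
    baseline_s: tuple = (-0.5, -0.2)
    response_half_window_s: float = 0.26
    # statistics
    n_perm_within: int = 100
    n_perm_group: int = 500
    alpha: float = 0.05
    bands: tuple = (("low_beta", (15.0, 22.0)), ("high_beta", (25.0, 30.0)))
    # mediation (demo scale; analysis-scale default is 4 x 10000 / 1000)
    med_chains: int = 4
    med_iterations: int = 800
    med_burn_in: int = 200

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump({"config_hash": self.hash(), **asdict(self)}, f,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        d.pop("config_hash", None)
        for key in ("stages", "epoch_window_s", "coupling_band_hz", "toi_s",
                    "baseline_s", "bands"):
            if key in d and isinstance(d[key], list):
                d[key] = _tuplify(d[key])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _tuplify(x):
    if isinstance(x, list):
        return tuple(_tuplify(v) for v in x)
    return x


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash: {cfg_hash}\n")
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", mode="a")


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / "logs" / f".stage_{stage}.json"
    if marker.exists():
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    return False


def _mark_stage(out: Path, stage: str, cfg_hash: str) -> None:
    marker = out / "logs" / f".stage_{stage}.json"
    marker.write_text(json.dumps({"stage": stage, "config_hash": cfg_hash}))


def run(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages into ``out_dir``; returns the path."""
    out = Path(out_dir)
    for sub in ("data", "results", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "logs" / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    # requested stages plus their transitive prerequisites
    wanted = set(config.stages)
    changed = True
    while changed:
        changed = False
        for s in list(wanted):
            for dep in _STAGE_DEPS[s]:
                if dep not in wanted:
                    wanted.add(dep)
                    changed = True
    state = {}
    try:
        for stage in STAGES:
            if stage not in wanted:
                continue
            if stage == "simulate" and _stage_done(out, stage, cfg_hash):
                # content-hash gate: reload instead of regenerating
                state["cohort"] = pd.read_csv(out / "data" / "cohort.tsv",
                                              sep="\t", comment="#")
                log.info("stage %s already complete, skipping", stage)
                continue
            log.info("stage %s start", stage)
            try:
                _STAGE_FUNCS[stage](config, out, cfg_hash, state)
            except Exception as e:  # abort loudly with stage context
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            _mark_stage(out, stage, cfg_hash)
            log.info("stage %s done", stage)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _subject_list(config):
    n = config.n_young + config.n_older
    return [f"S{i:03d}" for i in range(n)]


def _stage_simulate(config, out, cfg_hash, state):
    cohort, truth = syn.generate_cohort(config.n_young, config.n_older,
                                        seed=config.seed)
    truth.to_json(out / "data" / "ground_truth.json")
    prepared = gabaprep.prepare_cohort(cohort)
    _write_table(prepared, out / "data" / "cohort.tsv", cfg_hash)
    state["cohort"] = prepared


def _stage_behavior(config, out, cfg_hash, state):
    rows = []
    for si, subject in enumerate(_subject_list(config)):
        sched = syn.generate_schedule(config.n_trials, config.p_trt,
                                      config.switch_ratio,
                                      seed=config.seed * 10007 + si)
        taps, truth = syn.generate_tap_stream(sched, syn.TapParams(),
                                              seed=config.seed * 10007 + si)
        scored = bhv.score_trials(taps, truth)
        scored.insert(0, "subject", subject)
        rows.append(scored)
        state.setdefault("schedules", {})[subject] = sched
        state.setdefault("trial_truth", {})[subject] = truth
    beh = pd.concat(rows, ignore_index=True)
    _write_table(beh, out / "data" / "behavior.tsv", cfg_hash)
    state["behavior"] = beh


def _subject_group(config, si):
    return "young" if si < config.n_young else "older"


def _stage_connectivity(config, out, cfg_hash, state):
    bank = spc.design_bank(config.bank_fmin, config.bank_fmax, config.bank_n,
                           config.fwhm_start_ms, config.fwhm_end_ms,
                           fs=config.fs)
    keep = bank.center_freqs_hz >= config.ispc_fmin
    beh = state["behavior"]
    z_maps, phase_rows = {}, []
    for si, subject in enumerate(_subject_list(config)):
        group = _subject_group(config, si)
        kappa = (config.coupling_kappa_young if group == "young"
                 else config.coupling_kappa_older)
        spec = syn.CouplingSpec(band_hz=config.coupling_band_hz,
                                mean_lag_rad=0.0, kappa=kappa,
                                snr=config.coupling_snr,
                                post_lag_rad=np.pi / 2, step_time_s=0.3)
        sched = state["schedules"][subject]
        epochs = syn.generate_sources(sched, spec, fs=config.fs,
                                      epoch_window_s=config.epoch_window_s,
                                      seed=config.seed * 20011 + si)
        if si == 0:
            epochs.to_hdf5(out / "data" / "example_epochs.h5")
        phases = {}
        for src in ("LSM1", "RSM1"):
            tf = spc.decompose(epochs.data[:, epochs.source_index(src)], bank,
                               time_s=epochs.time_s)
            phases[src] = tf.phase[:, keep, :]
        freqs = bank.center_freqs_hz[keep]
        time_s = epochs.time_s
        dphi = phases["LSM1"] - phases["RSM1"]
        toi_sel = (time_s >= config.toi_s[0]) & (time_s <= config.toi_s[1])
        base_sel = ((time_s >= config.baseline_s[0])
                    & (time_s <= config.baseline_s[1]))
        sb = beh[beh["subject"] == subject].set_index("trial_id")
        trial_ids = epochs.trial_table["trial_index"].to_numpy()
        modes = np.array([sb["transition_mode"].get(t, "") for t in trial_ids])
        for mode in ("into_IP", "into_AP"):
            sel = modes == mode
            if sel.sum() < 2:
                raise ValueError(f"subject {subject}: too few {mode} trials")
            step = config.downsample_step
            z = cls.within_subject_z(dphi[sel][:, :, toi_sel][:, :, ::step],
                                     dphi[sel][:, :, base_sel][:, :, ::step],
                                     n_perm=config.n_perm_within,
                                     seed=config.seed * 30013 + si)
            z_maps.setdefault(subject, {})[mode] = z
        # single-trial band-pooled phase lags at the time of transition
        for ti, trial in enumerate(trial_ids):
            if trial not in sb.index:
                continue
            lat = sb.loc[trial, "latency_ms"]
            if not np.isfinite(lat):
                continue
            for band_name, band in config.bands:
                lag = con.extract_phase_lag(
                    phases["LSM1"][ti], phases["RSM1"][ti], freqs, time_s,
                    band, lat / 1000.0)
                phase_rows.append(vars(con.PhaseTrial(
                    trial_id=int(trial), band=band_name, lag_rad=lag,
                    alignment_time_ms=float(lat),
                    subsequent_error=float(sb.loc[trial, "error_fraction"]),
                    subject=subject, group=group,
                    transition_mode=sb.loc[trial, "transition_mode"])))
    state["z_maps"] = z_maps
    state["freqs"] = freqs
    toi_t = time_s[toi_sel][::config.downsample_step]
    state["toi_time_s"] = toi_t
    phase_df = pd.DataFrame(phase_rows)
    _write_table(phase_df, out / "results" / "phase_trials.tsv", cfg_hash)
    state["phase_trials"] = phase_df


def _stage_clusters(config, out, cfg_hash, state):
    groups = {s: _subject_group(config, si)
              for si, s in enumerate(_subject_list(config))}
    cmaps = cls.contrast_maps(state["z_maps"], groups)
    freqs, times = state["freqs"], state["toi_time_s"]
    results = {
        "pooled_vs_zero": cls.cluster_permutation(
            cmaps["pooled"], "one-sample", n_perm=config.n_perm_group,
            alpha=config.alpha, seed=config.seed,
            freqs_hz=freqs, time_s=times),
        "group_contrast": cls.cluster_permutation(
            cmaps["pooled"], "between-group", groups=cmaps["labels"],
            n_perm=config.n_perm_group, alpha=config.alpha, seed=config.seed,
            freqs_hz=freqs, time_s=times),
        "mode_contrast": cls.cluster_permutation(
            cmaps["mode_diff"], "one-sample", n_perm=config.n_perm_group,
            alpha=config.alpha, seed=config.seed,
            freqs_hz=freqs, time_s=times),
        "interaction": cls.cluster_permutation(
            cmaps["mode_diff"], "between-group", groups=cmaps["labels"],
            n_perm=config.n_perm_group, alpha=config.alpha, seed=config.seed,
            freqs_hz=freqs, time_s=times),
    }
    for name, res in results.items():
        res.to_json(out / "results" / f"clusters_{name}.json")
    import h5py
    with h5py.File(out / "results" / "z_maps.h5", "w") as f:
        f.create_dataset("mode_diff", data=cmaps["mode_diff"],
                         track_times=False)
        f.create_dataset("pooled", data=cmaps["pooled"], track_times=False)
        f.create_dataset("freqs_hz", data=freqs, track_times=False)
        f.create_dataset("time_s", data=times, track_times=False)
        f.attrs["subjects"] = list(cmaps["subjects"])
        f.attrs["config_hash"] = cfg_hash
    state["clusters"] = results


def _stage_circstats(config, out, cfg_hash, state):
    pt = state["phase_trials"]
    cohort = state["cohort"]
    gaba = cohort.set_index("subject")["gaba_right_sm1_norm"]
    grp = cohort.set_index("subject")["group"]
    gl = pd.Series(cst.dichotomize_gaba(gaba.to_numpy(), grp.to_numpy()),
                   index=gaba.index)
    rows = []
    for (band, group), sub in pt.groupby(["band", "group"]):
        z, p = cst.rayleigh(sub["lag_rad"].to_numpy())
        rows.append({"test": "rayleigh", "subgroup": group, "band": band,
                     "statistic": z, "p_raw": p})
        if sub["subsequent_error"].std() > 0:
            r, p = cst.circ_linear_corr(sub["lag_rad"].to_numpy(),
                                        sub["subsequent_error"].to_numpy())
            rows.append({"test": "circ_linear_corr", "subgroup": group,
                         "band": band, "statistic": r, "p_raw": p})
    for band, sub in pt.groupby("band"):
        tab = cst.circ_anova2(sub["lag_rad"].to_numpy(),
                              sub["group"].to_numpy(),
                              gl.loc[sub["subject"]].to_numpy())
        for _, r in tab.iterrows():
            rows.append({"test": f"circ_anova2_{r['effect']}",
                         "subgroup": "all", "band": band,
                         "statistic": r["statistic"], "p_raw": r["p"]})
    res = pd.DataFrame(rows)
    res["p_fdr"] = cst.fdr(res["p_raw"].to_numpy())
    _write_table(res, out / "results" / "circstats.tsv", cfg_hash)
    state["circ_results"] = res


def _stage_mediation(config, out, cfg_hash, state):
    cohort = state["cohort"].copy()
    for c in ("X", "W", "M"):
        cohort[c] = cohort[c] - cohort[c].mean()
    spec = med.MediationModelSpec(chains=config.med_chains,
                                  iterations=config.med_iterations,
                                  burn_in=config.med_burn_in)
    post = med.fit(spec, cohort, seed=config.seed)
    summary = med.summarize(post)
    cond = med.conditional_effects(post)
    extra = []
    for key in ("indirect_low_w", "indirect_high_w"):
        d = cond[key]
        lo, hi = med.hdi(d)
        pdv = med.pd_direction(d)
        extra.append({"coefficient": key, "mean": d.mean(),
                      "median": np.median(d), "hdi89_lo": lo, "hdi89_hi": hi,
                      "pd": pdv, "p_equiv": med.pd_to_p(pdv),
                      "rhat": np.nan, "ess": np.nan})
    summary = pd.concat([summary, pd.DataFrame(extra)], ignore_index=True)
    _write_table(summary, out / "results" / "mediation.tsv", cfg_hash)
    state["mediation"] = summary


_STAGE_DEPS = {
    "simulate": (),
    "behavior": (),
    "connectivity": ("behavior",),
    "clusters": ("connectivity",),
    "circstats": ("connectivity", "simulate"),
    "mediation": ("simulate",),
}

_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "behavior": _stage_behavior,
    "connectivity": _stage_connectivity,
    "clusters": _stage_clusters,
    "circstats": _stage_circstats,
    "mediation": _stage_mediation,
}
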
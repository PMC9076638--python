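"""Tests of the ground-truth generators: paradigm schedule, tap streams,
coupled oscillatory sources and mediation cohorts."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phaselink import behavior as bhv
from phaselink import synthetic as syn
from phaselink._utils import circ_mean_resultant


class TestSchedule:
    def test_invariants_hold(self, small_schedule):
        small_schedule.validate()  # raises on violation
        ev = small_schedule.events
        assert set(ev["event_type"]) <= {"start", "continue", "switch",
                                         "pause", "tRT"}

    def test_zero_trt_probability_yields_no_probes(self):
        sched = syn.generate_schedule(300, p_trt=0.0, seed=2)
        assert "tRT" not in sched.counts()

    def test_trt_fraction_matches_probability(self):
        # ~10000 cue slots
        sched = syn.generate_schedule(5000, p_trt=0.05, seed=3)
        ev = sched.events
        cues = ev[ev["event_type"] != "pause"]
        frac = (cues["event_type"] == "tRT").mean()
        n = len(cues)
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * se

    def test_switch_continue_ratio(self):
        sched = syn.generate_schedule(10_000, seed=4)
        c = sched.counts()
        ratio = c["switch"] / c["continue"]
        # delta-method SE of the count ratio at p = 5/6
        n = c["switch"] + c["continue"]
        se = 5.0 * np.sqrt(1 / (n * 5 / 6) + 1 / (n * 1 / 6))
        assert abs(ratio - 5.0) < 3 * se

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_schedule(0)
        with pytest.raises(ValueError):
            syn.generate_schedule(10, p_trt=1.0)

    def test_regeneration_is_bit_identical(self):
        a = syn.generate_schedule(100, seed=9).events
        b = syn.generate_schedule(100, seed=9).events
        pd.testing.assert_frame_equal(a, b)


class TestTapStream:
    def test_fixed_latency_round_trips(self, small_schedule, clean_taps):
        taps, truth = clean_taps
        scored = bhv.score_trials(taps, truth)
        sw = scored.merge(truth, left_on="trial_id", right_on="trial_index")
        sw = sw[sw["cue_type"] == "switch"]
        assert np.allclose(sw["latency_ms"], 500.0)

    def test_always_wrong_scores_failed(self, small_schedule):
        params = syn.TapParams(always_wrong=True, tap_jitter_ms=0.0)
        taps, truth = syn.generate_tap_stream(small_schedule, params, seed=1)
        scored = bhv.score_trials(taps, truth)
        assert (scored["hurdle_code"] == "failed").all()
        assert scored["latency_ms"].isna().all()

    def test_gamma_latency_median_recovered(self):
        sched = syn.generate_schedule(260, seed=21)
        params = syn.TapParams(latency_shape=9.0, latency_scale_ms=60.0,
                               tap_jitter_ms=0.0)
        taps, truth = syn.generate_tap_stream(sched, params, seed=21)
        scored = bhv.score_trials(taps, truth)
        sw = scored.merge(truth, left_on="trial_id", right_on="trial_index")
        sw = sw[sw["cue_type"] == "switch"].dropna(subset=["latency_ms"])
        assert len(sw) >= 150
        # Monte-Carlo oracle for the gamma median and the SE of a sample
        # median at this n
        rng = np.random.default_rng(0)
        sims = rng.gamma(9.0, 60.0, size=(2000, len(sw)))
        med_dist = np.median(sims, axis=1)
        assert (abs(np.median(sw["latency_ms"]) - np.median(med_dist))
                < 3 * med_dist.std())

    def test_empty_schedule_rejected(self):
        empty = syn.EventSchedule(events=pd.DataFrame(
            columns=["event_type", "onset_ms", "side", "trial_index",
                     "mode_after"]), session_length_ms=0.0)
        with pytest.raises(ValueError):
            syn.generate_tap_stream(empty, syn.TapParams(), seed=0)


class TestSources:
    def test_deterministic_zero_lag_gives_full_locking(self):
        spec = syn.CouplingSpec(kappa=1e6, mean_lag_rad=0.0, snr=50.0)
        ep = syn.generate_sources(20, spec, seed=5)
        from phaselink import connectivity as con
        from phaselink import spectral as spc
        bank = spc.design_bank()
        tfa = spc.decompose(ep.data[:, 0], bank, time_s=ep.time_s)
        tfb = spc.decompose(ep.data[:, 1], bank, time_s=ep.time_s)
        m = con.ispc(tfa.phase, tfb.phase, freqs_hz=bank.center_freqs_hz,
                     time_s=ep.time_s)
        band = (m.freqs_hz >= 15) & (m.freqs_hz <= 22)
        mid = (m.time_s > -1.0) & (m.time_s < 1.0)
        assert m.values[np.ix_(band, mid)].mean() > 0.98

    def test_mean_lag_round_trips(self):
        spec = syn.CouplingSpec(mean_lag_rad=np.pi, kappa=60.0, snr=3.0)
        ep = syn.generate_sources(40, spec, seed=6)
        from phaselink import connectivity as con
        from phaselink import spectral as spc
        bank = spc.design_bank()
        lags = []
        for i in range(ep.n_trials):
            tfa = spc.decompose(ep.data[i:i + 1, 0], bank, time_s=ep.time_s)
            tfb = spc.decompose(ep.data[i:i + 1, 1], bank, time_s=ep.time_s)
            lags.append(con.extract_phase_lag(
                tfa.phase[0], tfb.phase[0], bank.center_freqs_hz,
                ep.time_s, (15, 22), 0.0))
        mu, r = circ_mean_resultant(lags)
        assert r > 0.8
        assert abs(abs(mu) - np.pi) < 0.2  # 180 deg

    def test_lag_distribution_converges_to_spec(self):
        # empirical von Mises concentration at n=500 within 3 SE
        spec = syn.CouplingSpec(mean_lag_rad=0.5, kappa=4.0, snr=1e6)
        ep = syn.generate_sources(500, spec, seed=8)
        from phaselink import spectral as spc
        bank = spc.design_bank()
        tfa = spc.decompose(ep.data[:, 0], bank, time_s=ep.time_s)
        tfb = spc.decompose(ep.data[:, 1], bank, time_s=ep.time_s)
        fi = np.argmin(abs(bank.center_freqs_hz
                           - np.sqrt(15 * 22)))
        ti = np.argmin(abs(ep.time_s))
        lags = tfa.phase[:, fi, ti] - tfb.phase[:, fi, ti]
        mu, rbar = circ_mean_resultant(lags)
        # oracle: distribution of the circular mean for vM(0.5, 4), n=500
        rng = np.random.default_rng(1)
        sims = rng.vonmises(0.5, 4.0, size=(1000, 500))
        mus = np.angle(np.exp(1j * sims).mean(axis=1))
        assert abs(mu - 0.5) < 3 * mus.std()

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_sources(5, syn.CouplingSpec(band_hz=(25, 30)),
                                 fs=50.0)

    def test_occipital_source_uncoupled(self):
        spec = syn.CouplingSpec(kappa=100.0, snr=5.0)
        ep = syn.generate_sources(60, spec, seed=9)
        from phaselink import connectivity as con
        from phaselink import spectral as spc
        bank = spc.design_bank()
        tfa = spc.decompose(ep.data[:, 0], bank, time_s=ep.time_s)
        tfo = spc.decompose(ep.data[:, 2], bank, time_s=ep.time_s)
        m = con.ispc(tfa.phase, tfo.phase, freqs_hz=bank.center_freqs_hz,
                     time_s=ep.time_s)
        band = (m.freqs_hz >= 15) & (m.freqs_hz <= 22)
        assert m.values[band].mean() < 0.3


class TestCohort:
    def test_zero_noise_reproduces_linear_predictors(self):
        truth = syn.GroundTruth(
            coefficients=syn.MediationCoefficients(a1=0.5, a2=0.1, a3=-0.2,
                                                   b1=-0.4, b2=0.3, c1=0.2,
                                                   c2=0.1, c3=0.05, i1=1.0,
                                                   i2=-0.5),
            n_young=30, n_older=30, sigma1=0.0, beta1=0.0,
            sigma2=0.0, beta2=0.0, seed=3)
        df, _ = syn.generate_cohort(30, 30, truth, seed=3)
        c = truth.coefficients
        m_pred = c.i2 + c.a1 * df.X + c.a2 * df.W + c.a3 * df.X * df.W
        y_pred = (c.i1 + c.c1 * df.X + c.c2 * df.W + c.c3 * df.X * df.W
                  + c.b1 * df.M + c.b2 * df.M * df.W)
        np.testing.assert_allclose(df.M, m_pred, atol=1e-12)
        np.testing.assert_allclose(df.Y, y_pred, atol=1e-12)

    def test_group_gaba_offset_voxel_specific(self):
        truth = syn.GroundTruth(coefficients=syn.MediationCoefficients(),
                                n_young=100, n_older=100,
                                gaba_older_offset=-0.6, seed=4)
        df, _ = syn.generate_cohort(100, 100, truth, seed=4)
        y, o = df[df.group == "young"], df[df.group == "older"]
        p_sm = stats.ttest_ind(y.gaba_left_sm1, o.gaba_left_sm1).pvalue
        p_occ = stats.ttest_ind(y.gaba_occ, o.gaba_occ).pvalue
        assert p_sm < 0.001
        assert p_occ > 0.05

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, truth = syn.generate_cohort(5, 5, seed=12)
        truth.to_json(tmp_path / "gt.json")
        back = syn.GroundTruth.from_json(tmp_path / "gt.json")
        assert back == truth
        # regeneration from the serialized truth is bit-identical
        df1, _ = syn.generate_cohort(5, 5, truth, seed=truth.seed)
        df2, _ = syn.generate_cohort(5, 5, back, seed=back.seed)
        pd.testing.assert_frame_equal(df1, df2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_cohort(1, 5)
        bad = syn.GroundTruth(
            coefficients=syn.MediationCoefficients(a1=np.nan),
            n_young=5, n_older=5)
        with pytest.raises(ValueError):
            syn.generate_cohort(5, 5, bad)
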
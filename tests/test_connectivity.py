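"""ISPC identities, baseline correction, response-locking, phase-lag
extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phaselink import connectivity as con
from phaselink import synthetic as syn
from phaselink.containers import EpochedSourceData


def uniform_phases(seed, shape):
    return np.random.default_rng(seed).uniform(-np.pi, np.pi, shape)


class TestIspc:
    def test_identical_phases_give_one(self):
        p = uniform_phases(0, (10, 3, 40))
        m = con.ispc(p, p, downsample_step=1)
        np.testing.assert_allclose(m.values, 1.0)

    def test_constant_lag_gives_one(self):
        p = uniform_phases(1, (10, 3, 40))
        m = con.ispc(p, p - np.pi, downsample_step=1)
        np.testing.assert_allclose(m.values, 1.0)

    def test_canceling_lags_give_zero(self):
        p = uniform_phases(2, (4, 2, 20))
        lags = np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        m = con.ispc(p, p - lags[:, None, None], downsample_step=1)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_uniform_lags_expectation(self):
        # E[resultant length] ~ sqrt(pi)/(2 sqrt(n)) for uniform lags
        vals = []
        for r in range(300):
            a = uniform_phases(2 * r, (100, 1, 5))
            b = uniform_phases(2 * r + 1, (100, 1, 5))
            vals.append(con.ispc(a, b, downsample_step=1).values.mean())
        expect = np.sqrt(np.pi) / (2 * np.sqrt(100))
        assert np.mean(vals) == pytest.approx(expect, rel=0.05)

    def test_symmetry_and_lag_invariance(self):
        a = uniform_phases(5, (8, 2, 30))
        b = uniform_phases(6, (8, 2, 30))
        m_ab = con.ispc(a, b, downsample_step=1).values
        m_ba = con.ispc(b, a, downsample_step=1).values
        np.testing.assert_allclose(m_ab, m_ba)
        m_shift = con.ispc(a + 1.234, b, downsample_step=1).values
        np.testing.assert_allclose(m_ab, m_shift, atol=1e-12)

    def test_monotone_in_von_mises_concentration(self):
        means = []
        for kappa in (0.0, 1.0, 4.0, 16.0):
            rng = np.random.default_rng(int(kappa * 10) + 7)
            a = rng.uniform(-np.pi, np.pi, (200, 1, 10))
            lag = (rng.vonmises(0.3, kappa, (200, 1, 1)) if kappa > 0
                   else rng.uniform(-np.pi, np.pi, (200, 1, 1)))
            means.append(con.ispc(a, a - lag, downsample_step=1).values.mean())
        assert np.all(np.diff(means) > 0)

    def test_single_trial_rejected(self):
        p = uniform_phases(0, (1, 2, 10))
        with pytest.raises(ValueError):
            con.ispc(p, p)

    def test_downsampling_to_50hz_grid(self):
        p = uniform_phases(3, (5, 2, 250))
        t = np.arange(250) / 250.0
        m = con.ispc(p, p, time_s=t)
        assert m.values.shape[1] == 50
        assert np.allclose(np.diff(m.time_s), 1 / 50.0)

    def test_over_time_variant_full_epoch(self):
        # constant lag within a trial -> over-time ISPC 1 per trial
        t = np.linspace(0, 1, 100)
        a = np.tile(2 * np.pi * 10 * t, (3, 1, 1))
        b = a - 0.7
        out = con.ispc_over_time(a, b)
        np.testing.assert_allclose(out, 1.0)


class TestBaselineSubtract:
    def _map(self, values, times):
        return con.ISPCMap(values=values, freqs_hz=np.arange(values.shape[0],
                                                             dtype=float),
                           time_s=times)

    def test_self_baseline_is_zero(self):
        t = np.linspace(-0.6, 2.0, 60)
        m = self._map(np.full((4, 60), 0.37), t)
        out = con.baseline_subtract(m)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)
        assert out.variant == "baseline_subtracted"

    def test_known_difference(self):
        t = np.linspace(-0.6, 2.0, 60)
        vals = np.full((2, 60), 0.2)
        vals[1, -1] = 0.5
        out = con.baseline_subtract(self._map(vals, t))
        assert out.values[1, -1] == pytest.approx(0.3)

    def test_axis_mismatch_rejected(self):
        t = np.linspace(-0.6, 2.0, 60)
        m = self._map(np.zeros((3, 60)), t)
        other = con.ISPCMap(values=np.zeros((4, 60)),
                            freqs_hz=np.arange(4.0), time_s=t)
        with pytest.raises(ValueError):
            con.baseline_subtract(m, other.__class__(
                values=np.zeros((2, 60)), freqs_hz=np.arange(2.0), time_s=t))

    def test_step_coupling_positive_after_onset(self):
        # generator plants a coupling step at t=0; baseline-corrected ISPC
        # should rise only post-onset
        spec = syn.CouplingSpec(kappa=40.0, kappa_pre=0.0, snr=5.0,
                                post_lag_rad=0.0, step_time_s=0.0)
        ep = syn.generate_sources(60, spec, seed=13)
        from phaselink import spectral as spc
        bank = spc.design_bank()
        tfa = spc.decompose(ep.data[:, 0], bank, time_s=ep.time_s)
        tfb = spc.decompose(ep.data[:, 1], bank, time_s=ep.time_s)
        m = con.ispc(tfa.phase, tfb.phase, freqs_hz=bank.center_freqs_hz,
                     time_s=ep.time_s)
        out = con.baseline_subtract(m)
        band = (m.freqs_hz >= 15) & (m.freqs_hz <= 22)
        pre = out.values[np.ix_(band, (out.time_s > -1.5) & (out.time_s < -0.5))]
        post = out.values[np.ix_(band, (out.time_s > 0.5) & (out.time_s < 1.5))]
        assert post.mean() > pre.mean() + 0.3


class TestResponseLock:
    def _epochs(self, n=6):
        fs = 250.0
        t = np.arange(-2.5, 2.5 + 1e-9, 1 / fs)
        data = np.tile(t, (n, 3, 1))  # each sample holds its own time
        table = pd.DataFrame({"trial_index": np.arange(n),
                              "cue_type": "switch",
                              "mode_after": ["in_phase", "anti_phase"] * (n // 2)})
        return EpochedSourceData(data=data, time_s=t, fs=fs,
                                 trial_table=table)

    def _latencies(self, vals, modes):
        return pd.DataFrame({"trial_index": np.arange(len(vals)),
                             "transition_mode": modes,
                             "latency_ms": vals})

    def test_uniform_latency_is_uniform_shift(self):
        ep = self._epochs()
        lat = self._latencies([500.0] * 6, ["into_IP"] * 6)
        out = con.response_lock(ep, lat)
        assert out.alignment == "response"
        # data values carry original time: window center must sit at 0.5 s
        center = out.data[0, 0, out.data.shape[2] // 2]
        assert center == pytest.approx(0.5, abs=1 / 250)
        assert out.time_s[0] == pytest.approx(-0.26)

    def test_even_count_median_is_midpoint(self):
        ep = self._epochs(4)
        lat = self._latencies([400.0, 600.0, 400.0, 600.0], ["into_IP"] * 4)
        out = con.response_lock(ep, lat)
        center = out.data[0, 0, out.data.shape[2] // 2]
        assert center == pytest.approx(0.5, abs=1 / 250)

    def test_condition_specific_alignment(self):
        ep = self._epochs(6)
        modes = ["into_IP", "into_AP"] * 3
        lat = self._latencies([400, 800, 400, 800, 400, 800], modes)
        out = con.response_lock(ep, lat)
        c_ip = out.data[0, 0, out.data.shape[2] // 2]
        c_ap = out.data[1, 0, out.data.shape[2] // 2]
        assert c_ap - c_ip == pytest.approx(0.4, abs=2 / 250)

    def test_failed_trials_and_out_of_bounds_dropped(self):
        ep = self._epochs(4)
        lat = self._latencies([500.0, np.nan, 500.0, 2400.0],
                              ["into_IP", "into_IP", "into_IP", "into_AP"])
        out = con.response_lock(ep, lat)
        # nan-latency trial dropped; 2400 ms window [2.14, 2.66] exceeds epoch
        assert out.n_trials == 2


class TestExtractPhaseLag:
    def test_single_bin_band(self):
        freqs = np.array([10.0, 20.0, 30.0])
        t = np.array([0.0, 0.1])
        pa = np.zeros((3, 2))
        pb = np.array([[0.3, 0.3], [1.0, 1.0], [2.0, 2.0]])
        lag = con.extract_phase_lag(pa, pb, freqs, t, (18, 22), 0.0)
        assert lag == pytest.approx(-1.0)

    def test_identical_bins_return_theta(self):
        freqs = np.array([16.0, 18.0, 20.0])
        pa = np.full((3, 1), 0.9)
        pb = np.zeros((3, 1))
        lag = con.extract_phase_lag(pa, pb, freqs, np.array([0.0]), (15, 22), 0.0)
        assert lag == pytest.approx(0.9)

    def test_circular_pooling_of_wrapped_bins(self):
        # bins at +170 and -170 deg pool to 180, not 0
        freqs = np.array([16.0, 20.0])
        pa = np.array([[np.deg2rad(170)], [np.deg2rad(-170)]])
        pb = np.zeros((2, 1))
        lag = con.extract_phase_lag(pa, pb, freqs, np.array([0.0]), (15, 22), 0.0)
        assert abs(lag) == pytest.approx(np.pi, abs=1e-9)

    def test_masked_edge_rejected(self):
        freqs = np.array([16.0])
        mask = np.array([[True, False]])
        with pytest.raises(ValueError):
            con.extract_phase_lag(np.zeros((1, 2)), np.zeros((1, 2)), freqs,
                                  np.array([0.0, 0.1]), (15, 22), 0.0,
                                  edge_mask=mask)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            con.band_indices(np.array([10.0, 12.0]), (15, 22))

    @given(st.floats(-np.pi, np.pi))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_global_rotation_shifts_lag(self, rot):
        freqs = np.array([16.0, 18.0, 20.0])
        rng = np.random.default_rng(4)
        pa = rng.uniform(-0.5, 0.5, (3, 1))
        pb = np.zeros((3, 1))
        base = con.extract_phase_lag(pa, pb, freqs, np.array([0.0]), (15, 22), 0.0)
        moved = con.extract_phase_lag(pa + rot, pb, freqs, np.array([0.0]),
                                      (15, 22), 0.0)
        diff = np.angle(np.exp(1j * (moved - base - rot)))
        assert abs(diff) < 1e-9
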
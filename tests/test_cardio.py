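"""HRV / SpO2 feature extractors: stats, band powers, Poincare, PRSA."""

import numpy as np
import pytest

import neostress as ns
from neostress.cardio import BANDS_HRV


class TestTemporalStats:
    @pytest.mark.parametrize("x,mu,sd", [([1, 1, 1], 1.0, 0.0),
                                         ([0, 2], 1.0, np.sqrt(2))])
    def test_examples(self, x, mu, sd):
        got = ns.temporal_stats(x)
        assert got == (pytest.approx(mu), pytest.approx(sd))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(257)
        mu, sd = ns.temporal_stats(x)
        assert mu == pytest.approx(sum(x) / len(x), abs=1e-12)
        assert sd == pytest.approx(
            np.sqrt(sum((v - mu) ** 2 for v in x) / (len(x) - 1)), abs=1e-12)

    def test_short_input_missing(self):
        assert np.isnan(ns.temporal_stats([1.0])[0])


class TestResampling:
    def test_constant_tachogram_stays_constant(self, flat_tachogram):
        out = ns.resample_uniform(flat_tachogram, 8.0)
        np.testing.assert_allclose(out.values, 0.5, atol=1e-12)
        assert out.rate == 8.0

    def test_grid_nodes_preserved(self):
        series = ns.UniformSeries(np.arange(100, dtype=float), rate=1.0)
        out = ns.resample_uniform(series, 8.0)
        np.testing.assert_allclose(out.values[::8], series.values, atol=1e-12)

    def test_modulation_frequency_survives(self):
        t_beats = np.cumsum(np.full(3000, 0.4))
        rr = 0.4 + 0.02 * np.sin(2 * np.pi * 0.1 * t_beats)
        out = ns.resample_uniform(ns.Tachogram(np.cumsum(rr), rr), 8.0)
        x = out.values - out.values.mean()
        f = np.fft.rfftfreq(x.size, 1 / 8.0)
        peak = f[np.argmax(np.abs(np.fft.rfft(x)))]
        assert peak == pytest.approx(0.1, abs=0.02)


class TestBandPower:
    def _series(self, freq, rate=8.0, dur=600.0):
        t = np.arange(int(dur * rate)) / rate
        return ns.UniformSeries(np.sin(2 * np.pi * freq * t), rate)

    def test_lf_sinusoid_concentrates_in_lf(self):
        spec = ns.cwt_band_power(self._series(0.1))
        sel = spec.valid
        assert spec.lf[sel].mean() > 10 * spec.hf[sel].mean()

    def test_hf_sinusoid_concentrates_in_hf(self):
        spec = ns.cwt_band_power(self._series(1.0))
        sel = spec.valid
        assert spec.hf[sel].mean() > 10 * spec.lf[sel].mean()

    def test_power_scales_quadratically(self):
        s = self._series(0.5)
        doubled = ns.UniformSeries(2 * s.values, s.rate)
        a = ns.cwt_band_power(s)
        b = ns.cwt_band_power(doubled)
        sel = a.valid
        assert b.hf[sel].sum() == pytest.approx(4 * a.hf[sel].sum(), rel=0.01)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ns.ValidationError):
            ns.cwt_band_power(ns.UniformSeries(np.zeros(512), rate=2.0),
                              bands=BANDS_HRV)

    def test_epoch_features_match_slice_oracle(self):
        rng = np.random.default_rng(7)
        series = ns.UniformSeries(rng.standard_normal(4800), rate=8.0)
        spec = ns.cwt_band_power(series)
        feats = ns.spectral_epoch_features(spec, 200.0, 400.0)
        i0, i1 = 1600, 3200
        sel = spec.valid[i0:i1]
        assert feats["mu_hf"] == pytest.approx(spec.hf[i0:i1][sel].mean(), abs=1e-12)
        assert feats["sd_lf"] == pytest.approx(np.std(spec.lf[i0:i1][sel], ddof=1),
                                               abs=1e-12)

    def test_epoch_fully_in_cone_missing(self):
        spec = ns.cwt_band_power(self._series(0.5))
        feats = ns.spectral_epoch_features(spec, 0.0, 2.0)
        assert np.isnan(feats["mu_hf"])


class TestAutocorrelationLag:
    def test_white_noise_small_lag(self):
        # iid data: the sample ACF at each lag is symmetric around 0, so the
        # first non-positive lag is geometric: P(lag <= 3) = 7/8
        rng = np.random.default_rng(11)
        hits = sum(ns.acf_first_zero(rng.standard_normal(4096))[0] <= 3
                   for _ in range(20))
        assert hits >= 14

    def test_sinusoid_quarter_period(self):
        P = 64
        x = np.sin(2 * np.pi * np.arange(4096) / P)
        lag, flagged = ns.acf_first_zero(x)
        assert not flagged
        assert abs(lag - P // 4) <= 1

    def test_constant_rejected(self):
        with pytest.raises(ns.ValidationError):
            ns.acf_first_zero(np.ones(64))


class TestPoincare:
    def test_constant_series(self):
        pc = ns.poincare_features(np.full(64, 0.42))
        assert pc.sd1 == pc.sd2 == 0.0
        assert pc.cx == pc.cy == pytest.approx(0.42)

    def test_isotropic_cloud(self):
        rng = np.random.default_rng(0)
        pc = ns.poincare_features(rng.standard_normal(4096))
        assert pc.sd1 == pytest.approx(1.0, rel=0.1)
        assert pc.sd2 == pytest.approx(1.0, rel=0.1)
        assert pc.sd2 >= pc.sd1

    def test_energy_identity(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.standard_normal(2048)) * 0.01 + 0.4
        pc = ns.poincare_features(x)
        tau = pc.tau_lag
        X = np.column_stack((x[:-tau], x[tau:]))
        energy = X.var(axis=0, ddof=1).sum()
        assert pc.sd1**2 + pc.sd2**2 == pytest.approx(energy, abs=1e-9)

    def test_short_series_missing(self):
        with pytest.raises(ns.ValidationError):
            ns.poincare_features(np.arange(8.0))


class TestPRSA:
    def _series(self, values, rate=8.0):
        return ns.UniformSeries(values, rate)

    def test_increasing_ramp_has_no_down_anchors(self):
        x = np.linspace(0, 1, 8 * 400)
        prof = ns.prsa(self._series(x), T_s=5.0, direction="down")
        assert prof.missing

    def test_decreasing_ramp_slope_recovered(self):
        a = 0.01
        t = np.arange(8 * 400) / 8.0
        prof = ns.prsa(self._series(-a * t), T_s=5.0, direction="down")
        assert prof.n_anchors > 0
        assert prof.slope_ov == pytest.approx(-a, abs=1e-6)
        assert prof.curve.size == 120 * 8 + 1

    def test_white_noise_null_slope(self):
        devs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = ns.prsa(self._series(rng.standard_normal(2**14)), 10.0, "down")
            devs.append(prof.slope_ov)
        assert abs(np.mean(devs)) < 3 * np.std(devs) / np.sqrt(len(devs)) + 1e-3

    def test_down_of_negated_equals_negated_up(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.standard_normal(8 * 500)) * 0.01
        down = ns.prsa(self._series(-x), 5.0, "down")
        up = ns.prsa(self._series(x), 5.0, "up")
        np.testing.assert_allclose(down.curve, -up.curve, atol=1e-9)
        assert down.slope_ov == pytest.approx(-up.slope_ov, abs=1e-9)

    def test_feature_set_arity_and_linearity(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.standard_normal(8 * 500)) * 0.01
        feats = ns.prsa_feature_set(self._series(x), (1, 5, 10, 20, 50, 100), "down")
        assert len(feats) == 12
        feats2 = ns.prsa_feature_set(self._series(2 * x),
                                     (1, 5, 10, 20, 50, 100), "down")
        for k in feats:
            if np.isfinite(feats[k]):
                assert feats2[k] == pytest.approx(2 * feats[k], rel=1e-9)
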
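import numpy as np
import pytest

from enosefs.containers import SensorRecording
from enosefs.feature_extraction import (
    build_feature_table,
    ema_transient,
    extract_curve_features,
    extract_transient_features,
    read_feature_csv,
    read_recordings_csv,
    read_sparse,
    write_feature_csv,
    write_recordings_csv,
    write_sparse,
)


def _recording(channels, dt=0.5, gas_on=20.0, gas_off=80.0, duration=120.0):
    times = np.arange(0, duration + dt / 2, dt)
    channels = np.atleast_2d(channels)
    assert channels.shape[1] == times.size
    return SensorRecording(times, channels, gas_on, gas_off, (2.0, 18.0))


def _exp_curve(amplitude, baseline=10.0, tau=8.0, dt=0.5, gas_on=20.0, gas_off=80.0,
               duration=120.0, tau_decay=12.0):
    t = np.arange(0, duration + dt / 2, dt)
    rise = np.where(t >= gas_on, 1 - np.exp(-(t - gas_on) / tau), 0.0)
    plateau = 1 - np.exp(-(gas_off - gas_on) / tau)
    decay = plateau * np.exp(-(t - gas_off) / tau_decay)
    return baseline + amplitude * np.where(t <= gas_off, rise, decay), t


class TestEmaTransient:
    def test_constant_series_maps_to_zero(self):
        np.testing.assert_array_equal(ema_transient(np.full(10, 3.3), 0.1), np.zeros(10))

    def test_alpha_one_collapses_to_first_difference(self):
        r = np.array([1.0, 4.0, 2.0, 2.5])
        np.testing.assert_allclose(ema_transient(r, 1.0), [0, 3, -2, 0.5])

    def test_unit_step_geometric_decay(self):
        r = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(ema_transient(r, 0.5), [0, 0.5, 0.25, 0.125, 0.0625])

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            ema_transient(np.zeros(5), 0.0)


class TestTransientFeatures:
    def test_flat_recording_all_zero(self):
        rec = _recording(np.full(241, 10.0))
        np.testing.assert_array_equal(extract_transient_features(rec), np.zeros(8))

    def test_exponential_rise_dr_is_plateau(self):
        curve, _ = _exp_curve(3.0, tau=2.0)
        rec = _recording(curve)
        feats = extract_transient_features(rec)
        assert feats[0] == pytest.approx(3.0, abs=1e-6)   # dR
        assert feats[1] == pytest.approx(0.3, abs=1e-6)   # dR / baseline 10

    def test_matches_windowed_extrema_oracle(self):
        rng = np.random.default_rng(0)
        curve, t = _exp_curve(2.0)
        curve = curve + rng.normal(0, 0.1, curve.size)
        rec = _recording(curve)
        feats = extract_transient_features(rec, alphas=(0.1,))
        # independent re-scan of the EMA series over the two windows
        y = ema_transient(curve, 0.1)
        expo = (t >= 20.0) & (t <= 80.0)
        assert feats[2] == pytest.approx(y[expo].max(), abs=1e-12)
        assert feats[3] == pytest.approx(y[t > 80.0].min(), abs=1e-12)

    def test_zero_baseline_falls_back_to_dr(self):
        curve, _ = _exp_curve(3.0, baseline=0.0, tau=2.0)
        rec = _recording(curve)
        feats = extract_transient_features(rec)
        assert feats[1] == feats[0]


class TestCurveFeatures:
    def test_constant_curve_all_zero_block(self):
        rec = _recording(np.full(241, 10.0))
        feats = extract_curve_features(rec, n_interval_values=10)
        assert feats[0] == 0.0                      # max response
        assert feats[6] == pytest.approx(0.0)       # integral
        np.testing.assert_allclose(feats[7:], 0.0)  # interval values

    def test_linear_ramp_closed_forms(self):
        t = np.arange(0, 120.5, 0.5)
        ramp = np.where((t >= 20) & (t <= 80), (t - 20) / 60.0 * 4.0, 0.0)
        ramp = np.where(t > 80, 0.0, ramp)
        rec = _recording(ramp)
        feats = extract_curve_features(rec, n_interval_values=10)
        window = 60.0
        assert feats[0] == pytest.approx(4.0)
        np.testing.assert_allclose(feats[3:6], [0.3 * window, 0.6 * window, 0.9 * window],
                                   atol=1e-9)
        assert feats[6] == pytest.approx(4.0 * window / 2, rel=1e-12)

    def test_integral_matches_refined_oracle(self):
        curve, t = _exp_curve(2.5)
        rec = _recording(curve)
        feats = extract_curve_features(rec, n_interval_values=10)
        # trapezoid over a 10x-refined resampling of the same sampled signal
        fine = np.linspace(20.0, 80.0, 10 * (t.size - 1) + 1)
        oracle = np.trapezoid(np.interp(fine, t, curve - 10.0), fine)
        assert feats[6] == pytest.approx(oracle, abs=1e-9)

    def test_threshold_never_reached_saturates(self):
        # negative-going curve: max response above baseline is 0
        t = np.arange(0, 120.5, 0.5)
        curve = 10.0 - np.where((t >= 20) & (t <= 80), 2.0, 0.0)
        rec = _recording(curve)
        feats = extract_curve_features(rec)
        np.testing.assert_allclose(feats[3:6], 60.0)

    def test_translation_invariance(self):
        curve, _ = _exp_curve(2.0)
        f1 = extract_curve_features(_recording(curve))
        f2 = extract_curve_features(_recording(curve + 123.0))
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_quadrature_convergence_under_refinement(self):
        c1, _ = _exp_curve(2.0, dt=0.5)
        c2, _ = _exp_curve(2.0, dt=0.25)
        i1 = extract_curve_features(_recording(c1, dt=0.5))[6]
        i2 = extract_curve_features(_recording(c2, dt=0.25))[6]
        assert abs(i1 - i2) / abs(i2) < 1e-3


class TestBuildFeatureTable:
    def _recordings(self, n_sensors, n=4):
        out = []
        for i in range(n):
            chans = np.vstack([_exp_curve(1.0 + 0.1 * s)[0] for s in range(n_sensors)])
            out.append(_recording(chans))
        return out

    @pytest.mark.parametrize("n_sensors,scheme,n_iv,expected", [
        (8, "curve", 10, 136),
        (8, "curve", 9, 128),
        (16, "transient", None, 128),
        (6, "curve", 9, 96),
    ])
    def test_column_counts(self, n_sensors, scheme, n_iv, expected):
        recs = self._recordings(n_sensors)
        kwargs = {} if n_iv is None else {"n_interval_values": n_iv}
        table = build_feature_table(recs, [0, 0, 1, 1], scheme=scheme, **kwargs)
        assert table.n_features == expected
        assert len(set(table.feature_names)) == expected
        assert np.all(np.isfinite(table.values))

    def test_heterogeneous_rejected(self):
        recs = self._recordings(4)[:2] + self._recordings(6)[:2]
        with pytest.raises(ValueError):
            build_feature_table(recs, [0, 0, 1, 1])

    def test_informative_mask_propagation(self):
        recs = self._recordings(4)
        table = build_feature_table(recs, [0, 0, 1, 1], scheme="curve",
                                    n_interval_values=9,
                                    informative_sensors=[True, True, False, False])
        assert table.informative_mask.sum() == 2 * 16


class TestRoundTrips:
    def test_recordings_csv_round_trip(self, tmp_path):
        recs = [
            _recording(np.vstack([_exp_curve(1.0)[0], _exp_curve(2.0)[0]]))
            for _ in range(3)
        ]
        labels = [0, 1, 0]
        write_recordings_csv(recs, labels, tmp_path / "r.csv", tmp_path / "m.csv")
        back, lab = read_recordings_csv(tmp_path / "r.csv", tmp_path / "m.csv")
        assert len(back) == 3 and list(lab) == labels
        np.testing.assert_allclose(back[1].channels, recs[1].channels)
        assert back[0].gas_on == recs[0].gas_on

    def test_feature_csv_round_trip(self, tmp_path):
        recs = [_recording(_exp_curve(1.0 + i)[0]) for i in range(3)]
        table = build_feature_table(recs, [0, 1, 0], scheme="curve")
        write_feature_csv(table, tmp_path / "f.csv")
        back = read_feature_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.values, table.values)
        np.testing.assert_array_equal(back.labels, table.labels)
        assert back.feature_names == table.feature_names

    def test_sparse_round_trip(self, tmp_path):
        recs = [_recording(_exp_curve(1.0 + i)[0]) for i in range(3)]
        table = build_feature_table(recs, [1, 2, 1], scheme="curve")
        write_sparse(table, tmp_path / "f.dat")
        back = read_sparse(tmp_path / "f.dat", n_features=table.n_features)
        np.testing.assert_allclose(back.values, table.values)
        np.testing.assert_array_equal(back.labels, table.labels)
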
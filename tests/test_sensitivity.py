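"""Network training, profile-method sensitivity, SI and VPD breakpoints."""

import numpy as np
import pandas as pd
import pytest

from gravitr import sensitivity as sn


def _random_X(n=96, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(size=(n, 5)), columns=sn.PREDICTORS)


class TestBuildTrainingSet:
    def _weather(self, n_days=3):
        idx = pd.date_range("2017-02-20", periods=96 * n_days, freq="15min")
        rng = np.random.default_rng(1)
        w = pd.DataFrame({
            "T": 25 + 5 * np.sin(np.arange(len(idx)) / 10),
            "RH": 60 + 10 * np.cos(np.arange(len(idx)) / 10),
            "WS": rng.uniform(0.5, 3, len(idx)),
            "RAD": rng.uniform(0, 0.6, len(idx)),
        }, index=idx)
        return w

    def test_row_count_is_steps_per_day(self):
        w = self._weather()
        tr = pd.DataFrame({"C1": np.arange(len(w))}, index=w.index)
        X, Y = sn.build_training_set(w, tr)
        assert len(X) == 96 and len(Y) == 96

    def test_identical_days_average_to_single_day(self):
        w = self._weather(1)
        w3 = pd.concat([w, w, w])
        idx = pd.date_range("2017-02-20", periods=288, freq="15min")
        w3.index = idx
        tr = pd.DataFrame({"C1": np.tile(np.sin(np.arange(96)), 3)}, index=idx)
        X3, Y3 = sn.build_training_set(w3, tr)
        assert np.allclose(Y3["C1"], np.sin(np.arange(96)))

    def test_grid_mismatch_rejected(self):
        w = self._weather()
        tr = pd.DataFrame({"C1": [1.0]}, index=[w.index[0]])
        with pytest.raises(ValueError):
            sn.build_training_set(w, tr)


class TestTrainNN:
    def test_noiseless_linear_target_fits_closely(self):
        X = _random_X(seed=2)
        beta = np.array([1.0, -0.5, 2.0, 0.3, 0.1])
        Y = pd.DataFrame({"Y1": X.to_numpy() @ beta})
        m = sn.train_nn(X, Y, seed=1, n_restarts=3)
        assert m.history["val_mse"].iloc[m.best_epoch] < 1e-4
        assert m.r_validation[0] > 0.999

    def test_pure_noise_target_not_overfitted(self):
        rng = np.random.default_rng(3)
        X = _random_X(seed=3)
        Y = pd.DataFrame({"Y1": rng.normal(size=96)})
        m = sn.train_nn(X, Y, seed=2, n_restarts=3)
        # scale the validation variance as the training pipeline does
        ys = m.y_scaler.transform(rng.normal(size=(2000, 1)))
        # best-epoch validation MSE stays near the (scaled) noise variance:
        # no spurious structure is memorised
        val = m.history["val_mse"].iloc[m.best_epoch]
        var = np.var(m.y_scaler.transform(Y.to_numpy()))
        assert val <= 1.3 * var

    def test_untrained_network_predicts_biases(self):
        X = _random_X(seed=4)
        theta = np.zeros(5 * 5 + 5 + 5 * 2 + 2)
        theta[-2:] = [0.3, 0.7]  # output biases
        out, _ = sn._forward(theta, X.to_numpy(), 5, 2)
        assert np.allclose(out, [0.3, 0.7])

    def test_bit_reproducible_under_seed(self):
        X = _random_X(seed=5)
        Y = pd.DataFrame({"Y1": X["vpd"] * 2, "Y2": X["T"]})
        a = sn.train_nn(X, Y, seed=7, n_restarts=2)
        b = sn.train_nn(X, Y, seed=7, n_restarts=2)
        assert np.array_equal(a.theta, b.theta)
        assert a.best_epoch == b.best_epoch

    def test_history_bounded_by_max_epochs(self):
        X = _random_X(seed=6)
        Y = pd.DataFrame({"Y1": X["vpd"]})
        m = sn.train_nn(X, Y, seed=0, max_epochs=50, n_restarts=1)
        assert len(m.history) <= 50
        assert m.best_epoch == m.history["val_mse"].idxmin()

    def test_too_few_rows_rejected(self):
        X = _random_X(n=10)
        with pytest.raises(ValueError):
            sn.train_nn(X, pd.DataFrame({"Y": np.ones(10)}))


class TestProfiles:
    def _dead_input_model(self):
        """Hand-set weights: the 'WS' input (index 4) has zero weight."""
        rng = np.random.default_rng(8)
        X = _random_X(seed=8)
        n_in, h, n_out = 5, 5, 2
        W1 = rng.normal(size=(n_in, h)); W1[4, :] = 0.0
        b1 = rng.normal(size=h)
        W2 = rng.normal(size=(h, n_out))
        b2 = rng.normal(size=n_out)
        theta = np.concatenate([W1.ravel(), b1, W2.ravel(), b2])
        xs = sn.MinMaxScaler.fit(X.to_numpy())
        ys = sn.MinMaxScaler(lo=np.zeros(n_out), hi=np.ones(n_out))
        return sn.NNModel(theta=theta, n_hidden=h, n_out=n_out, x_scaler=xs,
                          y_scaler=ys, X_scaled=xs.transform(X.to_numpy()),
                          history=pd.DataFrame({"train_mse": [0], "val_mse": [0]}),
                          output_names=["C1", "C2"],
                          predictor_names=list(X.columns))

    def test_dead_input_has_flat_profiles(self):
        model = self._dead_input_model()
        prof = sn.sensitivity_profiles(model, "WS")
        for (_, _), sub in prof.groupby(["split", "output"]):
            assert np.ptp(sub["value"].to_numpy()) < 1e-12

    def test_splits_differ_for_live_inputs(self):
        model = self._dead_input_model()
        prof = sn.sensitivity_profiles(model, "vpd", splits=(0, 100))
        c0 = prof[(prof.split == 0) & (prof.output == "C1")]["value"].to_numpy()
        c1 = prof[(prof.split == 100) & (prof.output == "C1")]["value"].to_numpy()
        assert not np.allclose(c0, c1)

    def test_grid_spans_observed_range(self):
        model = self._dead_input_model()
        prof = sn.sensitivity_profiles(model, "T", splits=(0,))
        g = prof["grid"].to_numpy()
        lo = model.x_scaler.lo[0]; hi = model.x_scaler.hi[0]
        assert g.min() == pytest.approx(lo)
        assert g.max() == pytest.approx(hi)

    def test_unknown_predictor_rejected(self):
        model = self._dead_input_model()
        with pytest.raises(ValueError):
            sn.sensitivity_profiles(model, "XYZ")


class TestSensitivityIndex:
    def test_identity_curve_is_100(self):
        x = np.linspace(0, 1, 101)
        assert sn.sensitivity_index(x, x) == pytest.approx(100.0, abs=1e-6)

    def test_ramp_plateau_first_slope(self):
        x = np.linspace(0, 1, 101)
        y = np.minimum(x / 0.6, 1.0)
        assert sn.sensitivity_index(x, y) == pytest.approx(166.7, abs=0.5)

    def test_flat_curve_is_zero(self):
        x = np.linspace(0, 1, 101)
        assert sn.sensitivity_index(x, np.full(101, 3.0)) == 0.0


class TestVpdBreakpoint:
    x = np.linspace(0, 1, 101)

    def test_ramp_plateau_at_60_percent(self):
        y = np.minimum(self.x / 0.6, 1.0)
        frac, kpa = sn.vpd_breakpoint(self.x * 6.29, y, 6.29)
        assert frac == pytest.approx(60.0, abs=1.5)
        assert kpa == pytest.approx(0.6 * 6.29, abs=0.1)

    def test_rise_then_decline_breaks_at_peak(self):
        y = np.where(self.x < 0.6, self.x / 0.6, 1 - 0.3 * (self.x - 0.6))
        frac, _ = sn.vpd_breakpoint(self.x * 6.29, y, 6.29)
        assert frac == pytest.approx(60.0, abs=1.5)

    def test_monotone_curve_reports_unrestricted(self):
        frac, kpa = sn.vpd_breakpoint(self.x * 6.29, self.x, 6.29)
        assert frac == pytest.approx(100.0)
        assert kpa == pytest.approx(6.29)

    @pytest.mark.parametrize("pct,expected_kpa", [(56.0, 3.52), (62.0, 3.90)])
    def test_fraction_to_kpa_conversion(self, pct, expected_kpa):
        assert sn.fraction_to_kpa(pct, 6.29) == pytest.approx(expected_kpa,
                                                              abs=5e-3)
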
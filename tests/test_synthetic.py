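"""The synthetic experiment generator: weather, load cells, populations."""

import numpy as np
import pandas as pd
import pytest

from gravitr import preprocess as pp, refet, synthetic as syn


class TestWeather:
    def test_same_seed_identical(self):
        cfg = syn.SimulationConfig(seed=5, n_days=3)
        a = syn.simulate_weather(cfg)
        b = syn.simulate_weather(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_max_vpd_near_default(self):
        w = syn.simulate_weather(syn.SimulationConfig(seed=3))
        v = refet.vpd(w["T"], w["RH"])
        assert np.max(v) == pytest.approx(6.29, rel=0.05)

    def test_full_humidity_means_zero_vpd(self):
        w = syn.simulate_weather(syn.SimulationConfig(seed=3, n_days=2))
        v = refet.vpd(w["T"], np.full(len(w), 100.0))
        assert np.allclose(v, 0.0)

    def test_physical_ranges(self):
        w = syn.simulate_weather(syn.SimulationConfig(seed=9))
        assert (w["RAD"] >= 0).all()
        assert (w["WS"] >= 0).all()
        assert w["RH"].between(0, 100).all()
        night = w["timestamp"].dt.hour < 5
        assert np.allclose(w.loc[night, "RAD"], 0.0)

    def test_simulator_vpd_matches_refet(self):
        w = syn.simulate_weather(syn.SimulationConfig(seed=2, n_days=2))
        dw = refet.derive_weather(w.set_index("timestamp"))
        assert np.allclose(dw["vpd"], refet.vpd(w["T"], w["RH"]))

    def test_nonpositive_days_rejected(self):
        with pytest.raises(ValueError):
            syn.SimulationConfig(n_days=0)


class TestArchetype:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.GenotypeArchetype("G", "w", 0.05, 1.5, 0.25)
        with pytest.raises(ValueError):
            syn.GenotypeArchetype("G", "w", -1.0, 0.5, 0.25)

    def test_response_constant_above_knee(self):
        arch = syn.GenotypeArchetype("G", "w", 0.05, 0.6, 0.25)
        vpd = np.linspace(0, 6.29, 500)
        tr = arch.tr_response(vpd, 6.29)
        above = vpd >= 0.6 * 6.29
        assert np.allclose(tr[above], 0.05)
        assert np.all(np.diff(tr) >= -1e-12)

    def test_response_slope_vanishes_at_knee(self):
        arch = syn.GenotypeArchetype("G", "w", 0.05, 0.6, 0.25)
        k = 0.6 * 6.29
        h = 1e-5
        slope = (arch.tr_response(np.array([k]), 6.29)
                 - arch.tr_response(np.array([k - h]), 6.29)) / h
        assert abs(slope[0]) < 1e-3


class TestLoadCell:
    def test_constant_vpd_below_knee_gives_linear_weights(self):
        cfg = syn.SimulationConfig(seed=1, n_days=2, noise_sd=0.0,
                                   irrigation_days=())
        w = syn.simulate_weather(cfg)
        w["T"] = 25.0
        w["RH"] = 60.0  # constant VPD ~ 1.27 kPa, below any knee
        arch = syn.GenotypeArchetype("G", "w", 0.05, 0.8, 0.25)
        trace = syn.simulate_loadcell(arch, w, cfg)
        diffs = np.diff(trace.weights)
        assert np.allclose(diffs[1:], diffs[1], atol=1e-9)

    def test_ground_truth_plateau_stored(self):
        cfg = syn.SimulationConfig(seed=4, n_days=3, noise_sd=0.0,
                                   irrigation_days=())
        w = syn.simulate_weather(cfg)
        arch = syn.GenotypeArchetype("G", "w", 0.06, 0.6, 0.25)
        trace = syn.simulate_loadcell(arch, w, cfg)
        vpd = np.asarray(refet.vpd(w["T"], w["RH"]))
        above = vpd > 0.6 * cfg.vpd_max
        assert above.any()
        assert np.allclose(trace.true_tr[above], 0.06)

    def test_irrigation_day_has_large_weight_increase(self):
        cfg = syn.SimulationConfig(seed=6, n_days=4, irrigation_days=(2,),
                                   noise_sd=1.0)
        w = syn.simulate_weather(cfg)
        arch = syn.GenotypeArchetype("G", "w", 0.06, 0.7, 0.25)
        trace = syn.simulate_loadcell(arch, w, cfg)
        day2 = slice(2 * 96, 3 * 96)
        increases = np.diff(trace.weights[day2])
        assert increases.max() > 5 * cfg.noise_sd

    def test_grid_mismatch_rejected(self):
        cfg = syn.SimulationConfig(seed=1, n_days=2)
        w = syn.simulate_weather(syn.SimulationConfig(seed=1, n_days=3))
        arch = syn.GenotypeArchetype("G", "w", 0.05, 0.6, 0.25)
        with pytest.raises(ValueError):
            syn.simulate_loadcell(arch, w, cfg)

    def test_zero_noise_pipeline_recovers_ground_truth_et(self):
        cfg = syn.SimulationConfig(seed=8, n_days=3, noise_sd=0.0,
                                   irrigation_days=())
        w = syn.simulate_weather(cfg)
        arch = syn.GenotypeArchetype("G", "w", 0.05, 0.7, 0.25)
        trace = syn.simulate_loadcell(arch, w, cfg)
        etr = pp.weights_to_etr(trace.weights)
        assert np.allclose(etr, trace.true_et_grams[1:], atol=1e-9)

    def test_zero_noise_etr_passes_ratio_filter_untouched(self):
        cfg = syn.SimulationConfig(seed=8, noise_sd=0.0, irrigation_days=())
        w = syn.simulate_weather(cfg)
        dw = refet.derive_weather(w.set_index("timestamp"))
        arch = syn.GenotypeArchetype("G", "lowTE", 0.09, 0.8, 0.25)
        trace = syn.simulate_loadcell(arch, w, cfg)
        etr = pp.grams_to_mm(pp.weights_to_etr(trace.weights))
        res = refet.ratio_filter(etr, dw["et0"].to_numpy()[1:],
                                 dw["RAD"].to_numpy()[1:])
        assert res.n_removed == 0


class TestPopulation:
    def test_sector_counts(self, small_bundle):
        # 3 clusters x 4 genotypes x 2 reps -> 24 sectors
        assert small_bundle.loadcells.shape[1] == 1 + 24
        assert len(small_bundle.design) == 24

    def test_default_layout_192_sectors(self, default_bundle):
        assert default_bundle.loadcells.shape[1] == 1 + 192
        assert len(default_bundle.design) == 192

    def test_ground_truth_breakpoints_are_configured_values(self, small_bundle):
        assert small_bundle.ground_truth["cluster_breakpoints"] == {
            "wild": 0.56, "highTE": 0.70, "lowTE": 0.80}

    def test_same_seed_byte_identical(self):
        cfg = syn.SimulationConfig(seed=33, n_days=2)
        a = syn.make_population(cfg, n_genotypes_per_cluster=2, n_replicates=2)
        b = syn.make_population(cfg, n_genotypes_per_cluster=2, n_replicates=2)
        pd.testing.assert_frame_equal(a.loadcells, b.loadcells)
        pd.testing.assert_frame_equal(a.leafarea, b.leafarea)
        assert a.ground_truth == b.ground_truth

    def test_too_few_clusters_or_reps_rejected(self):
        cfg = syn.SimulationConfig(seed=1, n_days=2)
        with pytest.raises(ValueError):
            syn.make_population(cfg, clusters={"only": {
                "max_tr_scale": 0.05, "breakpoint_fraction": 0.5}})
        with pytest.raises(ValueError):
            syn.make_population(cfg, n_replicates=1)

    def test_bundle_roundtrips_through_csv(self, tmp_path, small_bundle):
        out = small_bundle.write(tmp_path)
        lc = pd.read_csv(out / "loadcells.csv", parse_dates=["timestamp"])
        pd.testing.assert_frame_equal(lc, small_bundle.loadcells)
        import json
        gt = json.loads((out / "ground_truth.json").read_text())
        assert gt["cluster_breakpoints"] == {"wild": 0.56, "highTE": 0.70,
                                             "lowTE": 0.80}
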
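import numpy as np
import pytest
from scipy.stats import spearmanr

from grasscast.synthetic import (LandscapeConfig, ScenarioDelta, apply_scenario,
                                 default_scenarios, generate_env_stack,
                                 make_exclusion_mask, make_species_truths,
                                 make_survey_map, sample_occurrences,
                                 species_truth_map, simulate_dataset)


def _neighbor_correlation(layer):
    """Lag-1 (rook) spatial autocorrelation: r between horizontally and
    vertically adjacent cell pairs."""
    pairs_a = np.concatenate([layer[:, :-1].ravel(), layer[:-1, :].ravel()])
    pairs_b = np.concatenate([layer[:, 1:].ravel(), layer[1:, :].ravel()])
    return np.corrcoef(pairs_a, pairs_b)[0, 1]


class TestEnvStack:
    def test_deterministic_given_seed(self):
        cfg = LandscapeConfig(n_rows=16, n_cols=16, seed=42)
        a = generate_env_stack(cfg)
        b = generate_env_stack(cfg)
        for n in a.layer_names:
            np.testing.assert_array_equal(a.layers[n], b.layers[n], strict=True)

    def test_layer_count_and_roles(self):
        cfg = LandscapeConfig(n_rows=8, n_cols=8, n_climate_layers=4,
                              n_static_layers=3, seed=0)
        stack = generate_env_stack(cfg)
        assert len(stack.layer_names) == 7
        assert len(stack.climate_layers) == 4
        assert len(stack.static_layers) == 3

    def test_standardization(self):
        stack = generate_env_stack(LandscapeConfig(n_rows=20, n_cols=20, seed=1))
        for n in stack.layer_names:
            v = stack.layers[n][stack.valid]
            assert abs(v.mean()) < 1e-9
            assert abs(v.std() - 1) < 1e-9

    def test_smoothing_increases_autocorrelation(self):
        smooth = generate_env_stack(
            LandscapeConfig(n_rows=40, n_cols=40, autocorr_range=5.0, seed=2))
        rough = generate_env_stack(
            LandscapeConfig(n_rows=40, n_cols=40, autocorr_range=0.0, seed=2))
        name = smooth.layer_names[0]
        assert (_neighbor_correlation(smooth.layers[name])
                > _neighbor_correlation(rough.layers[name]))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            LandscapeConfig(n_rows=1, n_cols=5)
        with pytest.raises(ValueError):
            LandscapeConfig(autocorr_range=-1)


class TestSpeciesTruths:
    def test_round_robin_covers_all_types(self, demo_stack):
        species, truths = make_species_truths(44, 17, demo_stack, seed=3)
        per_type = {}
        for s in species:
            per_type.setdefault(s.vegetation_type, []).append(s)
        assert set(per_type) == set(range(1, 18))
        assert all(len(v) >= 2 for v in per_type.values())
        # a type maps to exactly one functional class
        for members in per_type.values():
            assert len({m.functional_class for m in members}) == 1

    def test_both_classes_present(self, demo_stack):
        species, _ = make_species_truths(10, 5, demo_stack, seed=4)
        assert {s.functional_class for s in species} == {"productive", "wildlife"}

    def test_truths_in_open_unit_interval(self, demo_stack):
        _, truths = make_species_truths(6, 3, demo_stack, seed=5)
        for t in truths.values():
            v = t[np.isfinite(t)]
            assert v.min() > 0 and v.max() < 1

    def test_flat_response_gives_half(self, demo_stack):
        t = species_truth_map(demo_stack, {}, 0.0)
        np.testing.assert_allclose(t[demo_stack.valid], 0.5)

    def test_dominant_layer_drives_suitability(self, demo_stack):
        t = species_truth_map(demo_stack, {"clim_01": 4.0}, -1.0)
        rho = spearmanr(demo_stack.layers["clim_01"][demo_stack.valid],
                        t[demo_stack.valid]).statistic
        assert rho > 0.95

    def test_config_errors(self, demo_stack):
        with pytest.raises(ValueError):
            make_species_truths(3, 5, demo_stack, seed=0)


class TestSampling:
    def test_single_cell_truth(self, geom10):
        truth = np.zeros((10, 10))
        truth[4, 7] = 0.8
        occ = sample_occurrences(truth, geom10, 25, seed=6)
        r, c = geom10.cell_index(occ.records.lon.to_numpy(),
                                 occ.records.lat.to_numpy())
        assert (r == 4).all() and (c == 7).all()

    def test_counts_track_weights(self):
        from grasscast.rasters import GridGeometry
        geom = GridGeometry(20, 20, 0, 0, 1.0)
        rng = np.random.default_rng(7)
        truth = rng.random((20, 20))
        occ = sample_occurrences(truth, geom, 10_000, seed=8)
        r, c = geom.cell_index(occ.records.lon.to_numpy(),
                               occ.records.lat.to_numpy())
        counts = np.zeros((20, 20))
        np.add.at(counts, (r, c), 1)
        assert np.corrcoef(counts.ravel(), truth.ravel())[0, 1] >= 0.9

    def test_determinism_and_bounds(self, geom10):
        truth = np.full((10, 10), 0.5)
        a = sample_occurrences(truth, geom10, 50, seed=9)
        b = sample_occurrences(truth, geom10, 50, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert geom10.contains(a.coords[:, 0], a.coords[:, 1]).all()

    def test_zero_truth_errors(self, geom10):
        with pytest.raises(ValueError, match="zero"):
            sample_occurrences(np.zeros((10, 10)), geom10, 5, seed=0)


class TestScenario:
    def test_zero_delta_identity(self, demo_stack):
        out = apply_scenario(demo_stack, ScenarioDelta("null", {}))
        for n in demo_stack.layer_names:
            np.testing.assert_array_equal(out.layers[n], demo_stack.layers[n])

    def test_additive_shift(self, demo_stack):
        out = apply_scenario(demo_stack, ScenarioDelta("s", {"clim_01": 2.0}))
        diff = out.layers["clim_01"] - demo_stack.layers["clim_01"]
        np.testing.assert_allclose(diff[demo_stack.valid], 2.0)
        np.testing.assert_array_equal(out.layers["stat_01"],
                                      demo_stack.layers["stat_01"])

    def test_sequential_deltas_add(self, demo_stack):
        one = apply_scenario(apply_scenario(demo_stack,
                                            ScenarioDelta("a", {"clim_01": 2.0})),
                             ScenarioDelta("b", {"clim_01": 3.0}))
        five = apply_scenario(demo_stack, ScenarioDelta("c", {"clim_01": 5.0}))
        np.testing.assert_allclose(one.layers["clim_01"], five.layers["clim_01"],
                                   equal_nan=True)

    def test_static_layer_shift_rejected(self, demo_stack):
        with pytest.raises(ValueError):
            apply_scenario(demo_stack, ScenarioDelta("s", {"stat_01": 1.0}))

    def test_default_scenarios_warming_ladder(self, demo_stack):
        deltas = {d.scenario_id: d for d in default_scenarios(demo_stack)}
        # warming ladder +2 / +3 / +4.1 / +5 degrees at 0.2 sigma per degree
        assert deltas["SSP126"].shifts["clim_01"] == pytest.approx(0.4)
        assert deltas["SSP370"].shifts["clim_01"] == pytest.approx(0.82)
        assert deltas["SSP585"].shifts["clim_01"] == pytest.approx(1.0)
        # monotone in warming on the temperature proxy
        assert (deltas["SSP126"].shifts["clim_01"]
                < deltas["SSP245"].shifts["clim_01"]
                < deltas["SSP370"].shifts["clim_01"]
                < deltas["SSP585"].shifts["clim_01"])


class TestSurvey:
    def test_zero_flip_identity(self):
        truth = (np.random.default_rng(1).random((20, 20)) > 0.5).astype(float)
        np.testing.assert_array_equal(make_survey_map(truth, 0.0, seed=1), truth)

    def test_flip_rate_within_binomial_bounds(self):
        truth = np.zeros((100, 100))
        survey = make_survey_map(truth, 0.1, seed=2)
        frac = (survey != truth).mean()
        sd = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(frac - 0.1) < 3 * sd

    def test_deterministic(self):
        truth = np.ones((30, 30))
        a = make_survey_map(truth, 0.2, seed=3)
        b = make_survey_map(truth, 0.2, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            make_survey_map(np.ones((2, 2)), 0.6, seed=0)


class TestDataset:
    def test_all_products_share_geometry(self, tmp_path):
        cfg = LandscapeConfig(n_rows=12, n_cols=12, seed=10)
        paths = simulate_dataset(tmp_path, cfg, n_species=6, n_types=3,
                                 n_occurrences=15, mask_fraction=0.05)
        from grasscast.rasters import EnvStack, read_ascii_grid
        geoms = set()
        for man in paths["stacks"].values():
            geoms.add(EnvStack.read(man).geometry)
        for key in ("survey", "mask", "truth_grassland"):
            _, g, _ = read_ascii_grid(paths[key])
            geoms.add(g)
        assert len(geoms) == 1

    def test_mask_fraction(self):
        cfg = LandscapeConfig(n_rows=50, n_cols=50, seed=11)
        mask = make_exclusion_mask(cfg, fraction=0.1)
        assert abs(mask.mean() - 0.1) < 0.02
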
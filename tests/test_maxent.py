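import numpy as np
import pandas as pd
import pytest

from grasscast.features import build_features
from grasscast.maxent import (ConvergenceError, MaxentModel, MaxentResults,
                              SpeciesSkipError, auc, cv_replicates, default_betas,
                              maxent_objective, permutation_contributions)
from grasscast.synthetic import sample_occurrences, species_truth_map

from oracles import auc_by_pair_counting, maxent_oracle_objective


@pytest.fixture
def two_cell():
    """Background {A: f=0, B: f=1}; presences 3xB + 1xA; no regularization."""
    B = np.array([[0.0], [1.0]])
    P = np.array([[1.0], [1.0], [1.0], [0.0]])
    return MaxentModel(P, B, reg_multiplier=0.0, betas=np.zeros(1))


class TestFit:
    def test_two_cell_closed_form(self, two_cell):
        res = two_cell.fit()
        assert res.lam[0] == pytest.approx(np.log(3), abs=1e-6)
        np.testing.assert_allclose(res.raw_background, [0.25, 0.75], atol=1e-6)

    def test_constant_feature_gives_uniform_raw(self):
        B = np.full((6, 1), 0.5)
        P = np.full((4, 1), 0.5)
        res = MaxentModel(P, B, reg_multiplier=2.0, betas=np.array([0.1])).fit()
        np.testing.assert_allclose(res.raw_background, 1 / 6, atol=1e-9)
        # uniform raw -> cloglog constant 1 - exp(-1)
        np.testing.assert_allclose(res.predict_features(B, "cloglog"),
                                   1 - np.exp(-1), atol=1e-9)

    def test_raw_normalizes_over_background(self):
        rng = np.random.default_rng(1)
        B = rng.random((40, 3))
        P = B[rng.choice(40, 10)]
        res = MaxentModel(P, B, reg_multiplier=1.0).fit()
        assert abs(res.raw_background.sum() - 1.0) < 1e-9

    def test_unregularized_moment_matching(self):
        rng = np.random.default_rng(2)
        B = rng.random((30, 2))
        P = B[rng.choice(30, 8)]
        res = MaxentModel(P, B, betas=np.zeros(2)).fit(tol=1e-12)
        E = res.raw_background @ B
        np.testing.assert_allclose(E, P.mean(axis=0), atol=1e-5)

    @pytest.mark.parametrize("mult", [0.0, 1.0, 2.0])
    def test_objective_matches_convex_oracle(self, mult):
        rng = np.random.default_rng(10 + int(mult))
        B = rng.random((45, 3))
        P = B[rng.choice(45, 12)]
        model = MaxentModel(P, B, reg_multiplier=mult)
        res = model.fit()
        ours = maxent_objective(res.lam, P, B, model.betas)
        oracle = maxent_oracle_objective(P, B, model.betas)
        assert ours == pytest.approx(oracle, abs=1e-5)

    def test_regularization_monotonicity(self):
        # stronger lasso never grows the total weight mass
        rng = np.random.default_rng(3)
        B = rng.random((40, 3))
        P = B[rng.choice(40, 15)]
        l1 = []
        for mult in [0.25, 0.5, 1.0, 2.0, 4.0]:
            res = MaxentModel(P, B, reg_multiplier=mult).fit()
            l1.append(np.abs(res.lam).sum())
        assert all(a >= b - 1e-8 for a, b in zip(l1, l1[1:]))

    def test_nonconvergence_carries_trace(self):
        rng = np.random.default_rng(4)
        B = rng.random((30, 2))
        P = B[rng.choice(30, 10)]
        with pytest.raises(ConvergenceError) as err:
            MaxentModel(P, B, reg_multiplier=1.0).fit(tol=0.0, maxiter=1)
        assert err.value.trace.size == 1

    def test_beta_schedule_uses_presence_sd_and_kind(self):
        rng = np.random.default_rng(5)
        tab = rng.random((100, 2))
        fs = build_features(tab, ["a", "b"], {"linear", "hinge"}, n_hinge_knots=2)
        P = fs.transform(tab[:20])
        betas = default_betas(fs, P, reg_multiplier=2.0)
        m = 20
        sd = P.std(axis=0)
        # linear features interpolate the default table; hinge uses 0.5
        b0_lin = np.interp(m, [10, 30, 100], [1.0, 0.2, 0.05])
        np.testing.assert_allclose(betas[0], 2.0 * b0_lin * sd[0] / np.sqrt(m))
        j_h = next(i for i, f in enumerate(fs.defs) if f.kind == "hinge")
        np.testing.assert_allclose(betas[j_h], 2.0 * 0.5 * sd[j_h] / np.sqrt(m))


class TestPredict:
    def test_cloglog_monotone_in_raw(self):
        rng = np.random.default_rng(6)
        B = rng.random((50, 2))
        P = B[rng.choice(50, 12)]
        res = MaxentModel(P, B, reg_multiplier=1.0).fit()
        raw = res.predict_features(B, "raw")
        clog = res.predict_features(B, "cloglog")
        assert np.all((clog > 0) & (clog < 1))
        np.testing.assert_array_equal(np.argsort(raw), np.argsort(clog))

    def test_two_cell_orders_cells(self, two_cell):
        res = two_cell.fit()
        clog = res.predict_features(np.array([[0.0], [1.0]]), "cloglog")
        assert clog[1] > clog[0]

    def test_feature_mismatch_errors(self, two_cell):
        res = two_cell.fit()
        with pytest.raises(ValueError):
            res.predict_features(np.zeros((3, 2)))

    def test_save_load_roundtrip(self, tmp_path, demo_stack):
        rng = np.random.default_rng(7)
        tab = demo_stack.table()
        fs = build_features(tab, demo_stack.layer_names, {"linear", "hinge"}, 4)
        B = fs.transform(tab)
        P = B[rng.choice(B.shape[0], 20)]
        res = MaxentModel(P, B, fs, reg_multiplier=2.0).fit()
        res.save(tmp_path / "m.lambdas")
        back = MaxentResults.load(tmp_path / "m.lambdas")
        np.testing.assert_allclose(back.predict_map(demo_stack),
                                   res.predict_map(demo_stack), rtol=1e-12,
                                   equal_nan=True)


class TestAUC:
    @pytest.mark.parametrize("p,b,expected", [
        ([0.9, 0.8], [0.1, 0.2], 1.0),
        ([0.5, 0.5], [0.5, 0.5], 0.5),
        ([0.9, 0.3], [0.5, 0.1], 0.75),
    ])
    def test_worked_examples(self, p, b, expected):
        assert auc(p, b) == pytest.approx(expected)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.choice(np.linspace(0, 1, 7), size=9)
            b = rng.choice(np.linspace(0, 1, 7), size=13)
            assert auc(p, b) == pytest.approx(auc_by_pair_counting(p, b))

    def test_invariant_under_cloglog(self):
        rng = np.random.default_rng(9)
        B = rng.random((40, 2))
        P = B[rng.choice(40, 10)]
        res = MaxentModel(P, B, reg_multiplier=1.0).fit()
        a_raw = auc(res.predict_features(P, "raw"), res.predict_features(B, "raw"))
        a_clog = auc(res.predict_features(P, "cloglog"),
                     res.predict_features(B, "cloglog"))
        assert a_raw == a_clog


class TestContributions:
    def _fit_on(self, stack, weights, intercept, n=60, seed=0):
        truth = species_truth_map(stack, weights, intercept)
        occ = sample_occurrences(truth, stack.geometry, n, seed=seed)
        rows, cols = stack.geometry.cell_index(occ.records.lon.to_numpy(),
                                               occ.records.lat.to_numpy())
        tab = stack.table()
        fs = build_features(tab, stack.layer_names, {"linear", "hinge"}, 4)
        P = fs.transform(stack.values_at(rows, cols))
        res = MaxentModel(P, fs.transform(tab), fs, 2.0).fit()
        return res, stack.values_at(rows, cols), tab

    def test_single_informative_variable_gets_100(self, demo_stack):
        stack = demo_stack.subset(["clim_01", "stat_01"])
        res, pres, bg = self._fit_on(stack, {"clim_01": 5.0}, -4.0)
        contrib = permutation_contributions(res, pres, bg, seed=1)
        assert contrib.sum() == pytest.approx(100.0, abs=1e-6)
        assert contrib["clim_01"] > 80.0

    def test_zero_weight_variable_contributes_zero(self, demo_stack):
        stack = demo_stack.subset(["clim_01", "stat_01"])
        res, pres, bg = self._fit_on(stack, {"clim_01": 6.0}, -5.0)
        if "stat_01" not in res.active_variables():
            contrib = permutation_contributions(res, pres, bg, seed=2)
            assert contrib["stat_01"] == 0.0

    def test_duplicated_variable_shares_contribution(self, demo_stack):
        # two exchangeable copies of one informative layer carrying identical
        # weights must get (approximately) equal permutation importances
        import grasscast.rasters as rst
        from grasscast.maxent import MaxentResults
        base = demo_stack.layers["clim_01"]
        stack = rst.EnvStack({"va": base.copy(), "vb": base.copy()},
                             demo_stack.geometry)
        res, pres, bg = self._fit_on(stack, {"va": 5.0}, -4.0)
        # symmetrize the fitted weights across the copy pair: lasso splits
        # weight between perfect duplicates arbitrarily, the metric should not
        lam = res.lam.copy()
        fs = res.feature_set
        for j, f in enumerate(fs.defs):
            if f.layers == ("va",):
                twin = next(i for i, g in enumerate(fs.defs)
                            if g.layers == ("vb",) and g.kind == f.kind
                            and g.direction == f.direction
                            and (f.kind != "hinge" or np.isclose(g.knot, f.knot)))
                mean = 0.5 * (lam[j] + lam[twin])
                lam[j] = lam[twin] = mean
        sym = MaxentResults(res.model, lam)
        contrib = permutation_contributions(sym, pres, bg, seed=3)
        assert contrib.sum() == pytest.approx(100.0, abs=1e-6)
        assert abs(contrib["va"] - contrib["vb"]) < 10.0


class TestCV:
    def test_split_sizes_and_determinism(self, demo_stack):
        truth = species_truth_map(demo_stack, {"clim_01": 4.0}, -3.0)
        occ = sample_occurrences(truth, demo_stack.geometry, 20, seed=4)
        cv1 = cv_replicates(occ, demo_stack, kinds={"linear"}, seed=5,
                            n_replicates=3)
        assert (cv1.report.replicates["n_train"] == 15).all()
        assert (cv1.report.replicates["n_test"] == 5).all()
        cv2 = cv_replicates(occ, demo_stack, kinds={"linear"}, seed=5,
                            n_replicates=3)
        np.testing.assert_array_equal(cv1.mean_map, cv2.mean_map, strict=True)

    def test_too_few_presences_is_explicit_skip(self, demo_stack):
        truth = species_truth_map(demo_stack, {"clim_01": 4.0}, -3.0)
        occ = sample_occurrences(truth, demo_stack.geometry, 5, seed=6)
        with pytest.raises(SpeciesSkipError, match="skip"):
            cv_replicates(occ, demo_stack, kinds={"linear"}, seed=7)

    def test_projection_on_identical_stack_matches_training_map(self, demo_stack):
        truth = species_truth_map(demo_stack, {"clim_01": 4.0}, -3.0)
        occ = sample_occurrences(truth, demo_stack.geometry, 30, seed=8)
        cv = cv_replicates(occ, demo_stack, kinds={"linear"}, seed=9,
                           n_replicates=2,
                           project_stacks={"same": demo_stack})
        np.testing.assert_allclose(cv.projected["same"], cv.mean_map,
                                   rtol=1e-12, equal_nan=True)
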
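import numpy as np
import pandas as pd
import pytest

import pathsurv as ps
from pathsurv.containers import GeneSetCollection
from pathsurv.coxnet import (GroupStructure, PenalizedCoxPH,
                             PenalizedCoxResults, build_grouped_design)

from conftest import make_survival


class TestGroupStructure:
    def test_partition_enforced(self):
        gs = GroupStructure({"a": [0, 1], "b": [1, 2]})
        with pytest.raises(ValueError, match="partition"):
            gs.validate_partition(3)
        GroupStructure({"a": [0, 1], "b": [2]}).validate_partition(3)

    def test_default_weights_sqrt_cardinality(self):
        gs = GroupStructure({"a": [0, 1, 2, 3], "b": [4]})
        assert gs.weights["a"] == pytest.approx(2.0)
        assert gs.weights["b"] == pytest.approx(1.0)

    def test_positive_weights_required(self):
        with pytest.raises(ValueError, match="m_g"):
            GroupStructure({"a": [0]}, {"a": 0.0})


class TestGroupedDesign:
    def test_overlapping_gene_duplicated(self):
        expr = ps.ExpressionMatrix(["g1", "g2", "g3"], ["s1", "s2"],
                                   [[1, 2], [3, 4], [5, 6]])
        sets = GeneSetCollection({"P1": frozenset(["g1", "g2"]),
                                  "P2": frozenset(["g2", "g3"])})
        X, gs = build_grouped_design(expr, sets)
        assert list(X.columns) == ["P1::g1", "P1::g2", "P2::g2", "P2::g3"]
        np.testing.assert_array_equal(X["P1::g2"], X["P2::g2"])
        gs.validate_partition(4)


class TestFit:
    def test_lambda_max_gives_all_zero(self, survival_toy):
        X, t, e = survival_toy
        m = PenalizedCoxPH(X, t, e)
        res = m.fit(m.lambda_max())
        assert np.all(res.params.to_numpy() == 0)
        res2 = m.fit(m.lambda_max() * 0.98)
        assert np.any(res2.params.to_numpy() != 0)

    def test_unpenalized_matches_newton_oracle(self, survival_toy):
        lifelines = pytest.importorskip("lifelines")
        X, t, e = survival_toy
        res = PenalizedCoxPH(X, t, e).fit(0.0, tol=1e-10)
        df = pd.DataFrame(X, columns=res.params.index)
        df["T"], df["E"] = t, e
        oracle = lifelines.CoxPHFitter().fit(df, "T", "E").params_
        np.testing.assert_allclose(res.params.to_numpy(), oracle.to_numpy(),
                                   atol=1e-3)

    def test_singleton_groups_reduce_to_lasso(self, survival_toy):
        X, t, e = survival_toy
        gs = GroupStructure.singletons([f"x{i}" for i in range(X.shape[1])],
                                       weight=1.0)
        for lam in (0.08, 0.02):
            a = PenalizedCoxPH(X, t, e, penalty="lasso").fit(lam)
            b = PenalizedCoxPH(X, t, e, penalty="group", groups=gs).fit(lam)
            np.testing.assert_allclose(a.params.to_numpy(),
                                       b.params.to_numpy(), atol=1e-4)

    def test_objective_monotone_decreasing(self, survival_toy):
        X, t, e = survival_toy
        res = PenalizedCoxPH(X, t, e).fit(0.05)
        diffs = np.diff(res.objective_path)
        assert np.all(diffs <= 1e-12)

    def test_sample_permutation_invariance(self, survival_toy):
        X, t, e = survival_toy
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(t))
        a = PenalizedCoxPH(X, t, e).fit(0.05).params.to_numpy()
        b = PenalizedCoxPH(X[perm], t[perm], e[perm]).fit(0.05).params.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_kkt_conditions_hold(self, survival_toy):
        X, t, e = survival_toy
        res = PenalizedCoxPH(X, t, e).fit(0.05, tol=1e-10)
        assert res.kkt_violation() < 1e-5

    def test_group_sparsity_all_in_all_out(self):
        rng = np.random.default_rng(3)
        n, p = 150, 20
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:4] = [1.0, -0.8, 0.6, 0.5]
        t, e = make_survival(rng, n, X @ beta)
        gs = GroupStructure({f"g{k}": list(range(4 * k, 4 * k + 4))
                             for k in range(5)})
        res = PenalizedCoxPH(X, t, e, penalty="group", groups=gs).fit(0.1)
        b = res.params.to_numpy()
        for idx in gs.groups.values():
            block = b[idx]
            assert np.all(block == 0) or np.linalg.norm(block) > 0

    def test_zero_events_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError, match="event"):
            PenalizedCoxPH(X, np.arange(10.0), np.zeros(10, dtype=int))

    def test_squared_error_variant_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(4)
        n, p = 80, 6
        X = rng.standard_normal((n, p))
        y = X @ np.array([1.0, -0.5, 0, 0, 0.3, 0]) + rng.normal(0, 0.5, n)
        lam = 0.05
        mine = PenalizedCoxPH(X, y, loss="squared_error",
                              standardize=False).fit(lam, tol=1e-12)
        ref = sklearn.Lasso(alpha=lam, fit_intercept=True, tol=1e-12,
                            max_iter=100000).fit(X, y)
        np.testing.assert_allclose(mine.params.to_numpy(), ref.coef_, atol=1e-6)
        assert mine.intercept == pytest.approx(ref.intercept_, abs=1e-6)


class TestCV:
    def test_same_seed_same_folds_and_lambda(self, survival_toy):
        X, t, e = survival_toy
        m = PenalizedCoxPH(X, t, e)
        a = m.cv_lambda(n_lambda=20, seed=5)
        b = m.cv_lambda(n_lambda=20, seed=5)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2], b[2])

    def test_strong_signal_selected(self):
        rng = np.random.default_rng(6)
        n, p = 150, 10
        X = rng.standard_normal((n, p))
        t, e = make_survival(rng, n, 1.5 * X[:, 3])
        res = PenalizedCoxPH(X, t, e).fit_cv(n_lambda=30, seed=1)
        assert res.params.iloc[3] != 0

    def test_pure_noise_chooses_sparse_model(self):
        picked = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p = 150, 30
            X = rng.standard_normal((n, p))
            t, e = make_survival(rng, n)
            res = PenalizedCoxPH(X, t, e).fit_cv(n_lambda=30, seed=seed)
            if int((res.params != 0).sum()) <= 3:
                picked += 1
        assert picked >= 7

    def test_too_few_events_for_folds(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 3))
        t = np.arange(30.0) + 1
        e = np.zeros(30, dtype=int)
        e[:5] = 1
        with pytest.raises(ValueError, match="folds"):
            PenalizedCoxPH(X, t, e).cv_lambda(n_folds=10)


class TestPrediction:
    def test_linear_predictor_is_matrix_product(self):
        res = PenalizedCoxResults(
            params=pd.Series([0.5, -1.0], index=["a", "b"]), lam=0.0,
            penalty_kind="lasso", loss="cox", group_structure=None,
            standardization={})
        Xn = np.array([[1.0, 2.0], [0.0, 1.0], [3.0, 0.0]])
        np.testing.assert_allclose(res.predict_risk(Xn),
                                   Xn @ np.array([0.5, -1.0]))
        # a zeroed predictor never contributes
        Xn2 = Xn.copy()
        Xn2[:, 1] *= 2
        res.params.iloc[1] = 0.0
        np.testing.assert_allclose(res.predict_risk(Xn2), res.predict_risk(Xn))

    def test_survival_probability_contracts(self, survival_toy):
        X, t, e = survival_toy
        res = PenalizedCoxPH(X, t, e).fit(0.02)
        times = np.linspace(0, np.quantile(t, 0.9), 25)
        pi = res.predict_survival(X[:10], times)
        np.testing.assert_allclose(pi[:, 0], 1.0)  # H0(0) = 0
        assert np.all(np.diff(pi, axis=1) <= 1e-12)  # non-increasing in t
        assert np.all((pi >= 0) & (pi <= 1))
        # strongly protective profile approaches pi -> 1 everywhere
        x_safe = -50 * np.sign(res.params.to_numpy())[None, :]
        pi_safe = res.predict_survival(x_safe, times)
        assert np.all(pi_safe > 0.999)

    def test_baseline_extrapolation_warns(self, survival_toy):
        X, t, e = survival_toy
        res = PenalizedCoxPH(X, t, e).fit(0.02)
        with pytest.warns(UserWarning, match="extrapolat"):
            res.predict_survival(X[:2], [t.max() * 10])

    def test_feature_mismatch_error(self, survival_toy):
        X, t, e = survival_toy
        res = PenalizedCoxPH(X, t, e,
                             feature_names=["a", "b", "c", "d", "e"]).fit(0.1)
        bad = pd.DataFrame(np.zeros((2, 3)), columns=["a", "b", "zzz"])
        with pytest.raises(KeyError, match="absent"):
            res.predict_risk(bad)

    def test_json_round_trip_bitwise_predictions(self, survival_toy, tmp_path):
        X, t, e = survival_toy
        res = PenalizedCoxPH(X, t, e).fit(0.03)
        path = tmp_path / "m.json"
        res.save(path)
        back = PenalizedCoxResults.load(path)
        np.testing.assert_array_equal(back.predict_risk(X), res.predict_risk(X))
        times = np.linspace(0, t.max(), 7)
        np.testing.assert_array_equal(back.predict_survival(X[:5], times),
                                      res.predict_survival(X[:5], times))


class TestPathSolver:
    def test_screening_matches_direct_fits(self, survival_toy):
        X, t, e = survival_toy
        m = PenalizedCoxPH(X, t, e)
        grid = m.lambda_grid(12)
        betas = m._solve_path(grid)
        for i in (0, 4, 8, 11):
            direct = m.fit(grid[i], tol=1e-9)._beta_std
            np.testing.assert_allclose(betas[i], direct, atol=5e-4)
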
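import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import rankdata

from phylogrid import sdm
from phylogrid.grids import GridSpec, RasterStack
from phylogrid.sdm import (
    EvalMetrics,
    FeatureSpec,
    ModelSettings,
    PresenceBackgroundSDM,
    auc,
    build_features,
    evaluate_settings,
    fit_presence_background,
    partition_occurrences,
    select_model,
    settings_grid,
)


class TestFeatures:
    def test_settings_grid_size(self):
        assert len(settings_grid()) == 6 * 10

    def test_invalid_classes_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec(classes="LX")
        with pytest.raises(ValueError):
            FeatureSpec(classes="")
        with pytest.raises(ValueError):
            ModelSettings("L", rm=0.0)

    def test_linear_quadratic_columns(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        F, fmap = build_features(X, FeatureSpec(classes="LQ"))
        np.testing.assert_allclose(F[:, 0], X[:, 0])
        np.testing.assert_allclose(F[:, 1], X[:, 0] ** 2)
        assert fmap.feature_class == ["L", "Q"]

    def test_hinge_geometry(self):
        x = np.linspace(0.0, 1.0, 101)
        F, fmap = build_features(x.reshape(-1, 1), FeatureSpec(classes="H", n_hinge_knots=3))
        # forward and reverse hinges per knot, in [0, 1], hitting both ends
        assert F.shape[1] == 6
        assert F.min() == 0.0
        assert F.max() == pytest.approx(1.0)
        # forward hinge at knot k: zero below k, 1 at x_max
        k = fmap.knots[0][0]
        fwd = F[:, 0]
        assert np.all(fwd[x <= k] == 0.0)
        assert fwd[-1] == pytest.approx(1.0)

    def test_categorical_becomes_indicators(self):
        X = np.array([[0.0], [1.0], [2.0], [1.0]])
        F, fmap = build_features(X, FeatureSpec(classes="LQ"), categorical=(0,))
        assert F.shape == (4, 3)
        np.testing.assert_array_equal(F.sum(axis=1), 1.0)
        assert fmap.feature_class == ["C", "C", "C"]


class TestFit:
    def _toy(self, n_bg=200, seed=0):
        rng = np.random.default_rng(seed)
        bg = rng.normal(size=(n_bg, 1))
        pres = rng.normal(loc=1.0, scale=0.5, size=(30, 1))
        return pres, bg

    def test_one_covariate_matches_scalar_oracle(self):
        # independent check: optimize the penalized likelihood directly in
        # the single linear coefficient with a generic scalar minimizer
        pres, bg = self._toy()
        model = fit_presence_background(pres, bg, ModelSettings("L", 1.0))
        mu = np.vstack([pres, bg]).mean()
        sd = np.vstack([pres, bg]).std()
        zp = (pres[:, 0] - mu) / sd
        zb = (bg[:, 0] - mu) / sd
        lam = 1.0 / np.sqrt(len(pres))

        def obj(b):
            return -np.mean(zp * b) + logsumexp(zb * b) - np.log(len(zb)) + lam * abs(b)

        ref = minimize_scalar(obj, bounds=(-10, 10), method="bounded", options={"xatol": 1e-10})
        assert model.coef_[0] == pytest.approx(ref.x, abs=1e-4)

    def test_l1_drives_coefficients_to_zero(self):
        pres, bg = self._toy()
        strong = fit_presence_background(pres, bg, ModelSettings("LQ", 100.0))
        np.testing.assert_allclose(strong.coef_, 0.0, atol=1e-8)
        weak = fit_presence_background(pres, bg, ModelSettings("LQ", 0.5))
        assert np.abs(weak.coef_).max() > 0.1

    def test_monotone_suitability_in_informative_covariate(self):
        pres, bg = self._toy()
        model = fit_presence_background(pres, bg, ModelSettings("L", 1.0))
        x = np.linspace(-2, 2, 9).reshape(-1, 1)
        p = model.predict(x)
        assert np.all(np.diff(p) > 0)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_zero_variance_feature_gets_zero_coef(self):
        pres, bg = self._toy()
        pres2 = np.column_stack([pres, np.full(len(pres), 3.0)])
        bg2 = np.column_stack([bg, np.full(len(bg), 3.0)])
        model = fit_presence_background(pres2, bg2, ModelSettings("L", 1.0))
        assert model.coef_[1] == 0.0

    def test_logistic_output_and_unknown_output(self):
        pres, bg = self._toy()
        m = PresenceBackgroundSDM("L", 1.0, output="logistic")
        X = np.vstack([pres, bg])
        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        m.fit(X, y)
        p = m.predict(bg)
        assert ((p > 0) & (p < 1)).all()
        m.output = "nope"
        with pytest.raises(ValueError):
            m.predict(bg)

    def test_min_presence_enforced(self):
        pres, bg = self._toy()
        with pytest.raises(ValueError, match="presence"):
            fit_presence_background(pres[:2], bg, ModelSettings("L", 1.0))
        # but the CV path may lower the floor to 2
        fit_presence_background(pres[:2], bg, ModelSettings("L", 1.0), min_presence=2)

    def test_predict_grid_handles_missing_cells(self):
        pres, bg = self._toy()
        model = fit_presence_background(pres, bg, ModelSettings("L", 1.0))
        grid = GridSpec(0.0, 3.0, 1.0, 3, 3)
        stack = RasterStack(grid=grid)
        layer = np.linspace(-1, 1, 9).reshape(3, 3)
        layer[0, 0] = np.nan
        stack.add("env0", layer)
        out = model.predict_grid(stack)
        assert np.isnan(out[0, 0])
        assert np.isfinite(out).sum() == 8

    def test_deterministic_fit(self):
        pres, bg = self._toy()
        a = fit_presence_background(pres, bg, ModelSettings("LQH", 1.0)).coef_
        b = fit_presence_background(pres, bg, ModelSettings("LQH", 1.0)).coef_
        np.testing.assert_array_equal(a, b)


class TestAUC:
    def test_perfect_and_reverse(self):
        assert auc([2, 3], [0, 1]) == 1.0
        assert auc([0, 1], [2, 3]) == 0.0

    def test_ties_count_half(self):
        assert auc([1.0], [1.0]) == 0.5

    def test_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos = rng.integers(0, 5, size=rng.integers(1, 10)).astype(float)
            neg = rng.integers(0, 5, size=rng.integers(1, 10)).astype(float)
            brute = np.mean(
                [
                    1.0 if p > n else (0.5 if p == n else 0.0)
                    for p in pos
                    for n in neg
                ]
            )
            assert auc(pos, neg) == pytest.approx(brute, abs=1e-12)


class TestPartition:
    def test_jackknife_for_small_samples(self):
        lon = np.array([0.0, 1.0, 2.0, 3.0])
        lat = np.array([0.0, 1.0, 2.0, 3.0])
        folds = partition_occurrences(lon, lat, np.zeros(5), np.zeros(5))
        assert len(folds) == 4
        for i, f in enumerate(folds):
            assert list(f["test_p"]) == [i]
            assert len(f["train_p"]) == 3
            assert len(f["train_bg"]) == 5

    def test_spatial_blocks_partition_presences(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(0, 10, 40)
        lat = rng.uniform(0, 10, 40)
        bg_lon = rng.uniform(0, 10, 100)
        bg_lat = rng.uniform(0, 10, 100)
        folds = partition_occurrences(lon, lat, bg_lon, bg_lat)
        assert len(folds) == 4
        test_union = np.sort(np.concatenate([f["test_p"] for f in folds]))
        np.testing.assert_array_equal(test_union, np.arange(40))
        for f in folds:
            assert set(f["test_p"]).isdisjoint(f["train_p"])
            assert set(f["test_bg"]).isdisjoint(f["train_bg"])
            assert len(f["test_bg"]) + len(f["train_bg"]) == 100

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            partition_occurrences([0, 1], [0, 1], [0], [0])


class TestEvaluateAndSelect:
    def _metrics(self, **kw):
        base = dict(or_mtp=0.1, auc_diff=0.05, auc_test=0.8, auc_train=0.85, n_folds=4)
        base.update(kw)
        return EvalMetrics(**base)

    def test_evaluate_settings_on_separable_data(self):
        rng = np.random.default_rng(1)
        pres = rng.normal(3.0, 0.3, size=(10, 1))
        bg = rng.normal(0.0, 1.0, size=(200, 1))
        folds = partition_occurrences(
            pres[:, 0], pres[:, 0], bg[:, 0], bg[:, 0]
        )
        m = evaluate_settings(pres, bg, ModelSettings("L", 1.0), folds)
        assert m.auc_test > 0.9
        assert m.n_folds == 10
        assert 0.0 <= m.or_mtp <= 1.0

    def test_select_min_or_then_min_diff_then_max_auc(self):
        s1, s2, s3 = ModelSettings("L", 1.0), ModelSettings("Q", 1.0), ModelSettings("H", 1.0)
        res = {
            s1: self._metrics(or_mtp=0.2),
            s2: self._metrics(or_mtp=0.1, auc_diff=0.10),
            s3: self._metrics(or_mtp=0.1, auc_diff=0.02),
        }
        assert select_model(res) == s3
        res = {
            s1: self._metrics(auc_test=0.7),
            s2: self._metrics(auc_test=0.9),
        }
        assert select_model(res) == s2

    def test_select_filters_on_auc_then_falls_back(self):
        s1, s2 = ModelSettings("L", 1.0), ModelSettings("Q", 1.0)
        res = {
            s1: self._metrics(or_mtp=0.0, auc_test=0.5),  # best OR but filtered out
            s2: self._metrics(or_mtp=0.3, auc_test=0.9),
        }
        assert select_model(res) == s2
        allbad = {
            s1: self._metrics(or_mtp=0.0, auc_test=0.5),
            s2: self._metrics(or_mtp=0.3, auc_test=0.55),
        }
        with pytest.warns(UserWarning, match="full candidate set"):
            assert select_model(allbad) == s1

    def test_residual_tie_prefers_simpler_class_then_larger_rm(self):
        tie = self._metrics()
        res = {
            ModelSettings("LQH", 1.0): tie,
            ModelSettings("L", 1.0): tie,
            ModelSettings("H", 1.0): tie,
        }
        assert select_model(res).feature_classes == "H"
        res = {ModelSettings("L", 0.5): tie, ModelSettings("L", 3.0): tie}
        assert select_model(res).rm == 3.0

    @given(st.permutations(list(range(8))))
    def test_selection_is_order_invariant(self, perm):
        rng = np.random.default_rng(7)
        grid = settings_grid(("L", "Q"), (0.5, 1.0, 2.0, 4.0))
        metrics = [
            self._metrics(
                or_mtp=round(float(rng.choice([0.0, 0.1, 0.2])), 3),
                auc_diff=round(float(rng.uniform(0, 0.2)), 3),
                auc_test=round(float(rng.uniform(0.5, 1.0)), 3),
            )
            for _ in grid
        ]
        items = list(zip(grid, metrics))
        shuffled = [items[i] for i in perm]
        assert select_model(dict(items)) == select_model(dict(shuffled))


class TestBiasAndBackground:
    def _env(self, n=20, seed=0):
        grid = GridSpec(0.0, float(n), 1.0, n, n)
        stack = RasterStack(grid=grid)
        rng = np.random.default_rng(seed)
        stack.add("env0", rng.standard_normal((n, n)))
        return stack

    def test_bias_layer_highlights_sampled_environments(self):
        env = self._env()
        # points only where env0 is high
        rows, cols = np.nonzero(env["env0"] > 1.0)
        lon, lat = env.grid.cell_center(rows, cols)
        import pandas as pd

        occ = pd.DataFrame({"species": "x", "lon": lon, "lat": lat})
        bias = sdm.make_bias_layer(occ, env, seed=0, n_background=500)
        hi = bias[env["env0"] > 1.0].mean()
        lo = bias[env["env0"] < -1.0].mean()
        assert hi > lo

    def test_bias_needs_ten_points(self):
        import pandas as pd

        env = self._env()
        occ = pd.DataFrame({"species": "x", "lon": [0.5] * 5, "lat": [0.5] * 5})
        with pytest.raises(ValueError, match="10"):
            sdm.make_bias_layer(occ, env, seed=0)

    def test_background_follows_bias_weights(self):
        env = self._env()
        bias = np.zeros(env.grid.shape)
        bias[:, :10] = 1.0  # west half only
        bg = sdm.sample_background(bias, env, n=500, seed=1)
        assert (bg.cols < 10).all()
        assert bg.env.shape == (500, 1)

    def test_background_rejects_zero_bias(self):
        env = self._env()
        with pytest.raises(ValueError):
            sdm.sample_background(np.zeros(env.grid.shape), env, n=10, seed=0)
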
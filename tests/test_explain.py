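"""Shapley attribution: exactness, sampling tolerance, global summaries."""

import itertools
import math

import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor

from millet_nirs import explain as expl
from millet_nirs import model as mod


def brute_force_shapley(predict, x, background):
    """Interventional Shapley values by full coalition enumeration.

    v(S) averages the model over background rows with the features in S
    switched to x's values; phi_j is the Shapley-weighted average of
    marginal contributions over all 2^(d-1) coalitions excluding j.
    """
    background = np.asarray(background, dtype=float)
    d = x.size

    def value(coalition):
        Z = np.repeat(background.copy(), 1, axis=0)
        Z[:, list(coalition)] = x[list(coalition)]
        return float(np.mean(predict(Z)))

    phi = np.zeros(d)
    others = list(range(d))
    for j in range(d):
        rest = [k for k in others if k != j]
        for r in range(d):
            for S in itertools.combinations(rest, r):
                w = math.factorial(len(S)) * math.factorial(d - len(S) - 1) / math.factorial(d)
                phi[j] += w * (value(S + (j,)) - value(S))
    return phi


class _Linear:
    def __init__(self, beta, intercept=0.0):
        self.beta = np.asarray(beta, dtype=float)
        self.intercept = intercept

    def predict(self, X):
        return np.asarray(X) @ self.beta + self.intercept


class TestLinearShap:
    def test_closed_form_and_additivity(self):
        rng = np.random.default_rng(0)
        model = _Linear([2.0, -1.0, 0.0], intercept=5.0)
        bg = rng.standard_normal((30, 3))
        X = rng.standard_normal((10, 3))
        shap = expl.shap_linear(model, X, bg)
        mu = bg.mean(axis=0)
        assert np.allclose(shap.values, (X - mu) * model.beta, atol=1e-10)
        # dummy feature gets exactly zero
        assert np.allclose(shap.values[:, 2], 0.0)
        # additivity: base + row sum reproduces the prediction
        recon = shap.base_value + shap.values.sum(axis=1)
        assert np.max(np.abs(recon - model.predict(X))) < 1e-10

    def test_unit_shift_attribution(self):
        model = _Linear([2.0])
        bg = np.zeros((5, 1))
        shap = expl.shap_linear(model, np.array([[1.0]]), bg)
        assert shap.values[0, 0] == pytest.approx(2.0)

    def test_works_on_fitted_pls_pipeline(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.05, 50)
        m = mod.fit(mod.ModelSpec(family="PLS", seed=0), X, y)
        shap = expl.shap_linear(m, X[:10], X)
        recon = shap.base_value + shap.values.sum(axis=1)
        assert np.max(np.abs(recon - m.predict(X[:10]))) < 1e-8

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            expl.shap_linear(_Linear([1.0]), np.ones((2, 1)), np.empty((0, 1)))


class TestSampledShap:
    def test_single_feature_stump_matches_brute_force_exactly(self):
        rng = np.random.default_rng(2)
        Xtr = rng.standard_normal((40, 1))
        ytr = (Xtr[:, 0] > 0).astype(float)
        tree = RandomForestRegressor(n_estimators=1, max_depth=1, random_state=0)
        tree.fit(Xtr, ytr)
        bg = Xtr[:8]
        X = Xtr[10:14]
        # permutation budget a multiple of the background size makes the
        # cycled background average exact for a single feature
        shap = expl.shap_tree(tree, X, bg, n_permutations=16, seed=0)
        for i in range(X.shape[0]):
            exact = brute_force_shapley(tree.predict, X[i], bg)
            assert np.allclose(shap.values[i], exact, atol=1e-12)

    def test_three_feature_model_within_one_percent(self):
        rng = np.random.default_rng(3)
        Xtr = rng.standard_normal((80, 3))
        ytr = Xtr[:, 0] * 2 - Xtr[:, 1] + 0.5 * Xtr[:, 0] * Xtr[:, 2]
        rf = RandomForestRegressor(n_estimators=30, random_state=0).fit(Xtr, ytr)
        bg = Xtr[:10]
        X = Xtr[20:24]
        shap = expl.shap_tree(rf, X, bg, n_permutations=600, seed=1)
        scale = np.abs(rf.predict(Xtr)).mean()
        for i in range(X.shape[0]):
            exact = brute_force_shapley(rf.predict, X[i], bg)
            assert np.max(np.abs(shap.values[i] - exact)) <= 0.01 * max(scale, 1.0)

    def test_constant_model_attributes_nothing(self):
        class Const:
            def predict(self, X):
                return np.full(len(X), 3.74)

        rng = np.random.default_rng(4)
        shap = expl.shap_tree(Const(), rng.random((5, 3)), rng.random((6, 3)),
                              n_permutations=10, seed=0)
        assert np.allclose(shap.values, 0.0)
        assert shap.base_value == pytest.approx(3.74)

    def test_duplicated_features_share_attribution(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(200)
        Xtr = np.column_stack([z, z])

        model = _Linear([1.0, 1.0])
        bg = Xtr[:20]
        shap = expl.shap_tree(model, Xtr[50:70], bg, n_permutations=200, seed=2)
        mean_abs = np.abs(shap.values).mean(axis=0)
        assert mean_abs[0] == pytest.approx(mean_abs[1], rel=0.1)

    def test_additivity_within_tolerance_at_default_budget(self):
        rng = np.random.default_rng(6)
        Xtr = rng.standard_normal((60, 4))
        ytr = Xtr[:, 0] - Xtr[:, 2] ** 2
        rf = RandomForestRegressor(n_estimators=20, random_state=0).fit(Xtr, ytr)
        shap = expl.shap_tree(rf, Xtr[:6], Xtr, n_permutations=200, seed=3)
        recon = shap.base_value + shap.values.sum(axis=1)
        pred = rf.predict(Xtr[:6])
        denom = max(np.abs(pred).max(), 1.0)
        assert np.max(np.abs(recon - pred)) / denom <= 0.01

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        model = _Linear([1.0, 2.0])
        X, bg = rng.random((4, 2)), rng.random((6, 2))
        a = expl.shap_tree(model, X, bg, n_permutations=20, seed=5)
        b = expl.shap_tree(model, X, bg, n_permutations=20, seed=5)
        assert np.array_equal(a.values, b.values)


class TestSummaries:
    @staticmethod
    def _matrix(rows, names=None):
        rows = np.asarray(rows, dtype=float)
        names = names or [f"f{j}" for j in range(rows.shape[1])]
        return expl.ShapMatrix(values=rows, base_value=0.0, feature_names=names)

    def test_hand_counted_coverage(self):
        shap = self._matrix([[50.0, -30.0, 15.0, 5.0]])
        report = expl.summarize(shap)
        assert np.allclose(report.contribution_rate, [50, 30, 15, 5])
        assert report.k80 == 2 and report.k95 == 3
        assert np.all(np.diff(report.cumulative_rate) >= -1e-12)
        assert report.cumulative_rate[-1] == pytest.approx(100.0)

    def test_single_feature_full_rate(self):
        report = expl.summarize(self._matrix([[0.2], [-0.4]]))
        assert report.contribution_rate[0] == pytest.approx(100.0)
        assert report.k80 == report.k95 == 1

    def test_sign_of_mean_effect_preserved(self):
        report = expl.summarize(self._matrix([[1.0, -2.0], [3.0, -1.0]]))
        assert report.mean_signed[0] > 0 > report.mean_signed[1]

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            expl.summarize(self._matrix([[0.0, 0.0]]))

    def test_rates_sum_to_100_on_random_attributions(self):
        rng = np.random.default_rng(8)
        report = expl.summarize(self._matrix(rng.standard_normal((20, 13))))
        assert report.contribution_rate.sum() == pytest.approx(100.0)


class TestDependenceProfiles:
    def test_linear_model_profile_is_monotone(self):
        rng = np.random.default_rng(9)
        model = _Linear([2.0, -1.0])
        X = rng.standard_normal((30, 2))
        shap = expl.shap_linear(model, X, X)
        for feature, sign in (("f0", 1), ("f1", -1)):
            profile = expl.dependence_profile(shap, X, feature)
            assert profile["monotone"]
            assert profile["spearman_rho"] == pytest.approx(sign * 1.0)

    def test_constant_model_profile_is_flat(self):
        shap = expl.ShapMatrix(
            values=np.zeros((8, 2)), base_value=1.0, feature_names=("f0", "f1")
        )
        profile = expl.dependence_profile(shap, np.random.default_rng(0).random((8, 2)), "f0")
        assert np.allclose(profile["shap"], 0.0)
        assert not profile["monotone"]

    def test_v_shaped_response_flagged_non_monotone(self):
        rng = np.random.default_rng(10)
        Xtr = rng.uniform(-2, 2, size=(300, 1))
        ytr = (Xtr[:, 0] - Xtr[:, 0].mean()) ** 2
        rf = RandomForestRegressor(n_estimators=30, random_state=0).fit(Xtr, ytr)
        shap = expl.shap_tree(rf, Xtr[:40], Xtr[:50], n_permutations=50, seed=4)
        profile = expl.dependence_profile(shap, Xtr[:40], "f0")
        assert not profile["monotone"]

    def test_unknown_feature(self):
        shap = expl.ShapMatrix(values=np.ones((2, 1)), base_value=0.0, feature_names=("f0",))
        with pytest.raises(KeyError):
            expl.dependence_profile(shap, np.ones((2, 1)), "f9")
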
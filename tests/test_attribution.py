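"""Shapley attributions: exact oracle, sampled mode, ranking, dependence trends."""

import numpy as np
import pytest

from photoscreen import classify as C
from photoscreen import descriptors as D
from photoscreen.attribution import (
    AttributionError,
    dependence_profile,
    rank_features,
    shapley_attributions,
)


class TestExactMode:
    def test_constant_model_all_zero(self, rng):
        bg = rng.normal(size=(10, 5))
        attr = shapley_attributions(lambda X: np.full(len(X), 0.7), bg, bg[:3], mode="exact")
        assert np.allclose(attr.values, 0.0)
        assert attr.base_value == pytest.approx(0.7)

    def test_linear_model_closed_form(self, rng):
        # for a linear model with an interventional background,
        # phi_i = beta_i * (x_i - mean_i(background))
        d = 7
        beta = rng.normal(size=d)
        bg = rng.normal(size=(40, d))
        x = rng.normal(size=(3, d))
        attr = shapley_attributions(lambda X: X @ beta + 2.0, bg, x, mode="exact")
        expected = beta * (x - bg.mean(axis=0))
        assert np.abs(attr.values - expected).max() < 1e-6

    def test_additivity(self, rng):
        d = 6
        bg = rng.normal(size=(20, d))
        x = rng.normal(size=(4, d))
        f = lambda X: np.tanh(X[:, 0] * X[:, 1]) + X[:, 2] ** 2  # noqa: E731
        attr = shapley_attributions(f, bg, x, mode="exact")
        assert np.all(attr.additivity_residual(f(x)) < 1e-6)

    def test_symmetry_of_interchangeable_features(self, rng):
        # f treats features 0 and 1 identically; their phi must be equal
        # whenever x_0 == x_1 and the background is exchangeable in them
        bg = np.tile(rng.normal(size=(25, 1)), (1, 3))
        x = np.array([[1.3, 1.3, -0.2]])
        f = lambda X: X[:, 0] + X[:, 1] + 0.5 * X[:, 2]  # noqa: E731
        attr = shapley_attributions(f, bg, x, mode="exact")
        assert attr.values[0, 0] == pytest.approx(attr.values[0, 1], abs=1e-9)

    def test_null_player_gets_zero(self, rng):
        bg = rng.normal(size=(15, 4))
        x = rng.normal(size=(2, 4))
        f = lambda X: X[:, 0] ** 2  # features 1..3 ignored
        attr = shapley_attributions(f, bg, x, mode="exact")
        assert np.allclose(attr.values[:, 1:], 0.0, atol=1e-12)

    def test_refuses_high_dimension(self, rng):
        bg = rng.normal(size=(5, 16))
        with pytest.raises(AttributionError, match="15"):
            shapley_attributions(lambda X: X[:, 0], bg, bg[:1], mode="exact")

    def test_empty_background_rejected(self):
        with pytest.raises(AttributionError):
            shapley_attributions(lambda X: X[:, 0], np.empty((0, 3)), np.zeros((1, 3)))


class TestSampledMode:
    def test_matches_exact_on_toy_model(self, rng):
        # ~10k coalition evaluations: 1667 permutations x 6 features
        d = 6
        bg = rng.normal(size=(25, d))
        x = rng.normal(size=(2, d))
        f = lambda X: np.sin(X[:, 0]) + X[:, 1] * X[:, 2] - 0.3 * X[:, 4]  # noqa: E731
        exact = shapley_attributions(f, bg, x, mode="exact")
        sampled = shapley_attributions(f, bg, x, mode="sampled", n_permutations=1667, seed=0)
        assert np.abs(sampled.values - exact.values).max() <= 0.02

    def test_additivity_holds_at_any_sample_size(self, rng):
        d = 5
        bg = rng.normal(size=(10, d))
        x = rng.normal(size=(3, d))
        f = lambda X: X[:, 0] * X[:, 3]  # noqa: E731
        attr = shapley_attributions(f, bg, x, mode="sampled", n_permutations=3, seed=1)
        assert np.all(attr.additivity_residual(f(x)) < 1e-10)

    def test_seeded_reproducibility(self, rng):
        bg = rng.normal(size=(10, 4))
        x = rng.normal(size=(2, 4))
        f = lambda X: X.sum(axis=1)  # noqa: E731
        a = shapley_attributions(f, bg, x, mode="sampled", n_permutations=10, seed=9)
        b = shapley_attributions(f, bg, x, mode="sampled", n_permutations=10, seed=9)
        assert np.array_equal(a.values, b.values)


class TestRankFeatures:
    def test_planted_s1_t1_signal_ranks_top(self, fitted_svm, rng):
        # the fixture's label rule lives in S1 and T1, so the trained
        # margin model's attributions should put them among the leaders
        bg = fitted_svm["X_train"][rng.choice(len(fitted_svm["X_train"]), 25, replace=False)]
        attr = shapley_attributions(
            fitted_svm["model"],
            bg,
            fitted_svm["X_test"],
            mode="sampled",
            n_permutations=20,
            seed=0,
            feature_names=D.FEATURE_NAMES,
        )
        top3 = rank_features(attr)[:3]
        assert "S1" in top3 and "T1" in top3

    def test_all_zero_preserves_input_order(self):
        from photoscreen.attribution import AttributionSet

        attr = AttributionSet(np.zeros((4, 3)), 0.0, ["a", "b", "c"])
        assert rank_features(attr) == ["a", "b", "c"]

    def test_invariant_to_record_order(self, rng):
        from photoscreen.attribution import AttributionSet

        vals = rng.normal(size=(10, 5))
        names = list("abcde")
        a = rank_features(AttributionSet(vals, 0.0, names))
        b = rank_features(AttributionSet(vals[::-1], 0.0, names))
        assert a == b


class TestDependenceProfile:
    def test_constant_phi_flat_trend(self):
        x = np.linspace(0, 1, 100)
        table, _ = dependence_profile(x, np.full(100, 0.25), bins=5)
        assert np.allclose(table["mean_phi"], 0.25)
        assert np.allclose(table["sd_phi"], 0.0)

    def test_decreasing_signal_gives_decreasing_trend(self, rng):
        # mirrors the attribution trend decreasing in S1
        x = rng.uniform(1.5, 3.5, 400)
        phi = -0.4 * x + rng.normal(0, 0.01, 400)
        table, _ = dependence_profile(x, phi, bins=8)
        trend = table["mean_phi"]
        assert np.all(np.diff(trend[~np.isnan(trend)]) < 0)

    def test_u_shape_has_single_interior_minimum(self, rng):
        # mirrors the U-shaped attribution trend in T1
        x = rng.uniform(0.8, 2.8, 600)
        phi = (x - 1.8) ** 2 + rng.normal(0, 0.005, 600)
        table, _ = dependence_profile(x, phi, bins=9)
        trend = table["mean_phi"]
        interior_min = int(np.nanargmin(trend))
        assert 0 < interior_min < len(trend) - 1
        # single sign change in the first difference
        signs = np.sign(np.diff(trend))
        changes = np.count_nonzero(np.diff(signs[signs != 0]) != 0)
        assert changes == 1

    def test_cutoff_reported_inside_range(self, rng):
        x = rng.uniform(0, 1, 300)
        phi = np.where(x < 0.5, 0.3, -0.3) + rng.normal(0, 0.01, 300)
        _, cutoff = dependence_profile(x, phi, bins=10)
        assert cutoff is not None and 0 < cutoff < 1

    def test_fewer_points_than_bins_rejected(self):
        with pytest.raises(AttributionError):
            dependence_profile(np.arange(5), np.arange(5), bins=10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AttributionError):
            dependence_profile(np.arange(10), np.arange(9), bins=3)
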
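import numpy as np
import pytest
from scipy import integrate, stats

from cnvsift.classifiers import (
    RFConfig,
    RandomForestClassifier,
    SELU_ALPHA,
    SELU_LAMBDA,
    SNNClassifier,
    SNNConfig,
    SeluParams,
    alpha_dropout,
    init_weights,
    selu,
    selu_moments,
    solve_selu_fixed_point,
)
from cnvsift.evaluation import confusion_from_predictions, cross_validate, mcc
from cnvsift.synth import SyntheticSpec, generate_dataset


class TestSelu:
    def test_zero_is_fixed(self):
        assert selu(0.0) == 0.0

    def test_positive_branch_is_scaled_identity(self):
        assert selu(1.0) == pytest.approx(1.0507, abs=1e-4)

    def test_negative_saturation_limit(self):
        # lim_{x -> -inf} selu(x) = -lambda * alpha
        assert selu(-50.0) == pytest.approx(-SELU_LAMBDA * SELU_ALPHA, abs=1e-10)
        assert selu(-50.0) == pytest.approx(-1.7581, abs=1e-4)

    def test_continuous_at_zero(self):
        assert selu(-1e-12) == pytest.approx(selu(1e-12), abs=1e-10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SeluParams(0.9, 1.6)


class TestFixedPoint:
    def test_constants_to_four_decimals(self):
        p = solve_selu_fixed_point()
        assert round(p.lam, 4) == 1.0507
        assert round(p.alpha, 4) == 1.6733

    def test_moments_vanish_at_solution(self):
        p = solve_selu_fixed_point()
        m1, m2 = selu_moments(p.lam, p.alpha)
        assert abs(m1) < 1e-9
        assert abs(m2 - 1.0) < 1e-9

    def test_closed_forms_match_quadrature_oracle(self):
        """Closed-form moments equal direct numerical integration."""
        p = SeluParams(1.05, 1.67)

        def integrand(z, power):
            return selu(z, p) ** power * stats.norm.pdf(z)

        for power, closed in zip((1, 2), selu_moments(p.lam, p.alpha)):
            quad, _ = integrate.quad(integrand, -12, 12, args=(power,))
            assert closed == pytest.approx(quad, abs=1e-8)

    def test_only_unit_fixed_point_supported(self):
        with pytest.raises(ValueError):
            solve_selu_fixed_point(0.0, 2.0)


class TestInitWeights:
    def test_variance_is_one_over_fan_in(self):
        rng = np.random.default_rng(0)
        w = init_weights(10000, 4, rng)
        assert w.var() == pytest.approx(1 / 10000, rel=0.05)

    def test_mean_near_zero(self):
        rng = np.random.default_rng(1)
        w = init_weights(10000, 4, rng)
        se = np.sqrt(1 / 10000 / w.size)
        assert abs(w.mean()) < 3 * se

    def test_seeded_determinism(self):
        a = init_weights(50, 3, np.random.default_rng(5))
        b = init_weights(50, 3, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestAlphaDropout:
    def test_rate_zero_is_identity(self):
        x = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_array_equal(alpha_dropout(x, 0.0, training=True), x)

    def test_inference_is_identity(self):
        x = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_array_equal(alpha_dropout(x, 0.3, training=False), x)

    def test_moments_preserved(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1_000_000)
        out = alpha_dropout(x, 0.1, rng=rng, training=True)
        assert abs(out.mean()) < 0.01
        assert abs(out.var() - 1.0) < 0.02

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            alpha_dropout(np.zeros(3), 1.0, rng=np.random.default_rng(0))


class TestSelfNormalizingProperty:
    def test_one_layer_preserves_moments(self):
        """SELU layer with 1/n init keeps activations near (0, 1)."""
        rng = np.random.default_rng(3)
        n, width = 100_000, 200
        X = rng.standard_normal((n, width))
        W = init_weights(width, width, rng)
        acts = selu(X @ W)
        assert abs(acts.mean()) < 0.05
        assert abs(acts.var() - 1.0) < 0.1


def _snn_cfg(**kw):
    defaults = dict(epochs=60, seed=0)
    defaults.update(kw)
    return SNNConfig(**defaults)


class TestSNN:
    def test_fits_linearly_separable_data(self):
        spec = SyntheticSpec(
            n_case=100, n_control=100, n_probes=5, n_informative=2,
            effect_size=0.5, noise_sd=0.05, seed=0,
        )
        ds, _ = generate_dataset(spec)
        model = SNNClassifier(_snn_cfg()).fit(ds.X, ds.y)
        assert mcc(confusion_from_predictions(ds.y, model.predict(ds.X))) == 1.0

    def test_null_labels_give_null_cv_mcc(self):
        rng = np.random.default_rng(1)
        spec = SyntheticSpec(
            n_case=80, n_control=80, n_probes=10, n_informative=0,
            effect_size=0.0, seed=1,
        )
        ds, _ = generate_dataset(spec)
        mccs = []
        for seed in range(5):
            y = rng.permutation(ds.y)
            res = cross_validate(
                ds.X, y,
                lambda s: SNNClassifier(_snn_cfg(epochs=30, seed=s)),
                k=10, seed=seed,
            )
            mccs.append(res.mcc)
        assert abs(np.mean(mccs)) < 0.15

    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_case=40, n_control=40, n_probes=8, n_informative=2, seed=2)
        ds, _ = generate_dataset(spec)
        a = SNNClassifier(_snn_cfg(epochs=20)).fit(ds.X, ds.y).predict_scores(ds.X)
        b = SNNClassifier(_snn_cfg(epochs=20)).fit(ds.X, ds.y).predict_scores(ds.X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            SNNClassifier(_snn_cfg()).fit(np.zeros((10, 2)), np.zeros(10, dtype=int))

    def test_default_architecture(self):
        cfg = SNNConfig()
        assert cfg.hidden_layers == 3
        assert cfg.hidden_width == 200


class TestRandomForest:
    def test_single_tree_forest_equals_its_tree(self):
        from cnvsift import trees as tr

        spec = SyntheticSpec(n_case=30, n_control=30, n_probes=6, n_informative=2, seed=3)
        ds, _ = generate_dataset(spec)
        model = RandomForestClassifier(RFConfig(n_trees=1, seed=0)).fit(ds.X, ds.y)
        pred_forest = model.predict(ds.X)
        pred_tree, _ = tr.predict_batch(model.trees_[0], ds.X)
        np.testing.assert_array_equal(pred_forest, pred_tree)

    def test_separating_feature_perfect_training_mcc(self, separable_xy):
        X, y = separable_xy
        model = RandomForestClassifier(RFConfig(n_trees=100, seed=1)).fit(X, y)
        assert mcc(confusion_from_predictions(y, model.predict(X))) == 1.0

    def test_vote_fraction_is_exact_share(self):
        spec = SyntheticSpec(n_case=30, n_control=30, n_probes=6, n_informative=2, seed=4)
        ds, _ = generate_dataset(spec)
        model = RandomForestClassifier(RFConfig(n_trees=7, seed=0)).fit(ds.X, ds.y)
        from cnvsift import trees as tr

        votes = np.sum(
            [tr.predict_batch(t, ds.X)[0] == 1 for t in model.trees_], axis=0
        )
        np.testing.assert_allclose(model.predict_scores(ds.X), votes / 7)

    def test_tie_votes_go_negative(self):
        spec = SyntheticSpec(n_case=30, n_control=30, n_probes=6, n_informative=2, seed=4)
        ds, _ = generate_dataset(spec)
        model = RandomForestClassifier(RFConfig(n_trees=2, seed=0)).fit(ds.X, ds.y)
        scores = model.predict_scores(ds.X)
        pred = model.predict(ds.X)
        assert (pred[scores == 0.5] == 0).all()

    def test_invalid_tree_count_rejected(self):
        with pytest.raises(ValueError):
            RFConfig(n_trees=0)
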
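import numpy as np
import pytest

from gamnn import (
    FeatureSchema,
    FeatureSpec,
    GamnnConfig,
    build_model,
    contributions_table,
    feature_contribution,
    forward_logit,
    predict_proba,
    sigmoid,
)
from gamnn.model import GamnnModel
from gamnn.schema import Dataset, SchemaError

from conftest import random_model_params


class TestBuildModel:
    def test_architecture_shapes(self, mixed_schema):
        m = build_model(mixed_schema, GamnnConfig(seed=0, layer_size=50, n_hidden_layers=1))
        assert m.params["hW0"].shape == (3, 1, 50)  # one subnetwork per continuous
        assert m.params["V"].shape == (3, 50)
        assert m.params["w"].shape == (5,)  # one logistic weight per feature
        assert m.params["b0"].shape == ()

    def test_deeper_subnetworks(self, mixed_schema):
        m = build_model(mixed_schema, GamnnConfig(seed=0, n_hidden_layers=3, layer_size=10))
        assert m.params["hW1"].shape == (3, 10, 10)
        assert m.params["hW2"].shape == (3, 10, 10)

    def test_same_seed_bit_identical(self, mixed_schema):
        a = build_model(mixed_schema, GamnnConfig(seed=42))
        b = build_model(mixed_schema, GamnnConfig(seed=42))
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_binary_only_model_is_a_logistic_regression(self):
        schema = FeatureSchema(
            (FeatureSpec("P", "binary"), FeatureSpec("Q", "binary")), "y"
        )
        m = build_model(schema, GamnnConfig(seed=1))
        m.params["w"] = np.array([0.5, -1.2])
        m.params["b0"] = np.asarray(0.3)
        for x in ([0, 0], [1, 0], [0, 1], [1, 1]):
            x = np.asarray(x, dtype=float)
            expected = 0.3 + 0.5 * x[0] - 1.2 * x[1]
            assert forward_logit(m, x) == pytest.approx(expected, abs=1e-12)
            assert predict_proba(m, x) == pytest.approx(sigmoid(expected), abs=1e-12)


class TestForward:
    def test_fresh_model_outputs_intercept_only(self, mixed_schema):
        # shapes start exactly flat (zero bottleneck projection), so the
        # logit is the intercept for any input
        m = build_model(mixed_schema, GamnnConfig(seed=3))
        m.params["b0"] = np.asarray(0.3)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 5))
        X[:, 3:] = 0.0
        assert np.allclose(m.forward_logits(X), 0.3, atol=1e-12)

    def test_binary_contribution_equals_weight_times_input(self):
        schema = FeatureSchema((FeatureSpec("ART_LINE_YN", "binary"),), "y")
        m = build_model(schema, GamnnConfig(seed=0))
        m.params["w"] = np.array([0.993])
        m.params["b0"] = np.asarray(0.0)
        assert forward_logit(m, np.array([1.0])) == pytest.approx(0.993)
        assert feature_contribution(m, np.array([1.0]), "ART_LINE_YN") == pytest.approx(0.993)
        assert feature_contribution(m, np.array([0.0]), "ART_LINE_YN") == 0.0

    def test_dimension_mismatch_rejected(self, mixed_schema):
        m = build_model(mixed_schema, GamnnConfig(seed=0))
        with pytest.raises(ValueError):
            m.forward_logits(np.zeros((2, 3)))

    def test_missing_input_rejected(self, mixed_schema):
        m = build_model(mixed_schema, GamnnConfig(seed=0))
        X = np.zeros((1, 5))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            m.forward_logits(X)

    def test_probability_monotone_in_logit(self, mixed_schema):
        m = build_model(mixed_schema, GamnnConfig(seed=5))
        random_model_params(m, np.random.default_rng(5))
        X = np.random.default_rng(6).normal(size=(20, 5))
        logits = m.forward_logits(X)
        probs = sigmoid(logits)
        assert np.array_equal(np.argsort(logits), np.argsort(probs))
        assert sigmoid(0.0) == 0.5
        assert sigmoid(50.0) >= 1 - 1e-20


class TestAdditivity:
    def test_contributions_sum_to_logit_over_random_models(self, mixed_schema):
        """intercept + sum of per-feature contributions reconstructs the
        forward logit for arbitrary weights and inputs (100 seeds)."""
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = build_model(mixed_schema, GamnnConfig(seed=seed))
            random_model_params(m, rng)
            X = rng.normal(size=(8, 5))
            X[:, 3:] = (rng.random((8, 2)) < 0.5).astype(float)
            C, logits = m.contributions(X)
            resid = np.abs(float(m.params["b0"]) + C.sum(axis=1) - logits)
            worst = max(worst, resid.max())
        assert worst < 1e-6

    def test_continuous_contribution_strictly_inside_weight_band(self, mixed_schema):
        rng = np.random.default_rng(1)
        m = build_model(mixed_schema, GamnnConfig(seed=1))
        random_model_params(m, rng, scale=2.0)
        X = rng.normal(size=(50, 5), scale=3.0)
        C, _ = m.contributions(X)
        for j in m.cont_idx:
            w = abs(m.params["w"][j])
            # mathematically strict (|tanh| < 1); float tanh saturates to
            # exactly 1.0 for large inputs, hence <=
            assert (np.abs(C[:, j]) <= w).all()

    def test_permutation_equivariance(self):
        """Permuting schema order together with input columns (and the
        per-feature parameter blocks) leaves every logit unchanged."""
        rng = np.random.default_rng(9)
        specs = (
            FeatureSpec("A", "continuous"),
            FeatureSpec("B", "continuous"),
            FeatureSpec("C", "binary"),
        )
        schema = FeatureSchema(specs, "y")
        m = build_model(schema, GamnnConfig(seed=9, layer_size=10))
        random_model_params(m, rng)
        X = rng.normal(size=(12, 3))
        X[:, 2] = (rng.random(12) < 0.5).astype(float)
        base = m.forward_logits(X)

        perm_schema = FeatureSchema((specs[1], specs[0], specs[2]), "y")
        m2 = build_model(perm_schema, GamnnConfig(seed=9, layer_size=10))
        for l in ("hW0", "hb0"):
            m2.params[l] = m.params[l][[1, 0]]
        m2.params["V"] = m.params["V"][[1, 0]]
        m2.params["c"] = m.params["c"][[1, 0]]
        m2.params["w"] = m.params["w"][[1, 0, 2]]
        m2.params["b0"] = m.params["b0"]
        assert np.allclose(m2.forward_logits(X[:, [1, 0, 2]]), base, atol=1e-12)


class TestContributionTable:
    def test_single_sample_consistency(self, mixed_schema):
        rng = np.random.default_rng(2)
        m = build_model(mixed_schema, GamnnConfig(seed=2))
        random_model_params(m, rng)
        x = rng.normal(size=5)
        ds = Dataset(x[None, :], np.array([1]), mixed_schema.feature_names)
        table = contributions_table(m, ds)
        assert table.logits[0] == pytest.approx(forward_logit(m, x), abs=1e-9)
        total = table.intercept + table.contributions.sum()
        assert total == pytest.approx(table.logits[0], abs=1e-6)

    def test_unknown_feature_name(self, mixed_schema, small_dataset):
        m = build_model(mixed_schema, GamnnConfig(seed=0))
        with pytest.raises(SchemaError):
            feature_contribution(m, small_dataset.values[0], "NOPE")
        table = contributions_table(m, small_dataset)
        with pytest.raises(SchemaError):
            table.column("NOPE")


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Analytic backprop equals central finite differences through the
        full architecture (2 hidden layers, mixed feature kinds)."""
        schema = FeatureSchema(
            (
                FeatureSpec("A", "continuous"),
                FeatureSpec("B", "continuous"),
                FeatureSpec("C", "binary"),
            ),
            "y",
        )
        cfg = GamnnConfig(seed=3, n_hidden_layers=2, layer_size=6, dropout_p=0.0, l2_lambda=0.0)
        m = build_model(schema, cfg)
        random_model_params(m, np.random.default_rng(3), scale=0.5)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        X[:, 2] = rng.integers(0, 2, 5)
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])

        def loss():
            p = sigmoid(m.forward_logits(X))
            return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))

        def dlogit_fn(logit):
            return (sigmoid(logit) - y) / len(y)

        _, grads = m.forward_backward(X, dlogit_fn, training=False)
        eps = 1e-6
        for k, arr in m.params.items():
            flat = np.atleast_1d(arr).ravel()
            gf = np.atleast_1d(grads[k]).ravel()
            idxs = rng.choice(len(flat), min(len(flat), 12), replace=False)
            for i in idxs:
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert gf[i] == pytest.approx(num, rel=1e-4, abs=1e-8), k


class TestSerialization:
    def test_save_load_predicts_identically(self, mixed_schema, tmp_path):
        rng = np.random.default_rng(4)
        m = build_model(mixed_schema, GamnnConfig(seed=4))
        random_model_params(m, rng)
        p = tmp_path / "model.json"
        m.save(p)
        m2 = GamnnModel.load(p)
        X = rng.normal(size=(10, 5))
        assert np.array_equal(m.forward_logits(X), m2.forward_logits(X))
        assert m2.config.to_dict() == m.config.to_dict()

    def test_load_rejects_foreign_files(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            GamnnModel.load(p)


class TestConfig:
    def test_table_defaults(self):
        cfg = GamnnConfig()
        assert (cfg.n_hidden_layers, cfg.layer_size) == (1, 50)
        assert cfg.hidden_activation == "tanh"
        assert (cfg.dropout_p, cfg.l2_lambda) == (0.5, 0.0001)
        assert cfg.positive_class_weight == 100.0
        assert (cfg.batch_size, cfg.max_epochs) == (256, 100)
        assert cfg.in_grid()

    def test_free_form_values_allowed_but_flagged_off_grid(self):
        cfg = GamnnConfig(layer_size=33, dropout_p=0.1)
        assert not cfg.in_grid()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hidden_activation="sigmoid"),
            dict(dropout_p=1.0),
            dict(positive_class_weight=0.0),
            dict(n_hidden_layers=0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GamnnConfig(**kwargs)
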
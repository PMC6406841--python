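import numpy as np
import pytest

from bioword.classifier import (
    ClassifierError,
    ConvFilter,
    _batch_loss_and_grads,
    build_classifier,
    conv_feature_map,
    load_model,
    make_pair_feature,
    max_pool,
    predict_pairs,
    save_model,
    train_classifier,
)

TINY_TOPOLOGY = (((3, 3), (2, 3)), ((3, 5),), ((3, 7),))


def _separable_features(n, dim, seed):
    """Labeled pair features whose classes sit on opposite sides of a plane."""
    rng = np.random.default_rng(seed)
    half = dim // 2
    feats = []
    for label in (1, 0):
        center = 1.0 if label else -1.0
        for _ in range(n // 2):
            x = rng.normal(center, 1.0, size=dim)
            feats.append(make_pair_feature(x[:half], x[half:], label))
    order = rng.permutation(len(feats))
    return [feats[i] for i in order]


class TestConvFeatureMap:
    def test_length_law(self):
        filt = ConvFilter(np.ones(2), 0.0, "relu")
        fm = conv_feature_map(np.arange(5.0), filt)
        assert len(fm) == 5 - 2 + 1

    def test_zero_filter_relu_gives_zero_map(self):
        filt = ConvFilter(np.zeros(3), 0.0, "relu")
        np.testing.assert_array_equal(conv_feature_map(np.ones(6), filt),
                                      np.zeros(4))

    def test_identity_filter_hand_dot_products(self):
        filt = ConvFilter(np.array([1.0, 1.0]), 0.0, "identity")
        np.testing.assert_allclose(
            conv_feature_map(np.array([1.0, 2.0, 3.0]), filt), [3.0, 5.0]
        )

    def test_window_longer_than_input_rejected(self):
        with pytest.raises(ClassifierError, match="window"):
            conv_feature_map(np.ones(2), ConvFilter(np.ones(3), 0.0))

    @pytest.mark.parametrize("K,h", [(5, 2), (10, 7), (8, 8), (20, 1)])
    def test_length_law_parametrized(self, K, h):
        fm = conv_feature_map(np.arange(float(K)),
                              ConvFilter(np.ones(h), 0.5, "tanh"))
        assert len(fm) == K - h + 1


class TestMaxPool:
    def test_examples(self):
        assert max_pool(np.array([3.0, 5.0])) == 5.0
        assert max_pool(np.array([2.0, 2.0, 2.0])) == 2.0

    def test_random_map_matches_exhaustive_maximum(self):
        rng = np.random.default_rng(1)
        fm = rng.normal(size=37)
        assert max_pool(fm) == max(float(v) for v in fm)

    def test_empty_map_rejected(self):
        with pytest.raises(ClassifierError):
            max_pool(np.array([]))


class TestArchitecture:
    def test_subnet_widths_and_penultimate_dimension(self):
        model = build_classifier(64)
        assert model.subnet_widths == (64, 32, 128)
        assert model.penultimate_width == 224

    def test_forward_yields_probabilities(self):
        model = build_classifier(32, random_seed=1)
        X = np.random.default_rng(0).normal(size=(7, 32))
        probs = model.predict_proba(X)
        assert probs.shape == (7,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_input_shorter_than_largest_window_rejected(self):
        with pytest.raises(ClassifierError, match="window"):
            build_classifier(5)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        model = build_classifier(12, dropout_rate=0.0, random_seed=2,
                                 subnet_widths=(4, 3, 5), topology=TINY_TOPOLOGY)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 12))
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        _batch_loss_and_grads(model, X, y, train=False, rng=None)
        grads = [g.copy() for _, g in model._params()]
        eps = 1e-6
        for (param, _), grad in zip(model._params(), grads):
            flat = param.reshape(-1)
            gflat = grad.reshape(-1)
            # spot-check a deterministic subset of each tensor
            for idx in range(0, flat.size, max(1, flat.size // 7)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = _batch_loss_and_grads(model, X, y, train=False, rng=None)
                flat[idx] = orig - eps
                lm = _batch_loss_and_grads(model, X, y, train=False, rng=None)
                flat[idx] = orig
                assert gflat[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


class TestTraining:
    def test_learns_separable_data(self):
        feats = _separable_features(400, 16, seed=4)
        model = train_classifier(feats[:300], feats[300:], max_epochs=40,
                                 patience=8, random_seed=0)
        probs = predict_pairs(model, feats[300:])
        labels = np.array([f.label for f in feats[300:]])
        acc = np.mean((probs >= 0.5) == labels)
        assert acc >= 0.95

    def test_loss_descends_after_first_epoch(self):
        feats = _separable_features(200, 16, seed=5)
        model = train_classifier(feats[:150], feats[150:], max_epochs=3,
                                 patience=3, random_seed=0)
        losses = model.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_identical_seed_identical_trajectory(self):
        feats = _separable_features(120, 16, seed=6)
        m1 = train_classifier(feats[:90], feats[90:], max_epochs=5,
                              patience=5, random_seed=9)
        m2 = train_classifier(feats[:90], feats[90:], max_epochs=5,
                              patience=5, random_seed=9)
        assert m1.history["val_loss"] == m2.history["val_loss"]

    def test_single_class_training_set_rejected(self):
        feats = [make_pair_feature(np.ones(4), np.zeros(4), 1) for _ in range(10)]
        with pytest.raises(ClassifierError, match="single class"):
            train_classifier(feats, feats, max_epochs=1)

    def test_dimension_mismatch_rejected(self):
        tr = _separable_features(40, 16, seed=7)
        va = _separable_features(40, 24, seed=7)
        with pytest.raises(ClassifierError, match="dimension"):
            train_classifier(tr, va, max_epochs=1)


@pytest.fixture(scope="module")
def trained():
    feats = _separable_features(200, 16, seed=8)
    model = train_classifier(feats[:150], feats[150:], max_epochs=10,
                             patience=5, random_seed=1)
    return model, feats


class TestInference:
    def test_one_probability_per_pair_within_unit_interval(self, trained):
        model, feats = trained
        probs = predict_pairs(model, feats[:37])
        assert probs.shape == (37,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_inference_is_deterministic_despite_dropout(self, trained):
        model, feats = trained
        repeated = [feats[0], feats[0]]
        p = predict_pairs(model, repeated)
        assert p[0] == p[1]
        again = predict_pairs(model, repeated)
        np.testing.assert_array_equal(p, again)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        model, feats = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(predict_pairs(back, feats[:10]),
                                   predict_pairs(model, feats[:10]))
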
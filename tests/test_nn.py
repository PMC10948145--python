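"""Conv-Transformer network and estimator."""

import numpy as np
import pytest

from apodetect.nn import (
    Adam,
    ConvTransformerClassifier,
    ConvTransformerNet,
    ModelConfig,
    TrainConfig,
)
from apodetect.nn._layers import _softmax_lastaxis

TINY = ModelConfig(clip_len=3, input_size=9, conv_widths=(2, 3), token_dim=4,
                   n_heads=2, n_attention_blocks=1, mlp_widths=(5,),
                   conv_dropout=0.0, mlp_dropout=0.0, attn_dropout=0.0)


class TestNetwork:
    def test_analytic_gradients_match_finite_differences(self):
        net = ConvTransformerNet(TINY, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.random((3, 3, 9, 9))
        y = np.array([0, 1, 1])

        def loss():
            logits = net.forward(x, train=True)
            p = _softmax_lastaxis(logits)
            return -np.log(p[np.arange(3), y]).mean()

        net.loss_and_grad(x, y)
        eps = 1e-6
        checked = 0
        for key, lyr in net.parameters():
            for name, p in lyr.params.items():
                flat, g = p.ravel(), np.asarray(lyr.grads[name]).ravel()
                for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                    old = flat[i]
                    flat[i] = old + eps
                    lp = loss()
                    flat[i] = old - eps
                    lm = loss()
                    flat[i] = old
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - g[i]) <= 1e-4 * max(1.0, abs(fd), abs(g[i]))
                    checked += 1
        assert checked > 20

    def test_softmax_outputs_are_probabilities(self, rng):
        net = ConvTransformerNet(ModelConfig.small(), seed=0)
        x = rng.random((4, 5, 59, 59), dtype=np.float32)
        p = net.predict_proba(x)
        assert p.shape == (4, 2)
        assert (p >= 0).all() and (p <= 1).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic_and_batch_invariant(self, rng):
        net = ConvTransformerNet(ModelConfig.small(), seed=0)
        x = rng.random((2, 5, 59, 59), dtype=np.float32)
        doubled = np.concatenate([x, x])
        p1 = net.predict_proba(doubled)
        p2 = net.predict_proba(doubled)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1[:2], p1[2:], atol=1e-6)

    def test_parameter_count_grows_with_attention_depth(self):
        small = ConvTransformerNet(ModelConfig(conv_widths=(2, 3), token_dim=8,
                                               n_heads=2, n_attention_blocks=1,
                                               mlp_widths=(4,)), seed=0)
        deep = ConvTransformerNet(ModelConfig(conv_widths=(2, 3), token_dim=8,
                                              n_heads=2, n_attention_blocks=4,
                                              mlp_widths=(4,)), seed=0)
        assert deep.n_parameters() > small.n_parameters()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(token_dim=10, n_heads=3)
        with pytest.raises(ValueError, match="below 1"):
            ModelConfig(input_size=8, conv_widths=(2, 2, 2, 2))


def _separable_dataset(rng, n=60, K=5):
    """Class 1 brightens over time, class 0 stays flat."""
    X = rng.random((n, K, 59, 59), dtype=np.float32) * 0.2
    y = rng.integers(0, 2, n)
    ramp = np.linspace(0, 0.6, K)[None, :, None, None]
    X[y == 1] += ramp
    return X, y


class TestEstimator:
    def test_memorizes_a_small_training_set(self, rng):
        X, y = _separable_dataset(rng, n=50)
        clf = ConvTransformerClassifier(
            model_config=ModelConfig(conv_widths=(2, 4), token_dim=8, n_heads=2,
                                     n_attention_blocks=1, mlp_widths=(16,),
                                     conv_dropout=0.0, mlp_dropout=0.0,
                                     attn_dropout=0.0),
            train_config=TrainConfig(lr=3e-3, epochs=40, patience=40,
                                     augment=False),
            random_state=0)
        # validate on the training set itself: the checkpoint then tracks
        # memorization rather than a 6-sample validation split
        clf.fit(X, y, X_val=X, y_val=y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_checkpoint_has_best_validation_accuracy(self, rng):
        X, y = _separable_dataset(rng, n=80)
        clf = ConvTransformerClassifier(
            model_config=ModelConfig(conv_widths=(2, 4), token_dim=8, n_heads=2,
                                     n_attention_blocks=1, mlp_widths=(16,)),
            train_config=TrainConfig(lr=1e-3, epochs=8, patience=8),
            random_state=0)
        clf.fit(X, y)
        assert clf.history_.val_acc.iloc[clf.best_epoch_] == clf.history_.val_acc.max()

    def test_early_stopping_halts_training(self, rng):
        # unlearnable labels: validation accuracy cannot improve for long
        X = rng.random((60, 5, 59, 59), dtype=np.float32)
        y = rng.integers(0, 2, 60)
        clf = ConvTransformerClassifier(
            model_config=ModelConfig(conv_widths=(2,), token_dim=4, n_heads=2,
                                     n_attention_blocks=1, mlp_widths=(4,)),
            train_config=TrainConfig(lr=1e-4, epochs=60, patience=3,
                                     augment=False),
            random_state=0)
        clf.fit(X, y)
        assert clf.n_epochs_run_ < 60

    def test_training_is_reproducible(self, rng):
        X, y = _separable_dataset(rng, n=40)
        kw = dict(
            model_config=ModelConfig(conv_widths=(2, 4), token_dim=8, n_heads=2,
                                     n_attention_blocks=1, mlp_widths=(8,)),
            train_config=TrainConfig(lr=1e-3, epochs=4, patience=4),
            random_state=3)
        a = ConvTransformerClassifier(**kw).fit(X, y)
        b = ConvTransformerClassifier(**kw).fit(X, y)
        assert a.history_.equals(b.history_)

    def test_save_load_roundtrip(self, rng, tmp_path):
        X, y = _separable_dataset(rng, n=40)
        clf = ConvTransformerClassifier(
            model_config=ModelConfig(conv_widths=(2, 4), token_dim=8, n_heads=2,
                                     n_attention_blocks=1, mlp_widths=(8,)),
            train_config=TrainConfig(lr=1e-3, epochs=2, patience=2),
            random_state=0).fit(X, y)
        p = tmp_path / "model.npz"
        clf.save(p)
        back = ConvTransformerClassifier.load(p)
        np.testing.assert_allclose(back.predict_proba(X), clf.predict_proba(X),
                                   atol=1e-6)

    def test_single_class_training_warns(self, rng):
        X = rng.random((20, 5, 59, 59), dtype=np.float32)
        y = np.zeros(20, dtype=int)
        clf = ConvTransformerClassifier(
            model_config=ModelConfig(conv_widths=(2,), token_dim=4, n_heads=2,
                                     n_attention_blocks=1, mlp_widths=(4,)),
            train_config=TrainConfig(epochs=1))
        with pytest.warns(UserWarning, match="single-class"):
            clf.fit(X, y)

    def test_sklearn_params_protocol(self):
        clf = ConvTransformerClassifier(random_state=7)
        params = clf.get_params()
        assert params["random_state"] == 7
        clf.set_params(random_state=9)
        assert clf.random_state == 9
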
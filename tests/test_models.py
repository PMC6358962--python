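import dataclasses

import numpy as np
import pytest

from ppgpain import models


def _blobs(n=120, d=4, gap=2.0, seed=0, classes=2):
    """Well-separated Gaussian blobs squashed into [0, 1]."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(classes):
        center = np.full(d, 0.5) + (c - (classes - 1) / 2) * gap / (classes * 4)
        X.append(center + rng.normal(0, 0.05, size=(n // classes, d)))
        y.append(np.full(n // classes, c))
    X = np.clip(np.concatenate(X), 0, 1)
    return X, np.concatenate(y)


SMALL = models.NetConfig(layer_sizes=(4, 6, 6, 2), batch_size=20,
                         epochs_pretrain=5, epochs_finetune=150, seed=3)


class TestRBMPretrain:
    def test_zero_epochs_is_a_noop_with_empty_trace(self):
        X, _ = _blobs()
        cfg = dataclasses.replace(SMALL, epochs_pretrain=0)
        rbms, traces = models.rbm_pretrain(X, cfg)
        assert traces == [[], []]
        ref = models.RBM(4, 6, cfg, np.random.default_rng(cfg.seed))
        np.testing.assert_array_equal(rbms[0].W, ref.W)

    def test_fixed_seed_reproduces_traces(self):
        X, _ = _blobs()
        _, t1 = models.rbm_pretrain(X, SMALL)
        _, t2 = models.rbm_pretrain(X, SMALL)
        assert t1 == t2

    def test_reconstruction_error_decreases(self):
        # a learning rate slow enough that convergence spans many epochs
        # makes the decreasing trend observable at epoch 20 vs epoch 1
        X, _ = _blobs(n=200)
        cfg = dataclasses.replace(SMALL, epochs_pretrain=20, lr_weights=0.01,
                                  lr_vbias=0.01, lr_hbias=0.01)
        _, traces = models.rbm_pretrain(X, cfg)
        for trace in traces:
            assert trace[19] <= trace[0]

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            models.rbm_pretrain(np.full((10, 4), 5.0), SMALL)


class TestFinetuneAndMLPNN:
    @pytest.mark.parametrize("train", [models.train_dbn, models.train_mlpnn])
    def test_separable_toy_reaches_full_training_accuracy(self, train):
        X, y = _blobs(gap=4.0)
        net = train(X, y, SMALL)
        assert np.mean(net.predict(X) == y) == 1.0

    def test_loss_trend_is_decreasing(self):
        X, y = _blobs()
        net = models.train_mlpnn(X, y, SMALL)
        trace = np.array(net.loss_trace)
        k = len(trace) // 3
        assert trace[-k:].mean() < trace[:k].mean()

    def test_four_class_output_layer(self):
        X, y = _blobs(n=200, gap=6.0, classes=4)
        cfg = dataclasses.replace(SMALL, layer_sizes=(4, 6, 6, 4),
                                  epochs_finetune=300)
        net = models.train_dbn(X, y, cfg)
        assert net.predict_scores(X).shape == (200, 4)
        assert np.mean(net.predict(X) == y) > 0.9

    def test_scores_sum_to_one(self):
        X, y = _blobs()
        net = models.train_mlpnn(X, y, SMALL)
        np.testing.assert_allclose(net.predict_scores(X).sum(axis=1), 1.0)

    def test_label_cardinality_mismatch_rejected(self):
        X, y = _blobs(classes=2)
        cfg = dataclasses.replace(SMALL, layer_sizes=(4, 6, 6, 3))
        with pytest.raises(ValueError, match="classes"):
            models.train_mlpnn(X, y, cfg)

    def test_dbn_equals_mlpnn_under_forced_initialization(self):
        # the two trainers differ only in initialization: injecting the
        # DBN's post-pretraining weights into the MLPNN trainer reproduces
        # the fine-tuning trajectory exactly
        X, y = _blobs()
        rbms, _ = models.rbm_pretrain(X, SMALL)
        probe = models.NeuralNetClassifier(config=SMALL)
        probe.init_from_rbms(rbms, np.random.default_rng(SMALL.seed + 1))
        init = ([W.copy() for W in probe.weights], [b.copy() for b in probe.biases])

        dbn = models.train_dbn(X, y, SMALL)
        mlp = models.train_mlpnn(X, y, dataclasses.replace(SMALL, seed=SMALL.seed + 1),
                                 init_weights=init)
        np.testing.assert_allclose(dbn.loss_trace, mlp.loss_trace)
        for Wd, Wm in zip(dbn.weights, mlp.weights):
            np.testing.assert_allclose(Wd, Wm)

    def test_xor_solvable_with_two_hidden_layers(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        cfg = models.NetConfig(layer_sizes=(2, 6, 6, 2), lr_weights=0.5,
                               lr_vbias=0.5, lr_hbias=0.5, batch_size=4,
                               momentum=0.9, weight_decay=0.0, init_scale=0.5,
                               epochs_finetune=3000, seed=1)
        net = models.train_mlpnn(X, y, cfg)
        assert np.mean(net.predict(X) == y) == 1.0

    def test_json_roundtrip(self):
        X, y = _blobs()
        net = models.train_mlpnn(X, y, SMALL)
        back = models.NeuralNetClassifier.from_json(net.to_json(), SMALL)
        np.testing.assert_array_equal(net.predict(X), back.predict(X))


class TestSVM:
    def test_defaults_match_reference_configuration(self):
        cfg = models.SVMConfig()
        assert cfg.gamma == 0.05 and cfg.C == 1.0

    def test_separated_clusters_reach_full_training_accuracy(self):
        X, y = _blobs(gap=6.0)
        svm = models.train_svm(X, y)
        assert np.mean(svm.predict(X) == y) == 1.0

    def test_vanishing_gamma_underfits_nonlinear_data(self, rng):
        # circular two-class layout: tiny gamma collapses toward the
        # majority rule while the reference gamma separates it well
        n = 200
        radius = np.concatenate([rng.uniform(0, 0.3, n), rng.uniform(0.6, 1.0, n)])
        theta = rng.uniform(0, 2 * np.pi, 2 * n)
        X = 0.5 + 0.5 * np.column_stack([radius * np.cos(theta),
                                         radius * np.sin(theta)])
        y = np.repeat([0, 1], n)
        tiny = models.train_svm(X, y, models.SVMConfig(gamma=1e-4))
        ref = models.train_svm(X, y, models.SVMConfig(gamma=50.0))
        assert np.mean(ref.predict(X) == y) > 0.95
        assert np.mean(tiny.predict(X) == y) < np.mean(ref.predict(X) == y) - 0.2

    def test_scores_sum_to_one_binary_and_multiclass(self):
        for classes in (2, 3):
            X, y = _blobs(n=90, gap=6.0, classes=classes)
            svm = models.train_svm(X, y)
            np.testing.assert_allclose(svm.predict_scores(X).sum(axis=1), 1.0,
                                       atol=1e-9)

    def test_single_class_input_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError, match="two classes"):
            models.train_svm(X, np.zeros(10))
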
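import itertools

import numpy as np
import pytest

from ppgpain import ensemble as ens


class FixedModel:
    """Base-classifier stub with predetermined predictions per input row id."""

    def __init__(self, preds, score_strength=1.0, classes=(0, 1)):
        self.preds = np.asarray(preds)
        self.classes = np.asarray(classes)
        self.strength = score_strength

    def predict(self, X):
        return self.preds[np.asarray(X, dtype=int).ravel()]

    def predict_scores(self, X):
        p = self.predict(X)
        scores = np.full((len(p), len(self.classes)),
                         (1 - self.strength) / (len(self.classes) - 1))
        for i, label in enumerate(p):
            scores[i, list(self.classes).index(label)] = self.strength
        return scores


def _ensemble(models):
    return ens.EnsembleModel(base_models=list(models), classes_=np.array([0, 1]))


class TestBootstrap:
    def test_single_row_sample_is_that_row(self, rng):
        assert ens.bootstrap_sample(1, rng).tolist() == [0]

    def test_expected_unique_fraction_approaches_632(self):
        fractions = [
            np.unique(ens.bootstrap_sample(2000, np.random.default_rng(s))).size / 2000
            for s in range(30)
        ]
        assert np.mean(fractions) == pytest.approx(1 - 1 / np.e, abs=0.01)

    def test_seeded_reproducibility(self):
        a = ens.bootstrap_sample(50, np.random.default_rng(5))
        b = ens.bootstrap_sample(50, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestMajorityVote:
    def test_simple_majority(self):
        preds = np.array([["A"], ["A"], ["B"]])
        assert ens.majority_vote(preds).tolist() == ["A"]

    def test_tie_broken_by_summed_score(self):
        preds = np.array([[0], [1]])
        scores = np.array([[[0.6, 0.4]], [[0.1, 0.9]]])  # class 1 scores higher
        assert ens.majority_vote(preds, scores).tolist() == [1]

    def test_tie_without_scores_takes_lowest_class_index(self):
        preds = np.array([[0], [1]])
        assert ens.majority_vote(preds, classes=np.array([0, 1])).tolist() == [0]

    def test_unanimous(self):
        preds = np.full((7, 3), "P")
        assert ens.majority_vote(preds).tolist() == ["P"] * 3

    def test_permutation_invariance(self, rng):
        preds = rng.integers(0, 2, size=(9, 20))
        out = ens.majority_vote(preds)
        perm = rng.permutation(9)
        np.testing.assert_array_equal(ens.majority_vote(preds[perm]), out)


class TestBagTrain:
    @staticmethod
    def _trainer(X, y, seed=0):
        from ppgpain.models import SVMConfig, train_svm
        return train_svm(X, y, SVMConfig(gamma=1.0))

    def test_bag_counts_and_determinism(self, rng):
        X = rng.random((40, 3))
        y = (X[:, 0] > 0.5).astype(int)
        a = ens.bag_train(self._trainer, X, y, n_bags=5, seed=2)
        b = ens.bag_train(self._trainer, X, y, n_bags=5, seed=2)
        assert a.n_bags == 5
        assert a.bag_seeds == b.bag_seeds
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_identical_rows_give_identical_predictions(self):
        X = np.tile([[0.2, 0.8]], (30, 1)) + np.repeat([[0.0], [0.5]], 15, axis=0)
        y = np.repeat([0, 1], 15)
        bag = ens.bag_train(self._trainer, X, y, n_bags=4, seed=0)
        stacked = np.stack([m.predict(X) for m in bag.base_models])
        assert (stacked == stacked[0]).all()

    def test_trainer_failure_is_annotated(self):
        def bad_trainer(X, y, seed=0):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="base classifier 0"):
            ens.bag_train(bad_trainer, np.zeros((5, 2)), np.zeros(5), n_bags=1)


class TestHillClimbSelection:
    def _validation(self, n=30):
        X = np.arange(n, dtype=float).reshape(-1, 1)
        y = np.tile([0, 1], n // 2)
        return X, y

    def test_single_base_model_is_selected(self):
        X, y = self._validation()
        model = _ensemble([FixedModel(y)])
        assert ens.hc_select(model, X, y) == [0]

    def test_perfect_model_dominates_random_ones(self, rng):
        X, y = self._validation()
        perfect = FixedModel(y)
        rand1 = FixedModel(rng.integers(0, 2, len(y)))
        rand2 = FixedModel(rng.integers(0, 2, len(y)))
        model = _ensemble([rand1, perfect, rand2])
        selected = ens.hc_select(model, X, y)
        assert 1 in selected
        acc = np.mean(model.predict(X) == y)
        assert acc == 1.0

    def test_selection_never_below_best_single(self, rng):
        X, y = self._validation(40)
        for seed in range(8):
            r = np.random.default_rng(seed)
            bases = [FixedModel(np.where(r.random(len(y)) < p, y, 1 - y))
                     for p in (0.9, 0.7, 0.6, 0.5, 0.5)]
            model = _ensemble(bases)
            singles = [np.mean(b.predict(X) == y) for b in bases]
            ens.hc_select(model, X, y)
            assert np.mean(model.predict(X) == y) >= max(singles)

    def test_greedy_close_to_exhaustive_on_small_bags(self, rng):
        # across simulation seeds, greedy selection recovers on average at
        # least 95% of the exhaustive-best subset's validation accuracy
        X, y = self._validation(40)
        ratios = []
        for seed in range(6):
            r = np.random.default_rng(100 + seed)
            bases = [FixedModel(np.where(r.random(len(y)) < p, y, 1 - y))
                     for p in (0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5)]
            model = _ensemble(bases)
            ens.hc_select(model, X, y)
            greedy_acc = np.mean(model.predict(X) == y)
            best = 0.0
            for k in range(1, len(bases) + 1):
                for subset in itertools.combinations(range(len(bases)), k):
                    model.selected = list(subset)
                    best = max(best, np.mean(model.predict(X) == y))
            assert greedy_acc >= 0.9 * best
            ratios.append(greedy_acc / best)
        assert np.mean(ratios) >= 0.95

    def test_empty_validation_rejected(self):
        model = _ensemble([FixedModel(np.array([0, 1]))])
        with pytest.raises(ValueError, match="empty"):
            ens.hc_select(model, np.empty((0, 1)), np.empty(0))
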
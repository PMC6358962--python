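"""Bootstrap bagging with majority voting and hill-climbing selective bagging.

Bagging trains ``n_bags`` (default 50) base classifiers on bootstrap
resamples of the training set (with replacement, same size) and combines
their predictions by majority vote; 50-50 ties break by the larger summed
class score, then by the lower class index. Selective bagging prunes the bag
by greedy forward hill climbing on validation accuracy: start from the best
single base model and repeatedly add the model whose inclusion most improves
the majority-vote validation accuracy, stopping when no addition helps. The
selected ensemble's validation accuracy is therefore never below the best
single base model's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnsembleModel", "bootstrap_sample", "bag_train", "majority_vote",
           "hc_select"]


def bootstrap_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a bootstrap resample (with replacement) of size ``n``."""
    if n < 1:
        raise ValueError("cannot bootstrap an empty training set")
    return rng.integers(0, n, size=n)


def majority_vote(
    predictions: np.ndarray,
    scores: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> np.ndarray:
    """Modal label per row of ``predictions`` (models x rows).

    ``scores`` (models x rows x classes), if given, breaks vote ties by the
    largest summed class score; remaining ties break by the lowest class
    index. ``classes`` fixes the class ordering (default: sorted unique
    labels).
    """
    preds = np.asarray(predictions)
    if preds.ndim != 2 or preds.shape[0] < 1:
        raise ValueError("predictions must be a (models x rows) array")
    if classes is None:
        classes = np.unique(preds)
    n_models, n_rows = preds.shape
    counts = np.stack([(preds == c).sum(axis=0) for c in classes], axis=1)

    if scores is not None:
        summed = np.asarray(scores).sum(axis=0)  # rows x classes
    else:
        summed = np.zeros((n_rows, len(classes)))
    # lexicographic argmax: vote count, then summed score, then low index
    best = np.zeros(n_rows, dtype=int)
    for j in range(1, len(classes)):
        better = (counts[:, j] > counts[np.arange(n_rows), best]) | (
            (counts[:, j] == counts[np.arange(n_rows), best])
            & (summed[:, j] > summed[np.arange(n_rows), best])
        )
        best = np.where(better, j, best)
    return np.asarray(classes)[best]


@dataclass
class EnsembleModel:
    """Bag of trained base classifiers with an optional selected subset."""

    base_models: list = field(default_factory=list)
    bag_seeds: list[int] = field(default_factory=list)
    selected: list[int] | None = None
    classes_: np.ndarray | None = None

    @property
    def n_bags(self) -> int:
        return len(self.base_models)

    def _active(self) -> list:
        if self.selected is None:
            return self.base_models
        return [self.base_models[i] for i in self.selected]

    def _stack(self, X: np.ndarray, models: list) -> tuple[np.ndarray, np.ndarray]:
        preds = np.stack([m.predict(X) for m in models])
        scores = np.stack([m.predict_scores(X) for m in models])
        return preds, scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds, scores = self._stack(X, self._active())
        return majority_vote(preds, scores, classes=self.classes_)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Mean of the active base models' class scores (rows sum to 1)."""
        _, scores = self._stack(X, self._active())
        return scores.mean(axis=0)


def bag_train(
    trainer,
    X: np.ndarray,
    y: np.ndarray,
    n_bags: int = 50,
    seed: int = 0,
) -> EnsembleModel:
    """Train ``n_bags`` base models on independent bootstrap replicates.

    ``trainer(X, y, seed) -> model`` must be deterministic given its seed.
    A trainer failure is re-raised annotated with the offending bag index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    model = EnsembleModel(classes_=np.unique(y))
    for b in range(n_bags):
        idx = bootstrap_sample(len(y), rng)
        bag_seed = int(rng.integers(0, 2**31 - 1))
        try:
            base = trainer(X[idx], y[idx], bag_seed)
        except Exception as exc:  # noqa: BLE001 - annotate and propagate
            raise RuntimeError(f"base classifier {b} failed to train") from exc
        model.base_models.append(base)
        model.bag_seeds.append(bag_seed)
    return model


def hc_select(
    model: EnsembleModel,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> list[int]:
    """Greedy forward hill climbing over the bag on validation accuracy.

    Starts from the single best base model; each step adds the base model
    (best-improvement, lowest index on ties) whose inclusion most increases
    the majority-vote validation accuracy, stopping when no addition strictly
    improves. Stores and returns the selected indices.
    """
    y_val = np.asarray(y_val)
    if y_val.size == 0:
        raise ValueError("validation set is empty")
    preds, scores = model._stack(np.asarray(X_val, float), model.base_models)

    def acc(subset: list[int]) -> float:
        fused = majority_vote(preds[subset], scores[subset], classes=model.classes_)
        return float(np.mean(fused == y_val))

    singles = [acc([i]) for i in range(model.n_bags)]
    selected = [int(np.argmax(singles))]
    current = singles[selected[0]]
    remaining = set(range(model.n_bags)) - set(selected)
    while remaining:
        gains = [(acc(selected + [i]), i) for i in sorted(remaining)]
        best_acc, best_i = max(gains, key=lambda t: (t[0], -t[1]))
        if best_acc <= current:
            break
        selected.append(best_i)
        remaining.discard(best_i)
        current = best_acc
    model.selected = selected
    return selected
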
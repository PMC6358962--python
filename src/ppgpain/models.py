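"""Base classifiers: stacked-RBM deep belief network, multilayer perceptron,
and an RBF-kernel SVM baseline.

The DBN is a sigmoid feedforward network whose hidden layers are initialized
by greedy layer-wise unsupervised pre-training of restricted Boltzmann
machines (contrastive divergence with one Gibbs step, CD-1), then fine-tuned
end-to-end by mini-batch gradient descent with momentum and weight decay on a
cross-entropy loss. The MLPNN is the same network fine-tuned from small
random initial weights — the two differ only in initialization. Min-max
normalized inputs in [0, 1] are treated as Bernoulli probabilities by the
first RBM.

Default hyperparameters follow the reference configuration: structure
15-6-6-2 (17-6-6-4 for the 4-class protocol), learning rates 0.08 for
weights and both bias sets, batch size 104, momentum 0.9, weight decay
0.00029, sigmoid activations; pre-training 20 epochs, fine-tuning 800. The
SVM baseline uses an RBF kernel with gamma = 0.05 and C = 1.

All trainers are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = ["NetConfig", "SVMConfig", "RBM", "NeuralNetClassifier",
           "rbm_pretrain", "train_dbn", "train_mlpnn", "SVMClassifier",
           "train_svm", "make_trainer"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass(frozen=True)
class NetConfig:
    """Shared DBN/MLPNN hyperparameters."""

    layer_sizes: tuple[int, ...] = (15, 6, 6, 2)
    lr_weights: float = 0.08
    lr_vbias: float = 0.08
    lr_hbias: float = 0.08
    batch_size: int = 104
    momentum: float = 0.9
    weight_decay: float = 0.00029
    epochs_pretrain: int = 20
    epochs_finetune: int = 800
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 3:
            raise ValueError("need input, >= 1 hidden, and output layers")
        if min(self.lr_weights, self.lr_vbias, self.lr_hbias) <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel SVM hyperparameters (gamma sweep optimum 0.05, C = 1)."""

    gamma: float = 0.05
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be positive")


class RBM:
    """Bernoulli-Bernoulli restricted Boltzmann machine trained by CD-1."""

    def __init__(self, n_visible: int, n_hidden: int, config: NetConfig,
                 rng: np.random.Generator):
        self.W = rng.uniform(-config.init_scale, config.init_scale,
                             size=(n_visible, n_hidden))
        self.vbias = np.zeros(n_visible)
        self.hbias = np.zeros(n_hidden)
        self.config = config
        self.recon_trace: list[float] = []

    def hidden_probs(self, V: np.ndarray) -> np.ndarray:
        return _sigmoid(V @ self.W + self.hbias)

    def train(self, data: np.ndarray, rng: np.random.Generator) -> None:
        cfg = self.config
        n = data.shape[0]
        dW = np.zeros_like(self.W)
        dv = np.zeros_like(self.vbias)
        dh = np.zeros_like(self.hbias)
        for _ in range(cfg.epochs_pretrain):
            order = rng.permutation(n)
            sq_err = 0.0
            for start in range(0, n, cfg.batch_size):
                V0 = data[order[start:start + cfg.batch_size]]
                m = V0.shape[0]
                H0 = _sigmoid(V0 @ self.W + self.hbias)
                H0s = (rng.random(H0.shape) < H0).astype(float)
                V1 = _sigmoid(H0s @ self.W.T + self.vbias)
                H1 = _sigmoid(V1 @ self.W + self.hbias)

                gW = (V0.T @ H0 - V1.T @ H1) / m - cfg.weight_decay * self.W
                gv = (V0 - V1).mean(axis=0)
                gh = (H0 - H1).mean(axis=0)
                dW = cfg.momentum * dW + cfg.lr_weights * gW
                dv = cfg.momentum * dv + cfg.lr_vbias * gv
                dh = cfg.momentum * dh + cfg.lr_hbias * gh
                self.W += dW
                self.vbias += dv
                self.hbias += dh
                sq_err += float(np.sum((V0 - V1) ** 2))
            self.recon_trace.append(sq_err / data.size)


def rbm_pretrain(
    data: np.ndarray, config: NetConfig
) -> tuple[list[RBM], list[list[float]]]:
    """Greedy layer-wise CD-1 pre-training of the hidden-layer stack.

    Each RBM trains on the hidden activations (probabilities) of the previous
    one. Returns the RBMs and their per-epoch mean-squared reconstruction
    error traces (empty when ``epochs_pretrain`` is 0).
    """
    X = np.asarray(data, dtype=float)
    if X.min() < 0 or X.max() > 1:
        raise ValueError("pre-training expects inputs normalized to [0, 1]")
    rng = np.random.default_rng(config.seed)
    rbms: list[RBM] = []
    layer_input = X
    for n_vis, n_hid in zip(config.layer_sizes[:-2], config.layer_sizes[1:-1]):
        if layer_input.shape[1] != n_vis:
            raise ValueError("layer size mismatch during pre-training")
        rbm = RBM(n_vis, n_hid, config, rng)
        rbm.train(layer_input, rng)
        if not np.all(np.isfinite(rbm.W)):
            raise FloatingPointError("non-finite RBM parameters during pre-training")
        rbms.append(rbm)
        layer_input = rbm.hidden_probs(layer_input)
    return rbms, [r.recon_trace for r in rbms]


@dataclass
class NeuralNetClassifier:
    """Sigmoid feedforward classifier trained by mini-batch backpropagation.

    ``weights[l]`` maps layer l to l+1; the output layer holds one sigmoid
    unit per class and is read out through score normalization. Instantiate
    through :func:`train_dbn` / :func:`train_mlpnn`.
    """

    config: NetConfig
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    loss_trace: list[float] = field(default_factory=list)
    recon_traces: list[list[float]] = field(default_factory=list)

    # -- initialization -------------------------------------------------
    def init_random(self, rng: np.random.Generator) -> None:
        sizes = self.config.layer_sizes
        self.weights = [
            rng.uniform(-self.config.init_scale, self.config.init_scale, size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(b) for b in sizes[1:]]

    def init_from_rbms(self, rbms: list[RBM], rng: np.random.Generator) -> None:
        self.init_random(rng)  # output layer stays randomly initialized
        for l, rbm in enumerate(rbms):
            self.weights[l] = rbm.W.copy()
            self.biases[l] = rbm.hbias.copy()

    # -- forward / training ---------------------------------------------
    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        for W, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ W + b))
        return acts

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> None:
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != cfg.layer_sizes[-1]:
            raise ValueError(
                f"output layer has {cfg.layer_sizes[-1]} units but the labels "
                f"carry {self.classes_.size} classes"
            )
        if X.shape[1] != cfg.layer_sizes[0]:
            raise ValueError(
                f"input dimension {X.shape[1]} != input layer {cfg.layer_sizes[0]}"
            )
        T = (y[:, None] == self.classes_[None, :]).astype(float)  # one-hot

        n = X.shape[0]
        vel_W = [np.zeros_like(W) for W in self.weights]
        vel_b = [np.zeros_like(b) for b in self.biases]
        for _ in range(cfg.epochs_finetune):
            order = rng.permutation(n)
            total_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                acts = self._forward(X[idx])
                out = acts[-1]
                Tb = T[idx]
                eps = 1e-12
                total_loss += float(
                    -np.sum(Tb * np.log(out + eps) + (1 - Tb) * np.log(1 - out + eps))
                )
                # sigmoid + cross-entropy: output delta is (out - target)
                delta = (out - Tb) / idx.size
                for l in range(len(self.weights) - 1, -1, -1):
                    gW = acts[l].T @ delta + cfg.weight_decay * self.weights[l]
                    gb = delta.sum(axis=0)
                    if l > 0:
                        delta = (delta @ self.weights[l].T) * acts[l] * (1 - acts[l])
                    vel_W[l] = cfg.momentum * vel_W[l] - cfg.lr_weights * gW
                    vel_b[l] = cfg.momentum * vel_b[l] - cfg.lr_hbias * gb
                    self.weights[l] += vel_W[l]
                    self.biases[l] += vel_b[l]
            if not all(np.all(np.isfinite(W)) for W in self.weights):
                raise FloatingPointError("non-finite network parameters")
            self.loss_trace.append(total_loss / n)

    # -- inference -------------------------------------------------------
    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores normalized to sum to 1 per row."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.config.layer_sizes[0]:
            raise ValueError("feature dimension does not match the network input")
        out = self._forward(X)[-1]
        sums = out.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return out / sums

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_scores(X), axis=1)]

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "layer_sizes": list(self.config.layer_sizes),
            "classes": self.classes_.tolist(),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        })

    @classmethod
    def from_json(cls, text: str, config: NetConfig | None = None) -> "NeuralNetClassifier":
        blob = json.loads(text)
        cfg = config or NetConfig(layer_sizes=tuple(blob["layer_sizes"]))
        net = cls(config=cfg)
        net.classes_ = np.asarray(blob["classes"])
        net.weights = [np.asarray(W) for W in blob["weights"]]
        net.biases = [np.asarray(b) for b in blob["biases"]]
        return net


def train_mlpnn(
    X: np.ndarray,
    y: np.ndarray,
    config: NetConfig = NetConfig(),
    init_weights: tuple[list[np.ndarray], list[np.ndarray]] | None = None,
) -> NeuralNetClassifier:
    """Backpropagation-trained MLP from random (or supplied) initial weights."""
    rng = np.random.default_rng(config.seed)
    net = NeuralNetClassifier(config=config)
    net.init_random(rng)
    if init_weights is not None:
        ws, bs = init_weights
        net.weights = [np.array(W, dtype=float) for W in ws]
        net.biases = [np.array(b, dtype=float) for b in bs]
    net.fit(X, y, rng)
    return net


def train_dbn(
    X: np.ndarray, y: np.ndarray, config: NetConfig = NetConfig()
) -> NeuralNetClassifier:
    """RBM-stack pre-training followed by supervised fine-tuning."""
    rbms, traces = rbm_pretrain(X, config)
    rng = np.random.default_rng(config.seed + 1)
    net = NeuralNetClassifier(config=config)
    net.init_from_rbms(rbms, rng)
    net.recon_traces = traces
    net.fit(np.asarray(X, float), y, rng)
    return net


class SVMClassifier:
    """RBF-kernel SVM with probability-like scores for ROC analysis.

    Binary scores come from a logistic squash of the margin; multiclass
    scores from a softmax over the one-vs-rest decision values.
    """

    def __init__(self, config: SVMConfig = SVMConfig()):
        self.config = config
        self._svc = SVC(kernel="rbf", gamma=config.gamma, C=config.C,
                        decision_function_shape="ovr")

    @property
    def classes_(self) -> np.ndarray:
        return self._svc.classes_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMClassifier":
        if np.unique(y).size < 2:
            raise ValueError("SVM training needs at least two classes")
        self._svc.fit(np.asarray(X, float), np.asarray(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.asarray(X, float))

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        d = self._svc.decision_function(np.asarray(X, float))
        if d.ndim == 1:  # binary: margin toward classes_[1]
            p1 = _sigmoid(d)
            return np.column_stack([1 - p1, p1])
        e = np.exp(d - d.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


def train_svm(X: np.ndarray, y: np.ndarray,
              config: SVMConfig = SVMConfig()) -> SVMClassifier:
    return SVMClassifier(config).fit(X, y)


def make_trainer(kind: str, config=None):
    """Return ``trainer(X, y, seed) -> model`` for 'dbn', 'mlpnn' or 'svm'."""
    from dataclasses import replace

    if kind == "svm":
        cfg = config or SVMConfig()

        def trainer(X, y, seed=0):  # SVC fit is deterministic
            return train_svm(X, y, cfg)
        return trainer

    cfg = config or NetConfig()
    if kind == "dbn":
        return lambda X, y, seed=0: train_dbn(X, y, replace(cfg, seed=seed))
    if kind == "mlpnn":
        return lambda X, y, seed=0: train_mlpnn(X, y, replace(cfg, seed=seed))
    raise ValueError(f"unknown model kind {kind!r}")
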
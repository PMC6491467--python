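"""Fully-connected networks for color classification and axial regression.

Both tasks share one architecture: a feed-forward network of four
fully-connected ReLU hidden layers (default 4096-4096-2048-1024 neurons) on
the flattened, normalized 13 x 13 patch.  The color network ends in a
Softmax head trained with cross-entropy, regularized by dropout (rate 0.5)
before the final layer; the axial/lateral networks end in a scalar head
trained with squared error plus an L2 weight penalty (factor 0.01), without
dropout.  Weights are Xavier-initialized and optimized with Adam; the
learning rate starts at 1e-4 (classifier) or 1e-3 (regressor) and is scaled
by 0.2 every 1000 iterations.

The Softmax output is the posterior P(dye | image); classification is
maximum a posteriori, and in the binary case the signed confidence

    Delta = P(dye 1 | x) - P(dye 2 | x)

lets molecules with |Delta| below a user threshold delta be rejected instead
of assigned, trading retention for accuracy.

Everything here is plain numpy: training is deterministic given the seed and
CPU-feasible at the benchmark sizes used in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import ConfigurationError

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainingLog",
    "ColorCall",
    "Network",
    "build_network",
    "train_color_network",
    "train_axial_network",
    "train_lateral_network",
    "infer_color",
    "infer_axial",
    "patches_to_inputs",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``n_classes=None`` selects the scalar (regression) head.  Dropout is the
    classifier's regularizer and the weight penalty the regressor's; the two
    are mutually exclusive.
    """

    input_size: int = 169
    hidden_layers: tuple[int, ...] = (4096, 4096, 2048, 1024)
    n_classes: int | None = None
    dropout_rate: float = 0.0
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.input_size < 1:
            raise ConfigurationError("input_size must be positive")
        if len(self.hidden_layers) != 4:
            raise ConfigurationError("architecture uses exactly 4 hidden layers")
        if any(h < 1 for h in self.hidden_layers):
            raise ConfigurationError("hidden layer sizes must be positive")
        if self.n_classes is not None and self.n_classes < 2:
            raise ConfigurationError("a classifier needs at least 2 classes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be nonnegative")
        if self.dropout_rate > 0 and self.weight_decay > 0:
            raise ConfigurationError(
                "dropout and weight decay are mutually exclusive"
            )

    @property
    def output_size(self) -> int:
        return 1 if self.n_classes is None else self.n_classes


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule (Adam with stepped learning-rate decay)."""

    initial_learning_rate: float = 1e-4
    decay_factor: float = 0.2
    decay_interval: int = 1000
    batch_size: int = 64
    max_epochs: int = 10
    plateau_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")

    def learning_rate(self, iteration: int) -> float:
        return self.initial_learning_rate * self.decay_factor ** (
            iteration // self.decay_interval
        )


@dataclass
class TrainingLog:
    """Per-epoch record of the optimization."""

    train_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    metric_name: str = ""
    n_iterations: int = 0
    stopped_epoch: int = 0


@dataclass
class ColorCall:
    """Per-molecule posterior with MAP class and confidence."""

    posterior: np.ndarray
    map_class: int
    delta: float
    accepted: bool

    def __post_init__(self) -> None:
        p = np.asarray(self.posterior, dtype=float)
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("posterior must be a probability vector")
        if not -1.0 - 1e-9 <= self.delta <= 1.0 + 1e-9:
            raise ValueError("|delta| must lie in [0, 1]")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """Feed-forward ReLU network with a Softmax or scalar head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        sizes = [spec.input_size, *spec.hidden_layers, spec.output_size]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Xavier uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- forward / backward -------------------------------------------------

    def _forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list[np.ndarray], np.ndarray | None]:
        """Returns (output, per-layer activations, dropout mask)."""
        acts = [X]
        h = X
        n_layers = len(self.weights)
        mask = None
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
                if (
                    training
                    and i == n_layers - 2
                    and self.spec.dropout_rate > 0
                ):
                    # inverted dropout before the final layer
                    keep = 1.0 - self.spec.dropout_rate
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                acts.append(h)
        return h, acts, mask

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference pass (dropout disabled)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_size:
            raise ValueError(
                f"input must be (n, {self.spec.input_size}); got {X.shape}"
            )
        out, _, _ = self._forward(X, training=False)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.spec.n_classes is None:
            raise ValueError("scalar-head network has no class posterior")
        return _softmax(self.forward(X))

    def predict_scalar(self, X: np.ndarray) -> np.ndarray:
        if self.spec.n_classes is not None:
            raise ValueError("classifier head does not output a scalar")
        return self.forward(X)[:, 0]

    def _backward(
        self,
        acts: list[np.ndarray],
        mask: np.ndarray | None,
        dout: np.ndarray,
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of the loss w.r.t. weights and biases.

        ``dout`` is dL/d(pre-activation output); ``acts`` are the forward
        activations (inputs to each layer).
        """
        gW = [np.empty(0)] * len(self.weights)
        gb = [np.empty(0)] * len(self.biases)
        delta = dout
        for i in range(len(self.weights) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if mask is not None and i == len(self.weights) - 1:
                    delta = delta * mask
                delta = delta * (acts[i] > 0)
        return gW, gb

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path, extra_metadata: dict | None = None) -> None:
        """Model bundle: architecture JSON + weight blob side by side."""
        path = Path(path)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {
            "schema": 1,
            "spec": asdict(self.spec),
            "normalization": "patch zero-centered, unit Euclidean norm",
        }
        if extra_metadata:
            meta.update(extra_metadata)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load(path: str | Path) -> "Network":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec_d = dict(meta["spec"])
        spec_d["hidden_layers"] = tuple(spec_d["hidden_layers"])
        net = Network(NetworkSpec(**spec_d), seed=0)
        with np.load(path.with_suffix(".npz")) as f:
            net.weights = [f[f"W{i}"] for i in range(len(net.weights))]
            net.biases = [f[f"b{i}"] for i in range(len(net.biases))]
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Xavier-initialized network; identical parameters for identical seeds."""
    return Network(spec, seed=seed)


def patches_to_inputs(patches: Sequence[np.ndarray]) -> np.ndarray:
    """Flatten normalized patches into the network input matrix."""
    from .preprocess import normalize_patch

    return np.stack([normalize_patch(np.asarray(p)).ravel() for p in patches])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _balanced_order(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Class-balanced epoch ordering: equal per-class counts, interleaved."""
    classes = np.unique(y)
    per_class = [rng.permutation(np.flatnonzero(y == c)) for c in classes]
    n = min(len(ix) for ix in per_class)
    stacked = np.stack([ix[:n] for ix in per_class], axis=1)  # (n, n_classes)
    return stacked.ravel()


def _snapshot(net: Network) -> tuple[list[np.ndarray], list[np.ndarray]]:
    return [W.copy() for W in net.weights], [b.copy() for b in net.biases]


def train_color_network(
    net: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig | None = None,
) -> tuple[Network, TrainingLog]:
    """Cross-entropy training of the Softmax color classifier.

    Epochs are class-balanced by stratified sampling.  Training stops at
    ``max_epochs`` or when validation accuracy has not improved for
    ``plateau_patience`` epochs; the best-validation parameters are kept.
    """
    if config is None:
        config = TrainingConfig()
    X, y = np.asarray(train_set[0], float), np.asarray(train_set[1])
    Xv, yv = np.asarray(val_set[0], float), np.asarray(val_set[1])
    if len(np.unique(y)) < 2:
        raise ConfigurationError("classifier training needs >= 2 classes")
    M = net.spec.n_classes
    if M is None:
        raise ConfigurationError("network must have a classifier head")
    rng = np.random.default_rng(config.seed)
    adam = _Adam(net.weights + net.biases)
    log = TrainingLog(metric_name="val_accuracy")
    best = (-np.inf, _snapshot(net))
    stall = 0
    it = 0
    for epoch in range(config.max_epochs):
        order = _balanced_order(y, rng)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            logits, acts, mask = net._forward(xb, training=True, rng=rng)
            p = _softmax(logits)
            onehot = np.eye(M)[yb]
            losses.append(float(-np.mean(np.sum(onehot * np.log(p + 1e-12), axis=1))))
            dout = (p - onehot) / len(xb)
            gW, gb = net._backward(acts, mask, dout)
            adam.step(
                net.weights + net.biases, gW + gb, config.learning_rate(it)
            )
            it += 1
        acc = float(np.mean(net.predict_proba(Xv).argmax(axis=1) == yv))
        log.train_loss.append(float(np.mean(losses)))
        log.val_metric.append(acc)
        log.stopped_epoch = epoch + 1
        if acc > best[0]:
            best = (acc, _snapshot(net))
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau_patience:
                break
    log.n_iterations = it
    net.weights, net.biases = best[1]
    return net, log


def _train_regressor(
    net: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig,
) -> tuple[Network, TrainingLog]:
    X, y = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    Xv, yv = np.asarray(val_set[0], float), np.asarray(val_set[1], float)
    if net.spec.n_classes is not None:
        raise ConfigurationError("network must have a scalar head")
    wd = net.spec.weight_decay
    rng = np.random.default_rng(config.seed)
    adam = _Adam(net.weights + net.biases)
    log = TrainingLog(metric_name="val_rmse")
    best = (np.inf, _snapshot(net))
    stall = 0
    it = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            out, acts, mask = net._forward(xb, training=True, rng=rng)
            err = out[:, 0] - yb
            mse = float(np.mean(err**2))
            losses.append(mse + wd * sum(float(np.sum(W**2)) for W in net.weights))
            dout = (2.0 * err / len(xb))[:, None]
            gW, gb = net._backward(acts, mask, dout)
            if wd > 0:
                gW = [g + 2.0 * wd * W for g, W in zip(gW, net.weights)]
            adam.step(
                net.weights + net.biases, gW + gb, config.learning_rate(it)
            )
            it += 1
        rmse = float(np.sqrt(np.mean((net.predict_scalar(Xv) - yv) ** 2)))
        log.train_loss.append(float(np.mean(losses)))
        log.val_metric.append(rmse)
        log.stopped_epoch = epoch + 1
        if rmse < best[0]:
            best = (rmse, _snapshot(net))
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau_patience:
                break
    log.n_iterations = it
    net.weights, net.biases = best[1]
    return net, log


def train_axial_network(
    net: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig | None = None,
    color_labels: Sequence[int] | None = None,
) -> tuple[Network, TrainingLog]:
    """Squared-error training of a single-fluorophore axial regressor.

    Labels are z positions in nm.  One network is trained per dye; passing
    ``color_labels`` spanning more than one fluorophore is a configuration
    error.
    """
    if color_labels is not None and len(np.unique(color_labels)) > 1:
        raise ConfigurationError(
            "axial networks are trained per fluorophore; the training set "
            "mixes multiple dyes"
        )
    if config is None:
        config = TrainingConfig(initial_learning_rate=1e-3, batch_size=32)
    return _train_regressor(net, train_set, val_set, config)


def train_lateral_network(
    net: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig | None = None,
) -> tuple[Network, TrainingLog]:
    """Same machinery as the axial network with subpixel x (or y) labels in nm."""
    if config is None:
        config = TrainingConfig(initial_learning_rate=1e-3, batch_size=32)
    return _train_regressor(net, train_set, val_set, config)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def infer_color(
    net: Network, X: np.ndarray, delta_threshold: float = 0.0
) -> list[ColorCall]:
    """MAP color calls with confidence-based rejection.

    Binary confidence is the signed posterior difference
    ``Delta = P(class 0) - P(class 1)``; for more classes it generalizes to
    top-posterior minus runner-up.  A molecule is accepted iff
    ``|Delta| >= delta_threshold``.  Dropout is disabled, so repeated calls
    are identical.
    """
    P = net.predict_proba(np.asarray(X, dtype=float))
    calls = []
    for p in P:
        if len(p) == 2:
            delta = float(p[0] - p[1])
        else:
            top2 = np.sort(p)[-2:]
            delta = float(top2[1] - top2[0])
        calls.append(
            ColorCall(
                posterior=p,
                map_class=int(np.argmax(p)),
                delta=delta,
                accepted=bool(abs(delta) >= delta_threshold),
            )
        )
    return calls


def infer_axial(net: Network, X: np.ndarray) -> np.ndarray:
    """Deterministic z estimates (nm), one scalar per molecule."""
    return net.predict_scalar(np.asarray(X, dtype=float))
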
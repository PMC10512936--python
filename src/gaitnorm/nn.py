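"""A small fully connected network trainer on principal-component scores.

Architecture: input -> [dense -> Swish -> dropout] x n_hidden -> dense
(linear output).  Swish is x * sigmoid(x); dropout is inverted dropout
applied after each hidden activation and disabled at inference.  Training
minimizes mean squared error with the Adam optimizer over shuffled
minibatches for a fixed number of epochs (no early stopping).  Everything
is seeded, so a (data, hyperparameters, seed) triple maps to bit-identical
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitnorm.errors import DivergenceError, InputError


@dataclass(frozen=True)
class HyperParams:
    """Tunable architecture/optimization knobs explored by the grid search."""

    n_hidden_layers: int
    nodes_per_layer: int
    batch_size: int
    dropout_rate: float
    learning_rate: float

    def __post_init__(self):
        if self.n_hidden_layers < 1 or self.nodes_per_layer < 1 or self.batch_size < 1:
            raise InputError("layer, node and batch counts must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InputError("dropout rate must lie in [0, 1)")
        if self.learning_rate < 0.0:
            raise InputError("learning rate must be nonnegative")


@dataclass
class TrainingConfig:
    """Fixed training protocol: Swish activation, Adam, MSE, 300 epochs."""

    epochs: int = 300
    seed: int = 0
    activation: str = "swish"
    optimizer: str = "adam"
    loss: str = "mse"

    def __post_init__(self):
        if self.epochs < 1:
            raise InputError("epochs must be >= 1")
        if (self.activation, self.optimizer, self.loss) != ("swish", "adam", "mse"):
            raise InputError("only swish/adam/mse training is implemented")


@dataclass
class FnnWeights:
    """Dense-layer weight/bias pairs; the last pair is the linear output layer."""

    layers: list[tuple[np.ndarray, np.ndarray]]
    history: list[float] = field(default_factory=list)  # mean loss per epoch

    @property
    def n_inputs(self) -> int:
        return self.layers[0][0].shape[0]

    @property
    def n_outputs(self) -> int:
        return self.layers[-1][0].shape[1]


def _swish(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _swish_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def _init_layers(
    n_in: int, n_out: int, hp: HyperParams, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    sizes = [n_in] + [hp.nodes_per_layer] * hp.n_hidden_layers + [n_out]
    layers = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (a + b))  # Glorot uniform
        layers.append((rng.uniform(-limit, limit, size=(a, b)), np.zeros(b)))
    return layers


def forward(weights: FnnWeights, X: np.ndarray) -> np.ndarray:
    """Inference pass (dropout off)."""
    h = np.atleast_2d(np.asarray(X, dtype=float))
    if h.shape[1] != weights.n_inputs:
        raise InputError(f"input width {h.shape[1]} != network input {weights.n_inputs}")
    for W, b in weights.layers[:-1]:
        h = _swish(h @ W + b)
    W, b = weights.layers[-1]
    return h @ W + b


def train_fnn(
    scores_in: np.ndarray,
    scores_out: np.ndarray,
    hp: HyperParams,
    cfg: TrainingConfig,
) -> FnnWeights:
    """Train the network on score matrices with Adam / MSE.

    Minibatches are reshuffled each epoch from the run seed; a final short
    batch is kept.  Raises :class:`DivergenceError` naming the epoch if the
    loss becomes non-finite.
    """
    X = np.asarray(scores_in, dtype=float)
    Y = np.asarray(scores_out, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise InputError("score matrices must be 2-D with equal row counts")
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    layers = _init_layers(X.shape[1], Y.shape[1], hp, rng)
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in layers]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in layers]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = []
    keep = 1.0 - hp.dropout_rate
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = X[idx], Y[idx]
            # forward with cached pre-activations and dropout masks
            h = xb
            cache = []
            for W, b in layers[:-1]:
                z = h @ W + b
                a = _swish(z)
                if hp.dropout_rate > 0.0:
                    mask = (rng.random(a.shape) < keep) / keep
                    a_drop = a * mask
                else:
                    mask = None
                    a_drop = a
                cache.append((h, z, mask))
                h = a_drop
            Wl, bl = layers[-1]
            pred = h @ Wl + bl
            resid = pred - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            epoch_loss += loss * len(idx)
            # backward
            grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(layers)
            g = 2.0 * resid / resid.size
            grads[-1] = (h.T @ g, g.sum(axis=0))
            g = g @ Wl.T
            for li in range(len(layers) - 2, -1, -1):
                h_in, z, mask = cache[li]
                if mask is not None:
                    g = g * mask
                g = g * _swish_grad(z)
                grads[li] = (h_in.T @ g, g.sum(axis=0))
                g = g @ layers[li][0].T
            # adam update
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for li, (gW, gb) in enumerate(grads):
                W, b = layers[li]
                mW, mb = m[li]
                vW, vb = v[li]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m[li] = (mW, mb)
                v[li] = (vW, vb)
                W = W - hp.learning_rate * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
                b = b - hp.learning_rate * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
                layers[li] = (W, b)
        history.append(epoch_loss / n)
    return FnnWeights(layers=layers, history=history)


def save_weights(path, weights: FnnWeights) -> None:
    arrays = {}
    for i, (W, b) in enumerate(weights.layers):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    arrays["history"] = np.asarray(weights.history)
    np.savez(path, **arrays)


def load_weights(path) -> FnnWeights:
    with np.load(path, allow_pickle=False) as z:
        n = sum(1 for k in z.files if k.startswith("W"))
        layers = [(z[f"W{i}"], z[f"b{i}"]) for i in range(n)]
        history = z["history"].tolist() if "history" in z.files else []
    return FnnWeights(layers=layers, history=history)
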
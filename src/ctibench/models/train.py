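"""Pair classifier and SGD training loop.

The classifier joins a compound tower and a target tower: each emits a 128-d
representative vector, the pair is concatenated (256-d) and passed through
fully connected layers to a 2-neuron output whose softmax gives the
interaction probability.  Training minimizes the binary cross-entropy with
stochastic gradient descent (momentum); the seed fully determines parameter
initialization and batch order, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Dense, ReLU, SGDOptimizer, Sequential, cross_entropy, softmax

__all__ = [
    "TrainConfig",
    "PairClassifier",
    "fp2d_pair_model",
    "train",
    "standardize_features",
    "make_label_ambiguous_control",
]


def standardize_features(x: np.ndarray) -> np.ndarray:
    """Column z-scoring for tower inputs; zero-variance columns stay zero.

    Raw fingerprint vectors have uneven bit densities that put plain SGD
    near its stability edge; standardizing keeps activations O(1) so the
    default learning rate optimizes well.
    """
    x = np.asarray(x, dtype=np.float32)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    embedding_init: str = "RANDOM_UNIFORM"  # or "PHYSCHEM"


class PairClassifier:
    """compound tower + target tower -> concat -> FC head -> 2 logits."""

    def __init__(self, compound_tower: Sequential, target_tower: Sequential, head: Sequential):
        self.compound_tower = compound_tower
        self.target_tower = target_tower
        self.head = head

    def forward(self, x_compound: np.ndarray, x_target: np.ndarray) -> np.ndarray:
        vc = self.compound_tower.forward(x_compound)
        vt = self.target_tower.forward(x_target)
        self._split = vc.shape[1]
        return self.head.forward(np.concatenate([vc, vt], axis=1))

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.head.backward(grad_logits)
        self.compound_tower.backward(g[:, : self._split])
        self.target_tower.backward(g[:, self._split :])

    def predict_proba(self, x_compound: np.ndarray, x_target: np.ndarray) -> np.ndarray:
        """Probability of the positive class per pair."""
        return softmax(self.forward(x_compound, x_target))[:, 1]

    def parameters(self):
        return (
            self.compound_tower.parameters()
            + self.target_tower.parameters()
            + self.head.parameters()
        )

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]


def fp2d_pair_model(target_dim: int, seed: int = 0) -> PairClassifier:
    """Pair model with the 2D-fingerprint MLP compound tower.

    The target side is an MLP over any fixed-width target feature vector
    (pooled physicochemical features, a protein embedding, ...).  The head
    is 256 -> 64 -> 2.
    """
    from .towers import build_fp_mlp_tower

    rng = np.random.default_rng(seed)
    compound = build_fp_mlp_tower(seed=int(rng.integers(2**31)))
    target = Sequential(
        Dense(target_dim, 64, rng),
        ReLU(),
        Dense(64, 128, rng),
    )
    head = Sequential(Dense(256, 64, rng), ReLU(), Dense(64, 2, rng))
    return PairClassifier(compound, target, head)


def train(
    model: PairClassifier,
    x_compound: np.ndarray,
    x_target: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> dict:
    """SGD training; returns a history dict with per-epoch mean loss.

    Zero epochs returns the initialization untouched.  A non-finite loss
    aborts with diagnostics rather than training onward silently.
    """
    config = config or TrainConfig()
    xc = np.asarray(x_compound, dtype=np.float32)
    xt = np.asarray(x_target, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    if not (len(xc) == len(xt) == n):
        raise ValueError("feature/label lengths disagree")
    rng = np.random.default_rng(config.seed)
    opt = SGDOptimizer(model.parameters(), lr=config.lr, momentum=config.momentum)
    history: dict = {"loss": [], "config": config}
    onehot = np.eye(2, dtype=np.float32)[y]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            logits = model.forward(xc[batch], xt[batch])
            probs = softmax(logits)
            loss = cross_entropy(y[batch], probs[:, 1])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: logits range "
                    f"[{logits.min()}, {logits.max()}]"
                )
            grad = (probs - onehot[batch]) / len(batch)
            opt.zero_grad()
            model.backward(grad.astype(np.float32))
            opt.step()
            epoch_loss += loss * len(batch)
        history["loss"].append(epoch_loss / n)
    return history


def make_label_ambiguous_control(
    x_compound: np.ndarray, x_target: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """No-signal control set: every pair duplicated with both labels.

    Whatever the model's capacity, the optimal prediction for every input is
    probability 0.5, so the training loss converges to ln 2 from above; this
    makes the control a capacity-independent sanity bound (an independently
    shuffled-label copy can be memorized by a high-capacity network).
    """
    xc = np.concatenate([x_compound, x_compound])
    xt = np.concatenate([x_target, x_target])
    yy = np.concatenate([np.zeros(len(y), dtype=np.int64), np.ones(len(y), dtype=np.int64)])
    return xc, xt, yy
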
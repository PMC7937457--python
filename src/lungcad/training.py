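"""Loss, mini-batching and the two optimizers (plain GD and heavy-ball).

One *iteration* is one full pass over the training set.  "Batch gradient
descent with a batch size" is read as mini-batch gradient descent.  The
gradient applied per update is the gradient of the batch loss E^N itself —
a SUM over the batch's samples, not a mean — because E^N is defined as a
sum and the reference learning rate (0.0005) is stated together with a
batch size of 200: summed gradients make that pairing an effective
per-sample step of 0.1, the regime where these networks actually move.
Consequently η and batch size trade off against each other; halving the
batch halves the step an update takes.

Momentum is classical heavy-ball: v ← m·v − η·ḡ, θ ← θ + v, with the
velocity buffers persisting across updates.  m = 0 reduces exactly to
plain gradient descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .exceptions import TrainingDivergedError

__all__ = [
    "TrainConfig",
    "TrainState",
    "LossRecord",
    "mse_loss",
    "cross_entropy_loss",
    "evaluate_loss",
    "one_hot",
    "minibatch_iterator",
    "gd_step",
    "momentum_step",
    "train",
]


@dataclass
class TrainConfig:
    eta: float = 0.0005
    batch_size: int = 200
    momentum: float = 0.9       # 0 = plain mini-batch gradient descent
    iterations: int = 30
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum coefficient must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainState:
    """Live training state: parameter buffers, velocities, bookkeeping."""

    parameters: list            # (name, array) pairs, arrays updated in place
    velocities: list            # arrays congruent with parameters
    epoch: int = 0
    rng: Optional[np.random.Generator] = None


@dataclass
class LossRecord:
    """Per-iteration training loss E^N and (optional) held-out accuracy."""

    losses: List[float] = field(default_factory=list)
    accuracies: List[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        data = {"iteration": np.arange(1, len(self.losses) + 1),
                "loss": self.losses}
        if self.accuracies:
            data["accuracy"] = self.accuracies
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse_loss(y, t) -> float:
    """Sum-of-squares error E^N = ½ Σ_n Σ_k (t_k − y_k)²."""
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs t {t.shape}")
    return 0.5 * float(((t - y) ** 2).sum())


def cross_entropy_loss(y, t, eps: float = 1e-12) -> float:
    """Summed categorical cross-entropy −Σ_n Σ_k t log y."""
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs t {t.shape}")
    return -float((t * np.log(np.clip(y, eps, 1.0))).sum())


_LOSSES = {"mse": mse_loss, "cross_entropy": cross_entropy_loss}


def evaluate_loss(network, images, targets, loss: str = "mse",
                  chunk: int = 512) -> float:
    """Loss of a network over a set of images, forward passes chunked."""
    images = np.asarray(images, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    if images.ndim == 2:
        images = images[None]
    total = 0.0
    for i in range(0, len(targets), chunk):
        y, _ = network.forward(images[i:i + chunk])
        total += _LOSSES[loss](np.atleast_2d(y), targets[i:i + chunk])
    return total


def one_hot(labels, n_classes: int = 2):
    labels = np.asarray(labels, int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def minibatch_iterator(n_items, batch_size: int, seed):
    """Seeded permutation of range(n_items) cut into consecutive batches.

    ``seed`` may be an int or a ``numpy.random.Generator``; the last batch
    may be short.  The same seed yields the identical batch sequence.
    """
    if hasattr(n_items, "__len__"):
        n_items = len(n_items)
    if n_items < 1:
        raise ValueError("empty dataset")
    if batch_size < 1:
        raise ValueError("batch size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n_items)
    for start in range(0, n_items, batch_size):
        yield order[start:start + batch_size]


# ---------------------------------------------------------------------------
# update steps
# ---------------------------------------------------------------------------

def _check_finite(named_grads):
    for name, g in named_grads:
        if not np.all(np.isfinite(g)):
            raise TrainingDivergedError(f"non-finite gradient in {name}")


def gd_step(state: TrainState, named_grads, eta: float) -> TrainState:
    """Plain descent θ ← θ − η·g on the summed batch gradients."""
    _check_finite(named_grads)
    for (pname, p), (gname, g) in zip(state.parameters, named_grads):
        assert pname == gname, f"gradient order mismatch: {pname} vs {gname}"
        p -= eta * g
    return state


def momentum_step(state: TrainState, named_grads, eta: float, m: float) -> TrainState:
    """Heavy-ball update v ← m·v − η·g, θ ← θ + v (velocities persist)."""
    _check_finite(named_grads)
    for (pname, p), v, (gname, g) in zip(state.parameters, state.velocities,
                                         named_grads):
        assert pname == gname, f"gradient order mismatch: {pname} vs {gname}"
        v *= m
        v -= eta * g
        p += v
    return state


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def train(network, images, labels, config: TrainConfig,
          eval_images=None, eval_labels=None):
    """Run ``config.iterations`` full passes of mini-batch training.

    Records E^N over the whole training set after each pass, plus accuracy
    on the held-out set when one is given.  Fully deterministic for a fixed
    seed.  On a non-finite loss the run aborts with the last finite state
    attached to the raised :class:`TrainingDivergedError`.
    """
    images = np.asarray(images, float)
    labels = np.asarray(labels, int)
    if len(images) == 0:
        raise ValueError("empty dataset")
    if config.batch_size > len(images):
        raise ValueError("batch size exceeds the dataset size")
    targets = one_hot(labels)
    rng = np.random.default_rng(config.seed)
    params = network.parameter_arrays()
    state = TrainState(
        parameters=params,
        velocities=[np.zeros_like(a) for _, a in params],
        rng=rng,
    )
    history = LossRecord()
    for _ in range(config.iterations):
        for batch in minibatch_iterator(len(images), config.batch_size, rng):
            _, cache = network.forward(images[batch])
            # gradient of the summed batch loss E^N (no 1/N scaling)
            grads = network.backward(cache, targets[batch], loss=config.loss)
            named = grads.named_arrays()
            if config.momentum > 0:
                momentum_step(state, named, config.eta, config.momentum)
            else:
                gd_step(state, named, config.eta)
        state.epoch += 1
        epoch_loss = evaluate_loss(network, images, targets, config.loss)
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(
                f"training loss became non-finite at iteration {state.epoch}",
                state=state)
        history.losses.append(epoch_loss)
        if eval_images is not None:
            pred = network.predict_batched(eval_images)
            history.accuracies.append(float(np.mean(pred == np.asarray(eval_labels))))
    return network, history
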
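"""Forward primitives for the three layer kinds of a LeNet-style network.

A *feature-map stack* is a plain numpy array shaped ``(J, H, W)`` — ``J``
same-sized 2-D maps — or ``(N, J, H, W)`` for a batch of ``N`` samples.
Every operation in this module is a pure function over an explicit
parameter container and accepts either form, returning the same leading
shape it was given.

Conventions (fixed across the package):

* convolution is *valid-mode cross-correlation* — no kernel flip, no
  padding, so an ``H×W`` input and ``K×K`` kernel give ``(H−K+1)×(W−K+1)``;
* pooling tiles are non-overlapping, anchored top-left, window = stride;
* coordinates are 0-based row-major; max-pool ties go to the first
  occurrence in row-major tile order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ShapeError

ActivationKind = Literal["sigmoid", "relu", "identity"]

__all__ = [
    "ActivationKind",
    "ConvParams",
    "DenseParams",
    "PoolCache",
    "PoolParams",
    "activate",
    "activation_derivative",
    "conv_forward",
    "conv_preactivation",
    "dense_forward",
    "dense_preactivation",
    "pool_forward",
    "pool_preactivation",
    "relu",
    "sigmoid",
    "sigmoid_derivative",
    "softmax",
    "softmax_posteriors",
]


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def sigmoid(z):
    """Logistic function ``S(z) = 1 / (1 + exp(-z))``, numerically stable.

    The two-branch form never exponentiates a positive argument, so large
    |z| saturates to 0 or 1 instead of overflowing.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_derivative(z):
    """``S'(z) = S(z) (1 - S(z))``, evaluated at the pre-activation ``z``."""
    s = sigmoid(z)
    return s * (1.0 - s)


def relu(z):
    """Rectifier ``R(z) = max(0, z)``; the subgradient at 0 is taken as 0."""
    return np.maximum(0.0, np.asarray(z, dtype=float))


_FORWARD = {
    "sigmoid": sigmoid,
    "relu": relu,
    "identity": lambda z: np.asarray(z, dtype=float),
}

_DERIVATIVE = {
    "sigmoid": sigmoid_derivative,
    # strict inequality makes the subgradient at the kink exactly 0
    "relu": lambda z: (np.asarray(z) > 0).astype(float),
    "identity": lambda z: np.ones_like(np.asarray(z, dtype=float)),
}


def activate(u, kind: ActivationKind):
    """Apply the named activation elementwise to pre-activation ``u``."""
    try:
        return _FORWARD[kind](u)
    except KeyError:
        raise ValueError(f"unknown activation kind: {kind!r}") from None


def activation_derivative(u, kind: ActivationKind):
    """Elementwise derivative of the named activation at pre-activation ``u``."""
    try:
        return _DERIVATIVE[kind](u)
    except KeyError:
        raise ValueError(f"unknown activation kind: {kind!r}") from None


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ConvParams:
    """Weights of one convolutional layer.

    ``kernels`` has shape ``(J_out, J_in, K, K)`` — full connectivity, every
    output map sees every input map — and ``biases`` one scalar per output
    map.
    """

    kernels: np.ndarray
    biases: np.ndarray
    activation: ActivationKind = "sigmoid"

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.kernels.ndim != 4:
            raise ShapeError(
                f"kernels must be (J_out, J_in, K, K), got {self.kernels.shape}"
            )
        if self.kernels.shape[-1] != self.kernels.shape[-2]:
            raise ShapeError("kernels must be square")
        if self.biases.shape != (self.kernels.shape[0],):
            raise ShapeError("need exactly one bias per output map")

    @property
    def n_out(self) -> int:
        return self.kernels.shape[0]

    @property
    def n_in(self) -> int:
        return self.kernels.shape[1]

    @property
    def kernel_size(self) -> int:
        return self.kernels.shape[-1]

    @classmethod
    def initialize(cls, rng: np.random.Generator, n_in: int, n_out: int,
                   kernel_size: int, activation: ActivationKind = "sigmoid"):
        """Fan-balanced uniform init on ±sqrt(6/(fan_in+fan_out)), zero bias."""
        fan_in = n_in * kernel_size ** 2
        fan_out = n_out * kernel_size ** 2
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        kernels = rng.uniform(-limit, limit,
                              size=(n_out, n_in, kernel_size, kernel_size))
        return cls(kernels=kernels, biases=np.zeros(n_out), activation=activation)


@dataclass
class PoolParams:
    """Subsampling layer: per-map multiplicative bias β and additive bias b.

    In ``mean`` mode β and b are trainable (LeNet-style learned subsampling);
    in ``max`` mode they are frozen at (1, 0) and the activation defaults to
    identity, since scaling after a maximum is nonstandard.
    """

    mode: Literal["mean", "max"]
    window: int
    beta: np.ndarray
    bias: np.ndarray
    activation: ActivationKind = "identity"

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.mode not in ("mean", "max"):
            raise ValueError(f"pooling mode must be 'mean' or 'max', got {self.mode!r}")
        if self.window < 1:
            raise ValueError("pooling window must be >= 1")
        if self.beta.shape != self.bias.shape or self.beta.ndim != 1:
            raise ShapeError("beta and bias must be 1-D with one entry per map")

    @property
    def n_maps(self) -> int:
        return self.beta.shape[0]

    @property
    def trainable(self) -> bool:
        return self.mode == "mean"

    @classmethod
    def initialize(cls, n_maps: int, mode: str = "max", window: int = 2,
                   activation: ActivationKind = "identity"):
        return cls(mode=mode, window=window, beta=np.ones(n_maps),
                   bias=np.zeros(n_maps), activation=activation)


@dataclass
class PoolCache:
    """Intermediates kept by :func:`pool_forward` for the backward pass.

    ``pooled_raw`` is ``down(x)`` before β, b and the activation — the term
    the multiplicative-bias gradient needs.  ``argmax`` holds, in max mode,
    the flat row-major index of each tile's winner.
    """

    pooled_raw: np.ndarray
    mode: str
    window: int
    input_shape: tuple
    argmax: Optional[np.ndarray] = None


@dataclass
class DenseParams:
    """Fully connected layer: ``weights`` is (out × in), ``bias`` (out,)."""

    weights: np.ndarray
    bias: np.ndarray
    activation: ActivationKind = "sigmoid"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2:
            raise ShapeError(f"weights must be 2-D, got shape {self.weights.shape}")
        if self.bias.shape != (self.weights.shape[0],):
            raise ShapeError("bias length must equal the number of output units")

    @property
    def n_out(self) -> int:
        return self.weights.shape[0]

    @property
    def n_in(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def initialize(cls, rng: np.random.Generator, n_in: int, n_out: int,
                   activation: ActivationKind = "sigmoid"):
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights = rng.uniform(-limit, limit, size=(n_out, n_in))
        return cls(weights=weights, bias=np.zeros(n_out), activation=activation)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _check_stack(x, name="input") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim not in (3, 4):
        raise ShapeError(
            f"{name} must be (J, H, W) or (N, J, H, W), got shape {x.shape}"
        )
    return x


def conv_preactivation(x, params: ConvParams, layer_name: str = "conv"):
    """Valid cross-correlation plus bias, before the activation."""
    x = _check_stack(x, layer_name)
    k = params.kernel_size
    h, w = x.shape[-2:]
    if h < k or w < k:
        raise ShapeError(
            f"layer {layer_name!r}: kernel {k}x{k} larger than input {h}x{w}"
        )
    if x.shape[-3] != params.n_in:
        raise ShapeError(
            f"layer {layer_name!r}: expected {params.n_in} input maps, got {x.shape[-3]}"
        )
    # windows: (..., J_in, H', W', K, K)
    windows = sliding_window_view(x, (k, k), axis=(-2, -1))
    u = np.einsum("...ipqkl,oikl->...opq", windows, params.kernels, optimize=True)
    return u + params.biases[:, None, None]


def conv_forward(x, params: ConvParams, layer_name: str = "conv"):
    """Eq-style convolutional layer: activation(Σ_i x_i ⋆ k_ij + b_j)."""
    return activate(conv_preactivation(x, params, layer_name), params.activation)


def pool_preactivation(x, params: PoolParams, layer_name: str = "pool"):
    """Return ``(u, cache)`` where ``u = β·down(x) + b`` (before activation)."""
    x = _check_stack(x, layer_name)
    w = params.window
    h, wid = x.shape[-2:]
    if h % w or wid % w:
        raise ShapeError(
            f"layer {layer_name!r}: window {w} does not tile input {h}x{wid} "
            "(subsampling is non-overlapping, no padding)"
        )
    if x.shape[-3] != params.n_maps:
        raise ShapeError(
            f"layer {layer_name!r}: expected {params.n_maps} maps, got {x.shape[-3]}"
        )
    lead = x.shape[:-2]
    tiles = x.reshape(*lead, h // w, w, wid // w, w)
    tiles = np.swapaxes(tiles, -3, -2)          # (..., H', W', w, w)
    flat = tiles.reshape(*lead, h // w, wid // w, w * w)
    argmax = None
    if params.mode == "max":
        argmax = flat.argmax(axis=-1)           # first max wins (row-major)
        pooled = np.take_along_axis(flat, argmax[..., None], axis=-1)[..., 0]
    else:
        pooled = flat.mean(axis=-1)
    cache = PoolCache(pooled_raw=pooled, mode=params.mode, window=w,
                      input_shape=x.shape, argmax=argmax)
    u = params.beta[:, None, None] * pooled + params.bias[:, None, None]
    return u, cache


def pool_forward(x, params: PoolParams, layer_name: str = "pool"):
    """Subsampling layer ``f(β·down(x) + b)``; returns (output, cache)."""
    u, cache = pool_preactivation(x, params, layer_name)
    return activate(u, params.activation), cache


def dense_preactivation(x, params: DenseParams, layer_name: str = "dense"):
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.n_in:
        raise ShapeError(
            f"layer {layer_name!r}: expected input length {params.n_in}, "
            f"got {x.shape[-1]}"
        )
    return x @ params.weights.T + params.bias


def dense_forward(x, params: DenseParams, layer_name: str = "dense"):
    """Fully connected layer ``f(W x + b)``."""
    return activate(dense_preactivation(x, params, layer_name), params.activation)


# ---------------------------------------------------------------------------
# softmax classifier head
# ---------------------------------------------------------------------------

def softmax(logits, axis: int = -1):
    """Stable softmax (max-logit subtraction); sums to 1 along ``axis``."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_posteriors(x, weights, bias):
    """Two-class posterior ``softmax(Wᵀx + a)``.

    ``weights`` has one column per class (shape ``(d, 2)``), ``bias`` one
    entry per class.  Dimensional consistency forces the class offsets to be
    a length-2 vector.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if bias.shape[-1] != weights.shape[-1]:
        raise ShapeError("one bias entry per class is required")
    return softmax(x @ weights + bias, axis=-1)
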
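"""Sensitivities and parameter gradients for every layer kind.

The *sensitivity* δ of a layer is ∂E/∂u at that layer's pre-activation u.
Because the forward pass is cross-correlation (no kernel flip), the
backward formulas here are the ones that make the analytic gradient agree
with central differences — the numerical oracle, not any particular
convolution idiom, is the arbiter of orientation.

Batch handling: every function accepts a single sample or a leading batch
axis; parameter gradients are summed over the batch (callers divide by the
batch size for mean-gradient semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_layers import (
    ConvParams,
    DenseParams,
    PoolCache,
    PoolParams,
    activation_derivative,
)
from .exceptions import ShapeError

__all__ = [
    "ConvGrads",
    "DenseGrads",
    "PoolGrads",
    "output_delta",
    "softmax_mse_delta",
    "dense_backward",
    "dense_input_gradient",
    "conv_delta_from_pool",
    "conv_input_gradient",
    "conv_param_grads",
    "pool_delta_from_conv",
    "pool_input_gradient",
    "pool_param_grads",
    "numerical_gradient_check",
]


# ---------------------------------------------------------------------------
# gradient containers (mirror the parameter containers)
# ---------------------------------------------------------------------------

@dataclass
class ConvGrads:
    kernels: np.ndarray
    biases: np.ndarray


@dataclass
class PoolGrads:
    beta: np.ndarray
    bias: np.ndarray


@dataclass
class DenseGrads:
    weights: np.ndarray
    bias: np.ndarray


# ---------------------------------------------------------------------------
# output layer
# ---------------------------------------------------------------------------

def output_delta(y, t, u, activation):
    """δ at the output layer for the ½‖y−t‖² loss: f′(u)∘(y−t).

    Valid for elementwise activations (sigmoid / relu / identity).  For a
    softmax output use :func:`softmax_mse_delta`, whose Jacobian is not
    elementwise.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    u = np.asarray(u, float)
    if y.shape != t.shape or y.shape != u.shape:
        raise ShapeError("y, t and u must share one shape")
    return activation_derivative(u, activation) * (y - t)


def softmax_mse_delta(y, t):
    """δ at a softmax output under ½‖y−t‖²: (diag(y) − y yᵀ)(y − t).

    With r = y − t this is y ∘ (r − ⟨r, y⟩), vectorised over any batch axis.
    """
    y = np.asarray(y, float)
    r = y - np.asarray(t, float)
    return y * (r - (r * y).sum(axis=-1, keepdims=True))


def softmax_cross_entropy_delta(y, t):
    """δ at a softmax output under −Σ t log y: simply y − t."""
    return np.asarray(y, float) - np.asarray(t, float)


# ---------------------------------------------------------------------------
# dense layers
# ---------------------------------------------------------------------------

def dense_input_gradient(delta, params: DenseParams):
    """∂E/∂x for a dense layer given δ = ∂E/∂u: δ Wᵀ (i.e. (W)ᵀδ per sample)."""
    return np.asarray(delta, float) @ params.weights


def dense_backward(delta_next, params_next: DenseParams, u, x_prev,
                   activation_below="identity"):
    """Propagate through a dense layer: previous δ plus this layer's grads.

    ``delta_next`` is δ at the dense layer itself, ``u`` the pre-activation
    of the layer *below* with activation kind ``activation_below`` (so
    δ_prev = (Wᵀδ)∘f′(u)), and ``x_prev`` the activation feeding the dense
    layer (outer-product weight gradient ∂E/∂W = δ x_prevᵀ, summed over the
    batch; bias gradient δ itself, since ∂u/∂b = 1).
    """
    delta_next = np.asarray(delta_next, float)
    x_prev = np.asarray(x_prev, float)
    if x_prev.shape[-1] != params_next.n_in or delta_next.shape[-1] != params_next.n_out:
        raise ShapeError("delta/x_prev shapes inconsistent with the dense layer")
    if delta_next.ndim == 1:
        dw = np.outer(delta_next, x_prev)
        db = delta_next.copy()
    else:
        dw = np.einsum("no,ni->oi", delta_next, x_prev)
        db = delta_next.sum(axis=0)
    grads = DenseGrads(weights=dw, bias=db)
    dx = dense_input_gradient(delta_next, params_next)
    delta_prev = dx * activation_derivative(np.asarray(u, float), activation_below)
    return delta_prev, grads


# ---------------------------------------------------------------------------
# pooling layer: routing δ down to the layer below
# ---------------------------------------------------------------------------

def pool_input_gradient(delta, params: PoolParams, cache: PoolCache):
    """∂E/∂x below a pooling layer, given δ = ∂E/∂u at the pool.

    Mean mode: each input cell contributed 1/w² to its tile mean, so the
    upsampled δ is the Kronecker expansion scaled by β/w².  Max mode: the
    whole δ·β goes to the cached winner of each tile, zeros elsewhere.
    """
    delta = np.asarray(delta, float)
    if delta.shape != cache.pooled_raw.shape:
        raise ShapeError(
            f"delta shape {delta.shape} != pooled shape {cache.pooled_raw.shape}"
        )
    w = cache.window
    scaled = delta * params.beta[:, None, None]
    lead = delta.shape[:-2]
    hp, wp = delta.shape[-2:]
    if params.mode == "mean":
        up = np.repeat(np.repeat(scaled, w, axis=-2), w, axis=-1) / (w * w)
        return up
    # max mode: scatter into (..., H', W', w*w) tiles at the argmax slot
    tiles = np.zeros((*lead, hp, wp, w * w))
    np.put_along_axis(tiles, cache.argmax[..., None], scaled[..., None], axis=-1)
    tiles = tiles.reshape(*lead, hp, wp, w, w)
    tiles = np.swapaxes(tiles, -3, -2)           # (..., H', w, W', w)
    return tiles.reshape(cache.input_shape)


def conv_delta_from_pool(delta_pool, pool_params: PoolParams, u_conv,
                         cache: PoolCache, activation="sigmoid"):
    """δ of the convolutional layer sitting below a pooling layer.

    δ_conv = f′(u_conv) ∘ up(β·δ_pool), where up(·) is mean-sharing or
    winner-routing depending on the pooling mode.
    """
    dx = pool_input_gradient(delta_pool, pool_params, cache)
    return dx * activation_derivative(np.asarray(u_conv, float), activation)


def pool_param_grads(delta_pool, cache: PoolCache):
    """Gradients of the pooling layer's β and b from δ and down(x).

    ∂E/∂b_j = Σ_{u,v} δ_j and ∂E/∂β_j = Σ_{u,v} (δ_j ∘ down(x)_j).  In max
    mode β, b are frozen and the gradients are zeros of the right shape.
    """
    delta_pool = np.asarray(delta_pool, float)
    if delta_pool.shape != cache.pooled_raw.shape:
        raise ShapeError("delta geometry must match the pooled output")
    n_maps = delta_pool.shape[-3]
    if cache.mode == "max":
        return PoolGrads(beta=np.zeros(n_maps), bias=np.zeros(n_maps))
    axes = tuple(i for i in range(delta_pool.ndim) if i != delta_pool.ndim - 3)
    db = delta_pool.sum(axis=axes)
    dbeta = (delta_pool * cache.pooled_raw).sum(axis=axes)
    return PoolGrads(beta=dbeta, bias=db)


# ---------------------------------------------------------------------------
# convolutional layer: parameter grads and routing δ down
# ---------------------------------------------------------------------------

def conv_param_grads(delta_conv, x_prev):
    """Kernel and bias gradients of a convolutional layer.

    With a correlation forward pass the kernel gradient is the valid
    correlation of each input map with each output δ map,
    ∂E/∂k_oi[p,q] = Σ_{u,v} x_i[u+p, v+q] δ_o[u,v]; the bias gradient is
    the plain sum of δ_o.  Both are summed over any batch axis.
    """
    delta_conv = np.asarray(delta_conv, float)
    x_prev = np.asarray(x_prev, float)
    if delta_conv.ndim != x_prev.ndim:
        raise ShapeError("delta and input must have matching batch structure")
    hp, wp = delta_conv.shape[-2:]
    h, w = x_prev.shape[-2:]
    if h - hp != w - wp or h < hp:
        raise ShapeError("delta geometry inconsistent with a square valid kernel")
    windows = sliding_window_view(x_prev, (hp, wp), axis=(-2, -1))
    # windows: (..., J_in, K, K, H', W')
    if delta_conv.ndim == 3:
        dk = np.einsum("iklpq,opq->oikl", windows, delta_conv, optimize=True)
        db = delta_conv.sum(axis=(-2, -1))
    else:
        dk = np.einsum("niklpq,nopq->oikl", windows, delta_conv, optimize=True)
        db = delta_conv.sum(axis=(0, -2, -1))
    return ConvGrads(kernels=dk, biases=db)


def conv_input_gradient(delta, params: ConvParams):
    """∂E/∂x below a convolutional layer: full convolution of δ with kernels.

    ∂E/∂x_i[p,q] = Σ_o Σ_{u,v} δ_o[u,v] k_oi[p−u, q−v] — a full-mode true
    convolution, implemented as padding plus correlation with the 180°-
    rotated kernels.
    """
    delta = np.asarray(delta, float)
    k = params.kernel_size
    pad = [(0, 0)] * (delta.ndim - 2) + [(k - 1, k - 1)] * 2
    dpad = np.pad(delta, pad)
    windows = sliding_window_view(dpad, (k, k), axis=(-2, -1))
    flipped = params.kernels[:, :, ::-1, ::-1]
    return np.einsum("...opqkl,oikl->...ipq", windows, flipped, optimize=True)


def pool_delta_from_conv(delta_conv, conv_params: ConvParams, u_pool,
                         activation="identity"):
    """δ of the pooling layer sitting below a convolutional layer.

    δ_pool = f′(u_pool) ∘ Σ_o full-conv(δ_o, k_o·), the 180°-rotated-kernel
    full convolution summed over the conv layer's output maps.
    """
    dx = conv_input_gradient(delta_conv, conv_params)
    u_pool = np.asarray(u_pool, float)
    if dx.shape != u_pool.shape:
        raise ShapeError(f"routed delta {dx.shape} != pool geometry {u_pool.shape}")
    return dx * activation_derivative(u_pool, activation)


# ---------------------------------------------------------------------------
# the oracle: central-difference check of a whole network
# ---------------------------------------------------------------------------

def numerical_gradient_check(network, image, target, epsilon: float = 1e-5,
                             loss: str = "mse") -> float:
    """Max relative disagreement between analytic and numerical gradients.

    Perturbs every trainable parameter of ``network`` by ±ε, evaluates the
    loss on the single (image, target) pair, and compares the central
    difference against the analytic gradient from the backward pass.
    Returns ``max |g_a − g_n| / max(1, |g_a| + |g_n|)`` over all parameters.
    Intended for toy networks (a few thousand parameters at most).
    """
    from .training import evaluate_loss  # local import: avoid a cycle

    y, cache = network.forward(image)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite network output")
    analytic = network.backward(cache, np.asarray(target, float), loss=loss)
    worst = 0.0
    for (name, param), (gname, grad) in zip(network.parameter_arrays(),
                                            analytic.named_arrays()):
        assert name == gname
        it = np.nditer(param, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = param[idx]
            param[idx] = orig + epsilon
            lp = evaluate_loss(network, image, target, loss)
            param[idx] = orig - epsilon
            lm = evaluate_loss(network, image, target, loss)
            param[idx] = orig
            g_num = (lp - lm) / (2.0 * epsilon)
            g_ana = grad[idx]
            rel = abs(g_ana - g_num) / max(1.0, abs(g_ana) + abs(g_num))
            worst = max(worst, rel)
    return worst
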
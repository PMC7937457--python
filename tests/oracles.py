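"""Independent reference implementations used only by the tests.

Deliberately naive — nested loops and direct formulas — so they share no
code path with the package.
"""

import numpy as np


def conv_valid_loop(stack, kernels, biases):
    """Four-nested-loop valid cross-correlation, one sample."""
    j_out, j_in, k, _ = kernels.shape
    _, h, w = stack.shape
    out = np.zeros((j_out, h - k + 1, w - k + 1))
    for o in range(j_out):
        for p in range(h - k + 1):
            for q in range(w - k + 1):
                acc = 0.0
                for i in range(j_in):
                    acc += (stack[i, p:p + k, q:q + k] * kernels[o, i]).sum()
                out[o, p, q] = acc + biases[o]
    return out


def dense_loop(x, weights, bias):
    """Explicit dot-product-plus-bias, one sample."""
    out = np.zeros(weights.shape[0])
    for o in range(weights.shape[0]):
        acc = 0.0
        for i in range(weights.shape[1]):
            acc += weights[o, i] * x[i]
        out[o] = acc + bias[o]
    return out


def softmax_naive(logits):
    e = np.exp(np.asarray(logits, float))
    return e / e.sum()


def numeric_grad(f, x, epsilon=1e-6):
    """Central-difference gradient of scalar f at array x."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += epsilon
        xm = x.copy(); xm[idx] -= epsilon
        g[idx] = (f(xp) - f(xm)) / (2 * epsilon)
    return g


def confusion_tally_loop(predicted, truth):
    """One-pass tally under the normal-is-positive convention."""
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if t == 0 and p == 0:
            tp += 1
        elif t == 1 and p == 0:
            fp += 1
        elif t == 1 and p == 1:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn
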
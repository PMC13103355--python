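"""Small neural-network toolkit on autograd/numpy.

Parameters are pytrees (nested dicts/lists of numpy arrays); gradients come
back in the same shape from ``autograd.grad``.  Everything here is plain
numpy math so models stay CPU-friendly and bit-reproducible under a seed.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

# single-precision throughout: CPU-friendly, and ample for these scales
DTYPE = np.float32


# ---------------------------------------------------------------------------
# Pytree helpers

def tree_map(f, *trees):
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: tree_map(f, *(t[k] for t in trees)) for k in t0}
    if isinstance(t0, (list, tuple)):
        return type(t0)(tree_map(f, *parts) for parts in zip(*trees))
    return f(*trees)


def tree_leaves(tree):
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k])
    elif isinstance(tree, (list, tuple)):
        for t in tree:
            yield from tree_leaves(t)
    else:
        yield tree


def tree_copy(tree):
    return tree_map(lambda x: np.array(x, copy=True), tree)


def tree_allclose(a, b, atol=0.0):
    return all(
        np.allclose(x, y, atol=atol) for x, y in zip(tree_leaves(a), tree_leaves(b))
    )


# ---------------------------------------------------------------------------
# Layers

def linear_init(rng, d_in, d_out, scale=None):
    scale = scale if scale is not None else 1.0 / np.sqrt(d_in)
    return {
        "w": rng.normal(0.0, scale, size=(d_in, d_out)).astype(DTYPE),
        "b": np.zeros(d_out, dtype=DTYPE),
    }


def linear(p, x):
    return anp.matmul(x, p["w"]) + p["b"]


def layer_norm_init(d):
    return {"g": np.ones(d, dtype=DTYPE), "b": np.zeros(d, dtype=DTYPE)}


def layer_norm(p, x, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.var(x, axis=-1, keepdims=True)
    return p["g"] * (x - mu) / anp.sqrt(var + eps) + p["b"]


def gelu(x):
    # tanh approximation; x*x*x instead of x**3 (cheaper fwd and backward)
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654 * (x + 0.044715 * x * x * x)))


def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    return x - anp.log(anp.sum(anp.exp(x), axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# Optimizer

class AdamW:
    """AdamW over parameter pytrees; decoupled weight decay; per-step lr."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.98), eps=1e-8, weight_decay=0.0):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)

    def step(self, params, grads, lr=None):
        self.t += 1
        lr = self.lr if lr is None else lr
        b1, b2 = self.b1, self.b2
        self.m = tree_map(lambda m, g: b1 * m + (1 - b1) * g, self.m, grads)
        self.v = tree_map(lambda v, g: b2 * v + (1 - b2) * g * g, self.v, grads)
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t

        def upd(p, m, v):
            return p - lr * ((m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.weight_decay * p)

        return tree_map(upd, params, self.m, self.v)


def warmup_linear_decay(step, total_steps, warmup_steps, peak_lr, final_lr):
    """Linear warm-up to ``peak_lr`` then linear decay to ``final_lr``
    (the schedule shape used for masked-LM pretraining)."""
    if step < warmup_steps:
        return peak_lr * (step + 1) / max(1, warmup_steps)
    frac = (step - warmup_steps) / max(1, total_steps - warmup_steps)
    return peak_lr + (final_lr - peak_lr) * min(1.0, frac)
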
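"""Inter-protein contact prediction.

Ground truth follows the heavy-atom rule: residues i (chain A) and j
(chain B) are in contact when the minimum distance between their heavy
atoms is below 8 Å; a chain's interface is the support of the contact map.

The predictor encodes intra-chain and inter-chain feature stacks with 2-D
residual convolution encoders (the intra encoder is shared between the two
chains with tied weights), then refines the inter-chain pair representation
``z`` (L1 x L2 x c) through a stack of transformer blocks, each applying in
order: two parallel triangle-multiplication updates (one per chain as the
intermediate), two parallel cross-attention updates (intra-chain pairs as
keys/values), two parallel distance-modulated self-attention updates (rows
and columns of ``z``, logits scaled by a Gaussian transform of intra-chain
distances), and a two-layer transition — every stage residual.  A sigmoid
head reads contact probabilities off ``z``; training uses the two-class
focal loss (alpha=0.25, gamma=1.5) against the severe contact/non-contact
imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.extend import defvjp, primitive

from .data import ProteinPair, as_rng, encode_residues
from .nnops import AdamW, layer_norm, layer_norm_init, linear, linear_init, relu, sigmoid, softmax


# ---------------------------------------------------------------------------
# Geometry / ground truth


def min_distance_map(coords_x: Sequence[np.ndarray], coords_y: Sequence[np.ndarray]) -> np.ndarray:
    """Minimum heavy-atom distance for every residue pair.  ``coords_*`` are
    per-residue (n_atoms, 3) arrays; residues without atoms yield +inf (and
    a warning), i.e. never count as contacts."""
    for name, coords in (("x", coords_x), ("y", coords_y)):
        if any(len(c) == 0 for c in coords):
            warnings.warn(f"residue(s) with no heavy atoms in chain {name}; treated as no-contact")
    nx, ny = len(coords_x), len(coords_y)
    out = np.full((nx, ny), np.inf)
    ax = np.concatenate([c for c in coords_x if len(c)]) if nx else np.zeros((0, 3))
    ay = np.concatenate([c for c in coords_y if len(c)]) if ny else np.zeros((0, 3))
    ix = np.concatenate([np.full(len(c), i) for i, c in enumerate(coords_x) if len(c)]) \
        if len(ax) else np.zeros(0, dtype=int)
    iy = np.concatenate([np.full(len(c), j) for j, c in enumerate(coords_y) if len(c)]) \
        if len(ay) else np.zeros(0, dtype=int)
    if len(ax) and len(ay):
        d = np.sqrt(((ax[:, None, :] - ay[None, :, :]) ** 2).sum(-1))
        np.minimum.at(out, (ix[:, None].repeat(len(ay), 1), iy[None, :].repeat(len(ax), 0)), d)
    return out


def ground_truth_contacts(coords_a, coords_b, cutoff: float = 8.0) -> np.ndarray:
    """Binary (L1, L2) contact map: 1 iff min heavy-atom distance < cutoff
    (strict)."""
    return (min_distance_map(coords_a, coords_b) < cutoff).astype(np.float64)


def interface_truth(coords_a, coords_b, cutoff: float = 8.0):
    """Per-chain interface residue sets: supports of the contact map rows
    and columns."""
    cmap = ground_truth_contacts(coords_a, coords_b, cutoff)
    return (
        set(np.where(cmap.any(axis=1))[0].tolist()),
        set(np.where(cmap.any(axis=0))[0].tolist()),
    )


def gaussian_distance_transform(dist: np.ndarray, sigma: float = 8.0) -> np.ndarray:
    """d -> exp(-(d/sigma)^2); infinities map to 0."""
    out = np.exp(-((dist / sigma) ** 2))
    out[~np.isfinite(dist)] = 0.0
    return out


# ---------------------------------------------------------------------------
# Losses and evaluation


@dataclass(frozen=True)
class FocalLossParams:
    alpha: float = 0.25
    gamma: float = 1.5

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def focal_loss(pred, truth, params: FocalLossParams = FocalLossParams(), eps: float = 1e-7):
    """Two-class focal loss, mean over all cells:
    -alpha * (1 - p_t)^gamma * log(p_t) with p_t = p for contacts and 1-p
    otherwise.  gamma=0, alpha=1 recovers binary cross-entropy."""
    pred = anp.clip(pred, eps, 1.0 - eps)
    truth = anp.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p_t = truth * pred + (1.0 - truth) * (1.0 - pred)
    return anp.mean(-params.alpha * (1.0 - p_t) ** params.gamma * anp.log(p_t))


def top_k_precision(pred: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Fraction of the k highest-probability cells that are true contacts;
    ties broken by (row, column) lexicographic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pred.size:
        raise ValueError(f"k={k} exceeds number of cells {pred.size}")
    rows, cols = np.unravel_index(np.arange(pred.size), pred.shape)
    order = np.lexsort((cols, rows, -pred.ravel()))
    top = order[:k]
    return float(truth.ravel()[top].mean())


def top_k_cutoffs(L: int) -> dict:
    """The standard evaluation cutoffs {1, 10, 50, L/10, L/5, L} with L the
    shorter chain length; fractional cutoffs floor, minimum 1."""
    return {
        "top1": 1,
        "top10": 10,
        "top50": 50,
        "L/10": max(1, L // 10),
        "L/5": max(1, L // 5),
        "L": L,
    }


def interface_from_contacts(pred: np.ndarray, n_a: int, n_b: Optional[int] = None):
    """Extract ranked interface residues: walk predicted contact pairs in
    descending probability (lexicographic tie-break) collecting new residues
    per chain until n_a (chain A) and n_b (chain B) are gathered."""
    n_b = n_a if n_b is None else n_b
    L1, L2 = pred.shape
    if not (1 <= n_a <= L1) or not (1 <= n_b <= L2):
        raise ValueError("requested interface sizes exceed chain lengths")
    rows, cols = np.unravel_index(np.arange(pred.size), pred.shape)
    order = np.lexsort((cols, rows, -pred.ravel()))
    res_a, res_b = [], []
    seen_a, seen_b = set(), set()
    for idx in order:
        i, j = int(rows[idx]), int(cols[idx])
        if len(res_a) < n_a and i not in seen_a:
            seen_a.add(i)
            res_a.append(i)
        if len(res_b) < n_b and j not in seen_b:
            seen_b.add(j)
            res_b.append(j)
        if len(res_a) >= n_a and len(res_b) >= n_b:
            break
    return res_a, res_b


def ensemble_predict(prediction_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of member probability maps (order-invariant)."""
    if len(prediction_maps) == 0:
        raise ValueError("need at least one member prediction")
    shape = prediction_maps[0].shape
    if any(p.shape != shape for p in prediction_maps):
        raise ValueError("member maps have mismatched shapes")
    return np.mean(np.stack(prediction_maps), axis=0)


# ---------------------------------------------------------------------------
# Network configuration and parameters


@dataclass
class ContactNetConfig:
    c_z: int = 8            # inter pair-representation channels
    c_r: int = 8            # intra pair-representation channels
    n_blocks: int = 2       # transformer blocks (full-scale instance: 12)
    n_heads: int = 2
    c_head: int = 4         # per-head channel width in attention modules
    resnet_blocks: int = 1
    transition_expand: int = 4
    gauss_sigma: float = 8.0
    use_distance: bool = True   # ablation switch: intra distance features + modulation
    contact2: bool = False      # include a complex-derived inter distance channel
    symmetrize: bool = False    # homodimer mode: average with the transpose
    intra_channels: int = 83    # input channels of the intra 2-D feature stack
    inter_channels: int = 48    # input channels of the inter 2-D feature stack


def paper_scale_contact_config() -> ContactNetConfig:
    return ContactNetConfig(c_z=64, c_r=64, n_blocks=12, n_heads=4, c_head=16, resnet_blocks=4)


def _conv_init(rng, c_in, c_out, k=3):
    from .nnops import DTYPE

    scale = 1.0 / np.sqrt(c_in * k * k)
    return {
        "w": rng.normal(0.0, scale, size=(k, k, c_in, c_out)).astype(DTYPE),
        "b": np.zeros(c_out, dtype=DTYPE),
    }


def _pad_hw(x, pad):
    widths = ((0, 0),) * (x.ndim - 3) + ((pad, pad), (pad, pad), (0, 0))
    return np.pad(x, widths)


@primitive
def _conv_hw(x, w, b):
    """Same-padding 2-D cross-correlation over (..., H, W, C_in) via shifted
    matmuls; a custom primitive so the reverse pass is matmul-based too
    (autograd's generic slicing gradient is prohibitively slow here)."""
    k = w.shape[0]
    pad = k // 2
    H, W = x.shape[-3], x.shape[-2]
    xp = _pad_hw(x, pad)
    out = np.broadcast_to(b, x.shape[:-1] + (w.shape[-1],)).copy()
    for dy in range(k):
        for dx in range(k):
            out += np.matmul(xp[..., dy : dy + H, dx : dx + W, :], w[dy, dx])
    return out


def _conv_hw_vjp_x(ans, x, w, b):
    k = w.shape[0]
    pad = k // 2
    H, W = x.shape[-3], x.shape[-2]

    def vjp(g):
        gp = _pad_hw(g, pad)
        out = np.zeros(x.shape, dtype=g.dtype)
        for dy in range(k):
            for dx in range(k):
                out += np.matmul(
                    gp[..., dy : dy + H, dx : dx + W, :],
                    w[k - 1 - dy, k - 1 - dx].T,
                )
        return out

    return vjp


def _conv_hw_vjp_w(ans, x, w, b):
    k = w.shape[0]
    pad = k // 2
    H, W = x.shape[-3], x.shape[-2]

    def vjp(g):
        xp = _pad_hw(x, pad)
        gw = np.empty_like(w)
        gf = g.reshape(-1, g.shape[-1])
        for dy in range(k):
            for dx in range(k):
                patch = xp[..., dy : dy + H, dx : dx + W, :].reshape(-1, x.shape[-1])
                gw[dy, dx] = patch.T @ gf
        return gw

    return vjp


defvjp(
    _conv_hw,
    _conv_hw_vjp_x,
    _conv_hw_vjp_w,
    lambda ans, x, w, b: lambda g: g.reshape(-1, g.shape[-1]).sum(axis=0),
)


def conv2d(p, x):
    """Same-padding convolution over (..., H, W, C_in)."""
    return _conv_hw(x, p["w"], p["b"])


def _resnet_init(rng, c_in, c, n_blocks):
    return {
        "proj": _conv_init(rng, c_in, c, k=1),
        "blocks": [
            {"conv1": _conv_init(rng, c, c), "conv2": _conv_init(rng, c, c),
             "ln": layer_norm_init(c)}
            for _ in range(n_blocks)
        ],
    }


def resnet_encode(p, x):
    h = conv2d(p["proj"], x)
    for bp in p["blocks"]:
        y = layer_norm(bp["ln"], h)
        y = conv2d(bp["conv2"], relu(conv2d(bp["conv1"], y)))
        h = h + y
    return h


def _triangle_init(rng, c_z, c_r):
    return {
        "lz": linear_init(rng, c_z, c_z), "lzg": linear_init(rng, c_z, c_z),
        "lr": linear_init(rng, c_r, c_z), "lrg": linear_init(rng, c_r, c_z),
        "gate": linear_init(rng, c_z, c_z),
        "ln": layer_norm_init(c_z), "out": linear_init(rng, c_z, c_z),
    }


def triangle_update(p, z, r, side: str):
    """Triangle multiplication: z~_ij = g_ij * phi(sum_n r'_in z'_nj), with
    gated linear projections z' = L(z)*sigma(L(z)), r' = L(r)*sigma(L(r)),
    gate g = sigma(L(z)) and phi = LayerNorm then linear.  ``side`` selects
    the chain providing the intermediate residue n: 'a' sums over chain-A
    indices using r_a, 'b' over chain-B indices using r_b."""
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    if z.ndim not in (3, 4) or r.ndim != z.ndim or r.shape[-3] != r.shape[-2]:
        raise ValueError(f"bad shapes: z {z.shape}, r {r.shape}")
    expected = z.shape[-3] if side == "a" else z.shape[-2]
    if r.shape[-3] != expected:
        raise ValueError(f"r has {r.shape[-3]} residues, expected {expected} for side {side!r}")
    squeeze = z.ndim == 3
    if squeeze:
        z = z[None]
        r = r[None]
    zp = linear(p["lz"], z) * sigmoid(linear(p["lzg"], z))
    rp = linear(p["lr"], r) * sigmoid(linear(p["lrg"], r))
    g = sigmoid(linear(p["gate"], z))
    # per-channel matrix products via batched matmul (BLAS-friendly)
    if side == "a":
        # agg[i,j,c] = sum_n rp[i,n,c] * zp[n,j,c]
        agg = anp.matmul(anp.transpose(rp, (0, 3, 1, 2)), anp.transpose(zp, (0, 3, 1, 2)))
        agg = anp.transpose(agg, (0, 2, 3, 1))
    else:
        # agg[i,j,c] = sum_n rp[j,n,c] * zp[i,n,c]
        agg = anp.matmul(anp.transpose(rp, (0, 3, 1, 2)), anp.transpose(zp, (0, 3, 2, 1)))
        agg = anp.transpose(agg, (0, 3, 2, 1))
    out = g * linear(p["out"], layer_norm(p["ln"], agg))
    return out[0] if squeeze else out


def _cross_attn_init(rng, c_z, c_r, n_heads, c_head):
    ch = n_heads * c_head
    return {
        "q": linear_init(rng, c_z, ch), "k": linear_init(rng, c_r, ch),
        "v": linear_init(rng, c_r, ch), "bias": linear_init(rng, c_z, n_heads),
        "gate": linear_init(rng, c_z, ch), "out": linear_init(rng, ch, c_z),
    }


def cross_attention_update(p, z, r, side: str, n_heads: int, c_head: int):
    """Cross-attention: the inter-chain pair z_ij queries the intra-chain
    pairs sharing its chain-A residue i (side 'a': keys/values r_in) or its
    chain-B residue j (side 'b': keys/values r_jn)."""
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    L1, L2 = z.shape[-3], z.shape[-2]
    Lr = r.shape[-3]
    expected = L1 if side == "a" else L2
    if Lr != expected:
        raise ValueError(f"r has {Lr} residues, expected {expected} for side {side!r}")

    squeeze = z.ndim == 3
    if squeeze:
        z = z[None]
        r = r[None]

    def heads(x, ch):
        return anp.reshape(x, x.shape[:-1] + (n_heads, ch))

    q = heads(linear(p["q"], z), c_head)        # (B,L1,L2,H,ch)
    k = heads(linear(p["k"], r), c_head)        # (B,Lr,Lr,H,ch)
    v = heads(linear(p["v"], r), c_head)
    bias = linear(p["bias"], z)                 # (B,L1,L2,H)
    g = heads(sigmoid(linear(p["gate"], z)), c_head)
    scale = float(1.0 / np.sqrt(c_head))
    if side == "a":
        # query (i,j) attends keys r[i,n]: batch over (B, i, h)
        qb = anp.transpose(q, (0, 1, 3, 2, 4))               # (B,L1,H,L2,c)
        kb = anp.transpose(k, (0, 1, 3, 4, 2))               # (B,L1,H,c,N)
        logits = anp.matmul(qb, kb) * scale \
            + anp.transpose(bias, (0, 1, 3, 2))[..., None]   # (B,L1,H,L2,N)
        a = softmax(logits, axis=-1)
        vb = anp.transpose(v, (0, 1, 3, 2, 4))               # (B,L1,H,N,c)
        ctx = anp.transpose(anp.matmul(a, vb), (0, 1, 3, 2, 4))  # (B,L1,L2,H,c)
    else:
        # query (i,j) attends keys r[j,n]: batch over (B, j, h)
        qb = anp.transpose(q, (0, 2, 3, 1, 4))               # (B,L2,H,L1,c)
        kb = anp.transpose(k, (0, 1, 3, 4, 2))               # (B,L2,H,c,N)
        logits = anp.matmul(qb, kb) * scale \
            + anp.transpose(bias, (0, 2, 3, 1))[..., None]   # (B,L2,H,L1,N)
        a = softmax(logits, axis=-1)
        vb = anp.transpose(v, (0, 1, 3, 2, 4))               # (B,L2,H,N,c)
        ctx = anp.transpose(anp.matmul(a, vb), (0, 3, 1, 2, 4))  # (B,L1,L2,H,c)
    out = anp.reshape(g * ctx, ctx.shape[:-2] + (n_heads * c_head,))
    out = linear(p["out"], out)
    return out[0] if squeeze else out


def _self_attn_init(rng, c_z, n_heads, c_head):
    ch = n_heads * c_head
    return {
        "q": linear_init(rng, c_z, ch), "k": linear_init(rng, c_z, ch),
        "v": linear_init(rng, c_z, ch), "gate": linear_init(rng, c_z, ch),
        "out": linear_init(rng, ch, c_z),
    }


def self_attention_update(p, z, d_mod, axis: str, n_heads: int, c_head: int):
    """Distance-modulated self-attention over rows or columns of z.

    axis 'a': z_ij attends over z_mj (m along chain A), logits
    (q_ij . k_mj / sqrt(c)) * d_im with d the Gaussian-transformed intra-A
    distance map; axis 'b': z_ij attends over z_im with d_jm from chain B.
    Passing d identically 1 recovers plain self-attention."""
    if axis not in ("a", "b"):
        raise ValueError("axis must be 'a' or 'b'")
    L1, L2 = z.shape[-3], z.shape[-2]
    La = L1 if axis == "a" else L2
    if d_mod is None:
        raise ValueError("distance modulation matrix is required (pass ones to disable)")
    if d_mod.shape[-2:] != (La, La):
        raise ValueError(f"distance map shape {d_mod.shape}, expected (..., {La}, {La})")

    squeeze = z.ndim == 3
    if squeeze:
        z = z[None]
        if d_mod.ndim == 3:
            raise ValueError("batched distance map with unbatched z")
    if d_mod.ndim == 2:
        d_mod = d_mod[None]

    def heads(x):
        return anp.reshape(x, x.shape[:-1] + (n_heads, c_head))

    q, k, v = heads(linear(p["q"], z)), heads(linear(p["k"], z)), heads(linear(p["v"], z))
    g = heads(sigmoid(linear(p["gate"], z)))
    scale = float(1.0 / np.sqrt(c_head))
    if axis == "a":
        # query (i,j) attends keys z[m,j], logits scaled by d[i,m]: batch (B, j, h)
        qb = anp.transpose(q, (0, 2, 3, 1, 4))               # (B,L2,H,L1,c)
        kb = anp.transpose(k, (0, 2, 3, 4, 1))               # (B,L2,H,c,M)
        logits = anp.matmul(qb, kb) * scale * d_mod[:, None, None, :, :]
        a = softmax(logits, axis=-1)                          # (B,L2,H,L1,M)
        vb = anp.transpose(v, (0, 2, 3, 1, 4))               # (B,L2,H,M,c)
        ctx = anp.transpose(anp.matmul(a, vb), (0, 3, 1, 2, 4))  # (B,L1,L2,H,c)
    else:
        # query (i,j) attends keys z[i,m], logits scaled by d[j,m]: batch (B, i, h)
        qb = anp.transpose(q, (0, 1, 3, 2, 4))               # (B,L1,H,L2,c)
        kb = anp.transpose(k, (0, 1, 3, 4, 2))               # (B,L1,H,c,M)
        logits = anp.matmul(qb, kb) * scale * d_mod[:, None, None, :, :]
        a = softmax(logits, axis=-1)                          # (B,L1,H,L2,M)
        vb = anp.transpose(v, (0, 1, 3, 2, 4))               # (B,L1,H,M,c)
        ctx = anp.transpose(anp.matmul(a, vb), (0, 1, 3, 2, 4))  # (B,L1,L2,H,c)
    out = anp.reshape(g * ctx, ctx.shape[:-2] + (n_heads * c_head,))
    out = linear(p["out"], out)
    return out[0] if squeeze else out


def _transition_init(rng, c, expand):
    return {"l1": linear_init(rng, c, expand * c), "l2": linear_init(rng, expand * c, c)}


def transition(p, z):
    """Two linear maps with an intermediate ReLU."""
    return linear(p["l2"], relu(linear(p["l1"], z)))


def init_contact_params(cfg: ContactNetConfig, rng) -> dict:
    rng = as_rng(rng)
    inter_in = cfg.inter_channels + (1 if cfg.contact2 else 0)

    def block():
        return {
            "tri_a": _triangle_init(rng, cfg.c_z, cfg.c_r),
            "tri_b": _triangle_init(rng, cfg.c_z, cfg.c_r),
            "cross_a": _cross_attn_init(rng, cfg.c_z, cfg.c_r, cfg.n_heads, cfg.c_head),
            "cross_b": _cross_attn_init(rng, cfg.c_z, cfg.c_r, cfg.n_heads, cfg.c_head),
            "self_a": _self_attn_init(rng, cfg.c_z, cfg.n_heads, cfg.c_head),
            "self_b": _self_attn_init(rng, cfg.c_z, cfg.n_heads, cfg.c_head),
            "trans": _transition_init(rng, cfg.c_z, cfg.transition_expand),
        }

    return {
        "intra_enc": _resnet_init(rng, cfg.intra_channels, cfg.c_r, cfg.resnet_blocks),
        "inter_enc": _resnet_init(rng, inter_in, cfg.c_z, cfg.resnet_blocks),
        "blocks": [block() for _ in range(cfg.n_blocks)],
        "head": linear_init(rng, cfg.c_z, 1),
    }


@dataclass
class PairRepresentation:
    z: np.ndarray    # (L1, L2, c_z)
    r_a: np.ndarray  # (L1, L1, c_r)
    r_b: np.ndarray  # (L2, L2, c_r)


def encode(params, feats) -> PairRepresentation:
    """ResNet encoders: the intra encoder is shared (tied weights) between
    the chains; the inter encoder is separate."""
    return PairRepresentation(
        z=resnet_encode(params["inter_enc"], feats["inter"]),
        r_a=resnet_encode(params["intra_enc"], feats["intra_a"]),
        r_b=resnet_encode(params["intra_enc"], feats["intra_b"]),
    )


def contact_logits(params, cfg: ContactNetConfig, feats):
    rep = encode(params, feats)
    z, r_a, r_b = rep.z, rep.r_a, rep.r_b
    L1, L2 = z.shape[-3], z.shape[-2]
    if cfg.use_distance:
        d_a = feats["dmod_a"]
        d_b = feats["dmod_b"]
    else:
        d_a = np.ones((L1, L1), dtype=z.dtype)
        d_b = np.ones((L2, L2), dtype=z.dtype)
    for bp in params["blocks"]:
        z = z + triangle_update(bp["tri_a"], z, r_a, "a") \
              + triangle_update(bp["tri_b"], z, r_b, "b")
        z = z + cross_attention_update(bp["cross_a"], z, r_a, "a", cfg.n_heads, cfg.c_head) \
              + cross_attention_update(bp["cross_b"], z, r_b, "b", cfg.n_heads, cfg.c_head)
        z = z + self_attention_update(bp["self_a"], z, d_a, "a", cfg.n_heads, cfg.c_head) \
              + self_attention_update(bp["self_b"], z, d_b, "b", cfg.n_heads, cfg.c_head)
        z = z + transition(bp["trans"], z)
    return linear(params["head"], z)[..., 0]


def predict_contacts(params, cfg: ContactNetConfig, feats) -> np.ndarray:
    """Contact probability map (L1, L2) in [0,1]; in homodimer mode the map
    is symmetrized by averaging with its transpose."""
    probs = np.asarray(sigmoid(contact_logits(params, cfg, feats)))
    if cfg.symmetrize:
        if probs.shape[0] != probs.shape[1]:
            raise ValueError("symmetrization requires a square map")
        probs = 0.5 * (probs + probs.T)
    return probs


# ---------------------------------------------------------------------------
# Feature assembly


def _one_hot_sequence(seq: str) -> np.ndarray:
    idx = encode_residues(seq)
    return (idx[:, None] == np.arange(21)).astype(np.float64)


def _intra_stack(seq: str, pssm: Optional[np.ndarray], dist: Optional[np.ndarray],
                 sigma: float) -> np.ndarray:
    """2-D intra-chain features: pairwise concatenation of per-residue
    channels (one-hot 21 + PSSM 20) plus a Gaussian-transformed distance
    channel.  (L, L, 83)."""
    L = len(seq)
    f = _one_hot_sequence(seq)
    if pssm is None:
        pssm = np.zeros((L, 20))
    f = np.concatenate([f, pssm], axis=1)  # (L, 41)
    tile_i = np.repeat(f[:, None, :], L, axis=1)
    tile_j = np.repeat(f[None, :, :], L, axis=0)
    if dist is None:
        dchan = np.zeros((L, L, 1))
    else:
        dchan = gaussian_distance_transform(dist, sigma)[:, :, None]
    return np.concatenate([tile_i, tile_j, dchan], axis=2)


def assemble_features(
    pair: ProteinPair,
    lm_bundle=None,
    paired_msa=None,
    pssm_a: Optional[np.ndarray] = None,
    pssm_b: Optional[np.ndarray] = None,
    dist_a: Optional[np.ndarray] = None,
    dist_b: Optional[np.ndarray] = None,
    inter_dist: Optional[np.ndarray] = None,
    cfg: ContactNetConfig = None,
) -> dict:
    """Build the feature dict the contact network consumes.

    Inter channels: language-model inter-chain attention heads (final
    layer), MI+APC coupling scores, a PSSM inner-product channel, pairwise
    one-hot concatenation, and (contact2 mode) a Gaussian-transformed
    complex-derived inter-chain distance channel.  Missing sources are
    zero-filled so the channel layout is stable."""
    from .msa import coupling_scores  # local import to avoid cycles

    cfg = cfg or ContactNetConfig()
    sa, sb = pair.chain_a.residues, pair.chain_b.residues
    L1, L2 = len(sa), len(sb)
    if not cfg.use_distance:
        dist_a = dist_b = None
    chans = []
    # language-model inter attention (final layer), heads as channels
    if lm_bundle is not None:
        chans.append(np.moveaxis(lm_bundle.inter[-1], 0, -1))
        n_lm = lm_bundle.inter[-1].shape[0]
    else:
        n_lm = 4
        chans.append(np.zeros((L1, L2, n_lm)))
    # MSA coupling
    if paired_msa is not None:
        chans.append(coupling_scores(paired_msa)[:, :, None])
    else:
        chans.append(np.zeros((L1, L2, 1)))
    # PSSM inner product
    pa = pssm_a if pssm_a is not None else np.zeros((L1, 20))
    pb = pssm_b if pssm_b is not None else np.zeros((L2, 20))
    chans.append((pa @ pb.T)[:, :, None] / 20.0)
    # pairwise one-hot concatenation
    oa, ob = _one_hot_sequence(sa), _one_hot_sequence(sb)
    chans.append(np.repeat(oa[:, None, :], L2, axis=1))
    chans.append(np.repeat(ob[None, :, :], L1, axis=0))
    if cfg.contact2:
        if inter_dist is None:
            raise ValueError("contact2 mode requires an inter-chain distance map")
        chans.append(gaussian_distance_transform(inter_dist, cfg.gauss_sigma)[:, :, None])
    inter = np.concatenate(chans, axis=2)
    expected = cfg.inter_channels + (1 if cfg.contact2 else 0)
    if inter.shape[2] != expected:
        raise ValueError(
            f"inter feature stack has {inter.shape[2]} channels, config expects {expected}"
        )
    from .nnops import DTYPE

    feats = {
        "inter": inter.astype(DTYPE),
        "intra_a": _intra_stack(sa, pssm_a, dist_a, cfg.gauss_sigma).astype(DTYPE),
        "intra_b": _intra_stack(sb, pssm_b, dist_b, cfg.gauss_sigma).astype(DTYPE),
        "dmod_a": gaussian_distance_transform(
            dist_a if dist_a is not None else np.full((L1, L1), np.inf), cfg.gauss_sigma
        ).astype(DTYPE),
        "dmod_b": gaussian_distance_transform(
            dist_b if dist_b is not None else np.full((L2, L2), np.inf), cfg.gauss_sigma
        ).astype(DTYPE),
    }
    if feats["intra_a"].shape[2] != cfg.intra_channels:
        raise ValueError(
            f"intra feature stack has {feats['intra_a'].shape[2]} channels, "
            f"config expects {cfg.intra_channels}"
        )
    return feats


# ---------------------------------------------------------------------------
# Training-time cropping


def _best_windows(interface: np.ndarray, L: int, w: int, rng) -> int:
    counts = np.convolve(interface.astype(float), np.ones(w), mode="valid")
    best = np.where(counts == counts.max())[0]
    return int(best[rng.integers(len(best))])


def crop_training_complex(feats: dict, truth: np.ndarray, max_monomer_len: int = 256,
                          rng=None):
    """Crop each over-length chain to a contiguous ``max_monomer_len`` window
    containing the most interface residues (random choice among ties); all
    feature channels and the truth map are re-windowed consistently.
    Returns (feats, truth, (start_a, start_b))."""
    rng = as_rng(rng)
    L1, L2 = truth.shape
    wa, wb = min(L1, max_monomer_len), min(L2, max_monomer_len)
    sa = 0 if wa == L1 else _best_windows(truth.any(axis=1), L1, wa, rng)
    sb = 0 if wb == L2 else _best_windows(truth.any(axis=0), L2, wb, rng)
    if (sa, wa, sb, wb) == (0, L1, 0, L2):
        return feats, truth, (0, 0)
    out = {
        "inter": feats["inter"][sa : sa + wa, sb : sb + wb],
        "intra_a": feats["intra_a"][sa : sa + wa, sa : sa + wa],
        "intra_b": feats["intra_b"][sb : sb + wb, sb : sb + wb],
        "dmod_a": feats["dmod_a"][sa : sa + wa, sa : sa + wa],
        "dmod_b": feats["dmod_b"][sb : sb + wb, sb : sb + wb],
    }
    return out, truth[sa : sa + wa, sb : sb + wb], (sa, sb)


# ---------------------------------------------------------------------------
# Training


@dataclass
class ContactTrainConfig:
    epochs: int = 6
    lr: float = 1e-3
    lr_decay: float = 0.98      # multiplicative per-epoch decay
    weight_decay: float = 0.0
    batch_size: int = 4         # same-shape complexes are stacked per step
    tail_average_epochs: int = 2  # Polyak-average parameters over the last k epochs
    focal: FocalLossParams = field(default_factory=FocalLossParams)
    max_monomer_len: int = 256


def _stack_feats(feats_list):
    return {k: np.stack([f[k] for f in feats_list]) for k in feats_list[0]}


def train_contact(instances, cfg: ContactNetConfig, tc: ContactTrainConfig = None, rng=0,
                  val_instances=None):
    """Train the contact network on (features, truth) instances with AdamW,
    per-epoch learning-rate decay and focal loss; complexes of identical
    shape are stacked into minibatches.

    Returns (params, loss_trace, val_topL_per_epoch); when validation
    instances are given the parameters with the best validation top-L
    precision are returned."""
    tc = tc or ContactTrainConfig()
    rng = as_rng(rng)
    params = init_contact_params(cfg, rng)
    opt = AdamW(params, betas=(0.9, 0.999), weight_decay=tc.weight_decay)

    def loss_fn(p, feats, truth):
        probs = sigmoid(contact_logits(p, cfg, feats))
        return focal_loss(probs, truth, tc.focal)

    vgrad = value_and_grad(loss_fn)
    trace, val_scores = [], []
    best = (None, -1.0)
    lr = tc.lr
    from .nnops import tree_copy, tree_map

    avg_params, avg_count = None, 0
    for epoch in range(tc.epochs):
        order = rng.permutation(len(instances))
        cropped = []
        for i in order:
            feats, truth = instances[i]
            cropped.append(crop_training_complex(feats, truth, tc.max_monomer_len, rng)[:2])
        buckets = {}
        for feats, truth in cropped:
            buckets.setdefault(truth.shape, []).append((feats, truth))
        batches = []
        for group in buckets.values():
            for s in range(0, len(group), tc.batch_size):
                chunk = group[s : s + tc.batch_size]
                batches.append((_stack_feats([f for f, _ in chunk]),
                                np.stack([t for _, t in chunk])))
        for bi in rng.permutation(len(batches)):
            feats, truth = batches[bi]
            loss, grads = vgrad(params, feats, truth)
            if not np.isfinite(loss):
                raise RuntimeError(f"contact training diverged at epoch {epoch}")
            params = opt.step(params, grads, lr=lr)
            trace.append(float(loss))
            if epoch >= tc.epochs - tc.tail_average_epochs:
                if avg_params is None:
                    avg_params = tree_copy(params)
                else:
                    avg_params = tree_map(np.add, avg_params, params)
                avg_count += 1
        lr *= tc.lr_decay
        if val_instances is not None:
            score = float(np.mean([
                top_k_precision(predict_contacts(params, cfg, f), t, min(t.shape))
                for f, t in val_instances
            ]))
            val_scores.append(score)
            if score > best[1]:
                best = (params, score)
    if avg_params is not None and avg_count > 0:
        inv = 1.0 / avg_count
        params = tree_map(lambda a: (a * inv).astype(a.dtype), avg_params)
    if val_instances is not None and best[0] is not None:
        params = best[0]
    return params, np.array(trace), val_scores
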
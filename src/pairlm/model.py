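"""Paired-sequence masked language model with hybrid intra-/inter-chain attention.

Each transformer block computes two scaled dot-product attention maps per
head: one with rotary positional embeddings (RoPE), used for intra-chain
token pairs, and one without positional encoding ("row" attention), used for
inter-chain pairs.  With ``M`` the token-level inter-chain indicator and
``W_lh`` a learnable scalar per layer/head, the pre-softmax logits are

    A = W_lh * M * A_row + (1 - M) * A_rope + M

so cross-chain attention is content-based (position-free) with a +1 logit
bias, while within-chain attention keeps relative-position structure.  The
training objective is the masked-LM loss: the cross-entropy over masked
residues averaged per chain and summed over the two chains.

Perplexity is exp of the mean negative log-likelihood pooled over all masked
residue positions of a pair: 1 for a perfect predictor, ~20 (the residue
alphabet size) for a random one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from . import nnops
from .nnops import (
    AdamW,
    gelu,
    layer_norm,
    layer_norm_init,
    linear,
    linear_init,
    log_softmax,
    softmax,
    warmup_linear_decay,
)
from .data import (
    BOS_IDX,
    EOS_IDX,
    MASK_IDX,
    N_RESIDUE_CLASSES,
    PAD_IDX,
    VOCAB_SIZE,
    X_IDX,
    MaskPlan,
    ProteinPair,
    TokenizedPair,
    as_rng,
    plan_interface_masking,
    plan_pretrain_masking,
    plan_random_rounds,
    tokenize_pair,
)


# predictions are distributions over residue classes only (20 canonical + X);
# special tokens are never loss targets, so they are excluded from the softmax
N_OUTPUT_CLASSES = X_IDX + 1


@dataclass
class ModelConfig:
    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 64
    d_head: int = 16
    d_ffn: int = 256
    vocab_size: int = VOCAB_SIZE
    max_len: int = 1024
    rope_base: float = 10000.0
    inter_attention: bool = True  # False ablates all cross-chain information flow
    # positional bootstrap at init: content-independent query/key components
    # (rotary phases then encode position) and amplified BOS/EOS anchors --
    # without these, first-block outputs carry no decodable position signal
    # and cross-chain routing sits on an optimization saddle
    qk_bias_init: float = 4.0
    special_embed_scale: float = 15.0

    def __post_init__(self):
        if self.d_model != self.n_heads * self.d_head:
            raise ValueError("d_model must equal n_heads * d_head")
        if self.d_head % 2 != 0:
            raise ValueError("d_head must be even for rotary embeddings")
        for name in ("n_layers", "n_heads", "d_model", "d_head", "d_ffn", "vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def tiny_config(**overrides) -> ModelConfig:
    """The small configuration used throughout tests and experiments."""
    return ModelConfig(**overrides)


def paper_scale_config() -> ModelConfig:
    """The full-scale instance (33 blocks, 650M-class); constructible only."""
    return ModelConfig(n_layers=33, n_heads=20, d_model=1280, d_head=64, d_ffn=5120)


# ---------------------------------------------------------------------------
# Rotary positional embedding


_rope_cache: dict = {}


def _rope_tables(positions: np.ndarray, d_head: int, base: float):
    """Interleaved cos/sin tables (n, d_head) plus the constant pair-swap
    matrix S with (x @ S)[2i] = -x[2i+1], (x @ S)[2i+1] = x[2i]."""
    positions = np.asarray(positions)
    key = (positions.tobytes(), d_head, base)
    hit = _rope_cache.get(key)
    if hit is not None:
        return hit
    half = d_head // 2
    inv_freq = base ** (-np.arange(half) * 2.0 / d_head)
    ang = positions.astype(np.float64)[:, None] * inv_freq[None, :]
    cos = np.repeat(np.cos(ang), 2, axis=-1).astype(nnops.DTYPE)
    sin = np.repeat(np.sin(ang), 2, axis=-1).astype(nnops.DTYPE)
    swap = np.zeros((d_head, d_head), dtype=nnops.DTYPE)
    for i in range(0, d_head, 2):
        swap[i + 1, i] = -1.0
        swap[i, i + 1] = 1.0
    if len(_rope_cache) > 64:
        _rope_cache.clear()
    _rope_cache[key] = (cos, sin, swap)
    return cos, sin, swap


def rope_transform(x, positions, base: float = 10000.0):
    """Rotate query/key vectors by their absolute token position.

    ``x``: (..., n, d_head) with d_head even; ``positions``: (n,).  The
    rotation is norm-preserving and makes rotated-q . rotated-k depend only
    on the position offset.  Implemented as x*cos + (x S)*sin with a
    constant pair-swap matrix S (no slicing, cheap reverse-mode gradient).
    """
    d_head = x.shape[-1]
    if d_head % 2 != 0:
        raise ValueError("d_head must be even")
    cos, sin, swap = _rope_tables(positions, d_head, base)
    return x * cos + anp.matmul(x, swap) * sin


def hybrid_logits(a_row, a_rope, M, W):
    """Combine position-free and rotary attention logits with the inter-chain
    mask: ``W*M*a_row + (1-M)*a_rope + M`` elementwise."""
    if a_row.shape != a_rope.shape or a_row.shape[-2:] != M.shape[-2:]:
        raise ValueError(
            f"shape mismatch: a_row {a_row.shape}, a_rope {a_rope.shape}, M {M.shape}"
        )
    return W * M * a_row + (1.0 - M) * a_rope + M


# ---------------------------------------------------------------------------
# Parameters


def init_params(config: ModelConfig, rng) -> dict:
    rng = as_rng(rng)
    d, f = config.d_model, config.d_ffn

    def qk_linear():
        p = linear_init(rng, d, d)
        p["b"] = rng.normal(0.0, config.qk_bias_init, d).astype(nnops.DTYPE)
        return p

    def layer():
        return {
            "ln1": layer_norm_init(d),
            "wq": qk_linear(),
            "wk": qk_linear(),
            "wv": linear_init(rng, d, d),
            "wo": linear_init(rng, d, d),
            "w_hyb": np.ones(config.n_heads, dtype=nnops.DTYPE),
            "ln2": layer_norm_init(d),
            "ffn1": linear_init(rng, d, f),
            "ffn2": linear_init(rng, f, d),
        }

    embed = rng.normal(0.0, 0.02, size=(config.vocab_size, d))
    embed[BOS_IDX] *= config.special_embed_scale
    embed[EOS_IDX] *= config.special_embed_scale
    return {
        "embed": embed.astype(nnops.DTYPE),
        "layers": [layer() for _ in range(config.n_layers)],
        "ln_f": layer_norm_init(d),
        "head": linear_init(rng, d, config.vocab_size),
    }


# ---------------------------------------------------------------------------
# Forward pass


def _forward_core(params, cfg: ModelConfig, tokens, inter_mask, pad_mask=None,
                  collect_attention=False):
    """tokens (B,T) int; inter_mask (B,T,T); pad_mask (B,T) with 1=real.

    Returns (vocab logits (B,T,V), list of per-layer softmax attention
    (B,H,T,T), final hidden states (B,T,d))."""
    B, T = tokens.shape
    h = params["embed"][tokens]
    positions = np.arange(T)
    scale = float(1.0 / np.sqrt(cfg.d_head))
    attn_store = []
    key_bias = None
    if pad_mask is not None:
        key_bias = -1e9 * (1.0 - pad_mask)[:, None, None, :]
    for lp in params["layers"]:
        x = layer_norm(lp["ln1"], h)

        def split_heads(p):
            y = linear(p, x)
            y = anp.reshape(y, (B, T, cfg.n_heads, cfg.d_head))
            return anp.transpose(y, (0, 2, 1, 3))

        q, k, v = split_heads(lp["wq"]), split_heads(lp["wk"]), split_heads(lp["wv"])
        a_row = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) * scale
        qr = rope_transform(q, positions, cfg.rope_base)
        kr = rope_transform(k, positions, cfg.rope_base)
        a_rope = anp.matmul(qr, anp.transpose(kr, (0, 1, 3, 2))) * scale
        W = anp.reshape(lp["w_hyb"], (1, cfg.n_heads, 1, 1))
        M = inter_mask[:, None, :, :]
        logits = hybrid_logits(a_row, a_rope, M, W)
        if not cfg.inter_attention:
            logits = logits - 1e9 * M
        if key_bias is not None:
            logits = logits + key_bias
        a = softmax(logits, axis=-1)
        if collect_attention:
            attn_store.append(a)
        out = anp.matmul(a, v)
        out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (B, T, cfg.d_model))
        h = h + linear(lp["wo"], out)
        x2 = layer_norm(lp["ln2"], h)
        h = h + linear(lp["ffn2"], gelu(linear(lp["ffn1"], x2)))
    h_final = layer_norm(params["ln_f"], h)
    return linear(params["head"], h_final), attn_store, h_final


@dataclass
class AttentionBundle:
    """Per-layer, per-head attention split by chain, plus final-layer
    per-residue embeddings.  Shapes: intra_a[l] (H, La, La), intra_b[l]
    (H, Lb, Lb), inter[l] (H, La, Lb) (chain-A query rows); embeddings
    {'A': (La, d), 'B': (Lb, d)}.  Special tokens are dropped."""

    intra_a: list
    intra_b: list
    inter: list
    embeddings: dict
    inter_ba: list = None  # chain-B query rows (H, Lb, La), convenience view


@dataclass
class MaskedBatch:
    """A tokenized pair with masked positions replaced by the MASK token."""

    tokenized: TokenizedPair
    plan: MaskPlan
    input_tokens: np.ndarray
    mask_token_positions: np.ndarray  # token positions (chain A then chain B)
    targets: np.ndarray               # true residue token indices at those positions
    n_masked_a: int

    @property
    def n_masked(self) -> int:
        return len(self.mask_token_positions)


def make_masked_batch(pair: ProteinPair, plan: MaskPlan) -> MaskedBatch:
    plan.validate(pair)
    tk = tokenize_pair(pair)
    la = len(pair.chain_a)
    pos_a = np.array(sorted(plan.masked_a), dtype=np.int64) + 1
    pos_b = np.array(sorted(plan.masked_b), dtype=np.int64) + la + 3
    positions = np.concatenate([pos_a, pos_b])
    tokens = tk.tokens.copy()
    targets = tokens[positions].copy()
    tokens[positions] = MASK_IDX
    return MaskedBatch(tk, plan, tokens, positions, targets, len(pos_a))


# ---------------------------------------------------------------------------
# Losses and perplexity


def mlm_loss(logits, batch: MaskedBatch):
    """Masked-LM loss: mean cross-entropy over each chain's masked residues,
    summed over the two chains; a chain with no masked positions contributes
    zero.  ``logits``: (T, vocab) for the masked input."""
    if batch.n_masked == 0:
        raise ValueError("no masked positions in either chain")
    lp = log_softmax(logits[..., :N_OUTPUT_CLASSES], axis=-1)
    na = batch.n_masked_a
    loss = 0.0
    for pos, tgt in (
        (batch.mask_token_positions[:na], batch.targets[:na]),
        (batch.mask_token_positions[na:], batch.targets[na:]),
    ):
        if len(pos):
            loss = loss - anp.mean(lp[pos, tgt])
    return loss


def perplexity(nll_per_position) -> float:
    """exp of the mean negative log-likelihood pooled over masked positions."""
    nll = np.asarray(nll_per_position, dtype=np.float64)
    if nll.size == 0:
        raise ValueError("perplexity requires at least one masked position")
    return float(np.exp(nll.mean()))


class UniformModel:
    """Reference scorer assigning probability 1/n to every residue class."""

    def __init__(self, n_classes: int = N_RESIDUE_CLASSES):
        self.n_classes = n_classes

    def score(self, batch: MaskedBatch) -> np.ndarray:
        return np.full(batch.n_masked, np.log(self.n_classes))


class EchoModel:
    """Reference scorer assigning probability 1 to the true residue."""

    def score(self, batch: MaskedBatch) -> np.ndarray:
        return np.zeros(batch.n_masked)


def evaluate_perplexity_random(model, pair: ProteinPair, fraction: float = 0.15,
                               rng=0) -> float:
    """Iterative-masking perplexity: non-overlapping rounds of
    ``fraction`` of residues per chain until every position was masked
    exactly once; NLLs pooled over all positions before exponentiation."""
    plans = plan_random_rounds(pair, fraction, rng)
    nlls = [model.score(make_masked_batch(pair, plan)) for plan in plans]
    return perplexity(np.concatenate(nlls))


def evaluate_perplexity_interface(model, pair: ProteinPair, mode: str) -> float:
    """Interface-masking perplexity.  ``mode`` 'dual' masks all interface
    residues of both chains in one pass; 'single' runs one pass per chain
    (chain A's interface masked, then chain B's) and pools the NLLs."""
    mode = mode.lower()
    if mode == "dual":
        plans = [plan_interface_masking(pair, "dual")]
    elif mode == "single":
        plans = [
            plan_interface_masking(pair, "single_a"),
            plan_interface_masking(pair, "single_b"),
        ]
    else:
        raise ValueError(f"unknown interface perplexity mode {mode!r}")
    nlls = [model.score(make_masked_batch(pair, plan)) for plan in plans]
    return perplexity(np.concatenate(nlls))


# ---------------------------------------------------------------------------
# The model object


class PairLanguageModel:
    """Configuration + parameters with forward/scoring/feature extraction."""

    def __init__(self, config: ModelConfig, params: Optional[dict] = None, rng=0):
        self.config = config
        self.params = params if params is not None else init_params(config, rng)

    # -- forward ---------------------------------------------------------

    def _check_length(self, n_tokens: int):
        if n_tokens > self.config.max_len:
            raise ValueError(
                f"input of {n_tokens} tokens exceeds max_len={self.config.max_len}; crop first"
            )

    def forward(self, batch: MaskedBatch, collect_attention: bool = False):
        """Run one masked pair; returns (logits (T,vocab), AttentionBundle or None)."""
        self._check_length(len(batch.input_tokens))
        tokens = batch.input_tokens[None, :]
        inter = batch.tokenized.inter_mask[None, :, :]
        logits, attn, h = _forward_core(
            self.params, self.config, tokens, inter, collect_attention=collect_attention
        )
        bundle = None
        if collect_attention:
            bundle = self._extract_bundle(batch.tokenized, attn, h)
        return np.asarray(logits[0]), bundle

    def score(self, batch: MaskedBatch) -> np.ndarray:
        """Per-masked-position negative log-likelihood of the true residue."""
        logits, _ = self.forward(batch)
        lp = np.asarray(log_softmax(logits[..., :N_OUTPUT_CLASSES], axis=-1))
        return -lp[batch.mask_token_positions, batch.targets]

    def attention_bundle(self, pair: ProteinPair) -> AttentionBundle:
        """Unmasked forward pass returning attention maps and embeddings."""
        tk = tokenize_pair(pair)
        self._check_length(len(tk))
        logits, attn, h = _forward_core(
            self.params, self.config, tk.tokens[None, :], tk.inter_mask[None, :, :],
            collect_attention=True,
        )
        return self._extract_bundle(tk, attn, h)

    def _extract_bundle(self, tk: TokenizedPair, attn_store, h) -> AttentionBundle:
        pos_a = tk.residue_token_positions("A")
        pos_b = tk.residue_token_positions("B")
        intra_a, intra_b, inter, inter_ba = [], [], [], []
        for a in attn_store:
            a = np.asarray(a[0])  # (H,T,T)
            intra_a.append(a[:, pos_a[:, None], pos_a[None, :]])
            intra_b.append(a[:, pos_b[:, None], pos_b[None, :]])
            inter.append(a[:, pos_a[:, None], pos_b[None, :]])
            inter_ba.append(a[:, pos_b[:, None], pos_a[None, :]])
        h = np.asarray(h[0])
        return AttentionBundle(
            intra_a=intra_a, intra_b=intra_b, inter=inter,
            embeddings={"A": h[pos_a], "B": h[pos_b]},
            inter_ba=inter_ba,
        )

    # -- persistence -----------------------------------------------------

    def save(self, path):
        flat = dict(_flatten("", self.params))
        flat["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **flat)

    @classmethod
    def load(cls, path) -> "PairLanguageModel":
        with np.load(path) as zf:
            cfg = ModelConfig(**json.loads(bytes(zf["__config__"]).decode()))
            flat = {k: zf[k] for k in zf.files if k != "__config__"}
        return cls(cfg, params=_unflatten(flat))


def _flatten(prefix, tree):
    if isinstance(tree, dict):
        for k in tree:
            yield from _flatten(f"{prefix}{k}/", tree[k])
    elif isinstance(tree, (list, tuple)):
        for i, t in enumerate(tree):
            yield from _flatten(f"{prefix}{i}/", t)
    else:
        yield prefix[:-1], np.asarray(tree)


def _unflatten(flat: dict):
    def insert(node, parts, value):
        head = parts[0]
        if len(parts) == 1:
            node[head] = value
            return
        insert(node.setdefault(head, {}), parts[1:], value)

    root: dict = {}
    for key, value in flat.items():
        insert(root, key.split("/"), value)

    def listify(node):
        if not isinstance(node, dict):
            return node
        if node and all(k.isdigit() for k in node):
            return [listify(node[str(i)]) for i in range(len(node))]
        return {k: listify(v) for k, v in node.items()}

    return listify(root)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    peak_lr: float = 1e-3
    final_lr: float = 1e-4
    warmup_frac: float = 0.06
    weight_decay: float = 0.01
    betas: tuple = (0.9, 0.98)
    homomer_joint: bool = True
    log_every: int = 50
    # optional masking-plan override: callable pair -> MaskPlan (e.g. an
    # interface Single plan for the coupling-recovery experiments); None
    # selects the source-dependent pretraining rule
    plan_fn: Optional[object] = None


def _assemble_batch(pairs, plans):
    """Pad masked pairs to a common length; returns arrays for the batched
    loss (tokens, inter masks, pad mask, flat gather indices and weights)."""
    batches = [make_masked_batch(p, plan) for p, plan in zip(pairs, plans)]
    T = max(len(b.input_tokens) for b in batches)
    B = len(batches)
    tokens = np.full((B, T), PAD_IDX, dtype=np.int64)
    inter = np.zeros((B, T, T), dtype=nnops.DTYPE)
    pad = np.zeros((B, T), dtype=nnops.DTYPE)
    rows, cols, tgts, wts = [], [], [], []
    for i, b in enumerate(batches):
        n = len(b.input_tokens)
        tokens[i, :n] = b.input_tokens
        inter[i, :n, :n] = b.tokenized.inter_mask
        pad[i, :n] = 1.0
        na = b.n_masked_a
        for pos, tgt in (
            (b.mask_token_positions[:na], b.targets[:na]),
            (b.mask_token_positions[na:], b.targets[na:]),
        ):
            if len(pos):
                rows.extend([i] * len(pos))
                cols.extend(pos.tolist())
                tgts.extend(tgt.tolist())
                wts.extend([1.0 / len(pos)] * len(pos))
    return (
        tokens,
        inter,
        pad,
        np.array(rows),
        np.array(cols),
        np.array(tgts),
        np.array(wts),
    )


def batched_mlm_loss(params, cfg, tokens, inter, pad, rows, cols, tgts, wts):
    logits, _, _ = _forward_core(params, cfg, tokens, inter, pad_mask=pad)
    lp = log_softmax(logits[..., :N_OUTPUT_CLASSES], axis=-1)
    picked = lp[rows, cols, tgts]
    return -anp.sum(wts * picked) / tokens.shape[0]


def train_mlm(dataset, config: ModelConfig, train_config: TrainConfig = None,
              rng=0, model: Optional[PairLanguageModel] = None, stop_fn=None,
              stop_every: int = 4):
    """Masked-LM pretraining on a corpus of pairs.

    Masking follows each pair's source rule (interface-weighted for PDB,
    uniform 15% otherwise; homomers masked jointly by default), unless the
    train config carries a ``plan_fn`` override.  AdamW with β=(0.9, 0.98),
    linear warm-up then linear decay.  When ``stop_fn`` is given it is
    called with the live model every ``stop_every`` epochs and training
    halts early once it returns True.  Returns
    ``(PairLanguageModel, loss_trace)``.  Aborts on non-finite loss.
    """
    tc = train_config or TrainConfig()
    rng = as_rng(rng)
    if model is None:
        model = PairLanguageModel(config, rng=rng)
    params = model.params
    n = len(dataset)
    if n == 0:
        raise ValueError("empty training dataset")
    steps_per_epoch = max(1, n // tc.batch_size)
    total_steps = tc.epochs * steps_per_epoch
    warmup = int(tc.warmup_frac * total_steps)
    opt = AdamW(params, betas=tc.betas, weight_decay=tc.weight_decay)
    loss_fn = value_and_grad(batched_mlm_loss)
    trace = []
    step = 0
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        for s in range(steps_per_epoch):
            idx = order[s * tc.batch_size : (s + 1) * tc.batch_size]
            pairs = [dataset[i] for i in idx]
            if tc.plan_fn is not None:
                plans = [tc.plan_fn(p) for p in pairs]
            else:
                plans = [
                    plan_pretrain_masking(p, rng, homomer_joint=tc.homomer_joint)
                    for p in pairs
                ]
            args = _assemble_batch(pairs, plans)
            loss, grads = loss_fn(params, config, *args)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss!r} at step {step}"
                )
            lr = warmup_linear_decay(step, total_steps, warmup, tc.peak_lr, tc.final_lr)
            params = opt.step(params, grads, lr=lr)
            trace.append(float(loss))
            step += 1
        if stop_fn is not None and (epoch + 1) % stop_every == 0:
            model.params = params
            if stop_fn(model):
                break
    model.params = params
    return model, np.array(trace)
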
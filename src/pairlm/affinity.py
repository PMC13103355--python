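"""Binding-affinity regression on top of the pair language model.

Only the final transformer block of the backbone is fine-tuned, together
with a small readout: final-layer residue embeddings of the two (possibly
multi-chain, concatenated) sides are max-pooled along the sequence dimension
and passed through two fully connected layers with an intermediate ReLU.
Training minimizes mean squared error at batch size 1; cross-validation
folds are grouped so samples sharing a complex identifier never straddle a
train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from .data import ProteinPair, ProteinSequence, Source, as_rng, crop_pair, tokenize_pair
from .model import ModelConfig, PairLanguageModel, _forward_core
from .nnops import AdamW, linear, linear_init, relu, tree_copy


@dataclass
class AffinitySample:
    sample_id: str
    receptor_chains: List[ProteinSequence]
    ligand_chains: List[ProteinSequence]
    affinity: float          # ΔG-like signed energy, kcal/mol scale
    group_id: str
    n_couplings: Optional[int] = None  # known truth for synthetic samples

    def __post_init__(self):
        if not self.receptor_chains or not self.ligand_chains:
            raise ValueError("each side needs at least one chain")
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")


def concat_side(chains: List[ProteinSequence]) -> ProteinSequence:
    """Concatenate a side's chains, in the given order, with no separator.
    Order-dependent by construction."""
    if not chains:
        raise ValueError("cannot concatenate an empty chain list")
    if len(chains) == 1:
        return chains[0]
    return ProteinSequence(
        "+".join(c.id for c in chains), "".join(c.residues for c in chains)
    )


def sample_to_pair(sample: AffinitySample) -> ProteinPair:
    return ProteinPair(
        concat_side(sample.receptor_chains),
        concat_side(sample.ligand_chains),
        is_homomer=False,
        source=Source.SYNTHETIC,
    )


@dataclass
class AffinityConfig:
    hidden: int = 128
    per_side_pooling: bool = False  # default: one max-pool over the whole pair


def init_readout(rng, d_model: int, cfg: AffinityConfig) -> dict:
    rng = as_rng(rng)
    d_in = 2 * d_model if cfg.per_side_pooling else d_model
    return {
        "fc1": linear_init(rng, d_in, cfg.hidden),
        "fc2": linear_init(rng, cfg.hidden, 1),
    }


class AffinityModel:
    """Backbone + readout; only the backbone's last transformer block and
    the readout carry trainable state."""

    def __init__(self, backbone: PairLanguageModel, cfg: AffinityConfig = None,
                 readout: Optional[dict] = None, rng=0):
        self.backbone = backbone
        self.cfg = cfg or AffinityConfig()
        self.readout = readout if readout is not None else init_readout(
            rng, backbone.config.d_model, self.cfg
        )

    # -- forward ---------------------------------------------------------

    def _prep(self, sample: AffinitySample):
        pair = sample_to_pair(sample)
        if pair.total_length + 4 > self.backbone.config.max_len:
            pair, _ = crop_pair(pair, self.backbone.config.max_len - 4)
        tk = tokenize_pair(pair)
        pos_a = tk.residue_token_positions("A")
        pos_b = tk.residue_token_positions("B")
        return tk, pos_a, pos_b

    def predict(self, sample: AffinitySample) -> float:
        tk, pos_a, pos_b = self._prep(sample)
        trainable = {"last_block": self.backbone.params["layers"][-1],
                     "readout": self.readout}
        val = _affinity_forward(
            trainable, self.backbone.params, self.backbone.config, self.cfg,
            tk.tokens, tk.inter_mask, pos_a, pos_b,
        )
        return float(val)


def _affinity_forward(trainable, backbone_params, mcfg: ModelConfig, acfg: AffinityConfig,
                      tokens, inter_mask, pos_a, pos_b):
    params = {
        "embed": backbone_params["embed"],
        "layers": list(backbone_params["layers"][:-1]) + [trainable["last_block"]],
        "ln_f": backbone_params["ln_f"],
        "head": backbone_params["head"],
    }
    _, _, h = _forward_core(params, mcfg, tokens[None, :], inter_mask[None, :, :])
    h = h[0]
    if acfg.per_side_pooling:
        pooled = anp.concatenate(
            [anp.max(h[pos_a], axis=0), anp.max(h[pos_b], axis=0)]
        )
    else:
        pooled = anp.max(h[np.concatenate([pos_a, pos_b])], axis=0)
    out = linear(trainable["readout"]["fc2"],
                 relu(linear(trainable["readout"]["fc1"], pooled)))
    return out[0]


def predict_affinity(model: AffinityModel, sample: AffinitySample) -> float:
    return model.predict(sample)


@dataclass
class AffinityTrainConfig:
    epochs: int = 8
    lr: float = 1e-3
    weight_decay: float = 0.0


def finetune(backbone: PairLanguageModel, samples: List[AffinitySample],
             rng=0, cfg: AffinityConfig = None, tc: AffinityTrainConfig = None):
    """Fine-tune the last transformer block plus the readout with MSE loss at
    batch size 1.  All other backbone parameters are untouched (the returned
    model shares them bit-for-bit with a copy of the input backbone).

    Returns (AffinityModel, loss_trace)."""
    tc = tc or AffinityTrainConfig()
    cfg = cfg or AffinityConfig()
    rng = as_rng(rng)
    frozen = tree_copy(backbone.params)
    model = PairLanguageModel(backbone.config, params=frozen)
    aff = AffinityModel(model, cfg, rng=rng)
    trainable = {
        "last_block": tree_copy(frozen["layers"][-1]),
        "readout": aff.readout,
    }

    def loss_fn(tr, tokens, inter_mask, pos_a, pos_b, target):
        pred = _affinity_forward(tr, frozen, model.config, cfg,
                                 tokens, inter_mask, pos_a, pos_b)
        return (pred - target) ** 2

    vgrad = value_and_grad(loss_fn)
    opt = AdamW(trainable, weight_decay=tc.weight_decay)
    prepped = []
    for s in samples:
        tk, pos_a, pos_b = aff._prep(s)
        prepped.append((tk.tokens, tk.inter_mask, pos_a, pos_b, s.affinity))
    trace = []
    for _ in range(tc.epochs):
        for i in rng.permutation(len(prepped)):
            loss, grads = vgrad(trainable, *prepped[i])
            if not np.isfinite(loss):
                raise RuntimeError("affinity fine-tuning diverged (non-finite loss)")
            trainable = opt.step(trainable, grads, lr=tc.lr)
            trace.append(float(loss))
    model.params["layers"][-1] = trainable["last_block"]
    aff.readout = trainable["readout"]
    return aff, np.array(trace)


def grouped_kfold(samples: List[AffinitySample], k: int = 5, rng=0) -> List[List[int]]:
    """Group-aware folds: every sample of a group lands in one fold; groups
    are assigned greedily, largest first, to the currently smallest fold
    (ties broken by seeded rng).  Returns k lists of sample indices."""
    rng = as_rng(rng)
    groups = {}
    for idx, s in enumerate(samples):
        groups.setdefault(s.group_id, []).append(idx)
    if k > len(groups):
        raise ValueError(f"k={k} exceeds the number of groups ({len(groups)})")
    order = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    folds = [[] for _ in range(k)]
    for _, members in order:
        sizes = np.array([len(f) for f in folds])
        candidates = np.where(sizes == sizes.min())[0]
        folds[int(candidates[rng.integers(len(candidates))])].extend(members)
    return folds


def regression_metrics(pred, truth) -> dict:
    from .metrics import correlation

    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return {
        "pcc": correlation(pred, truth, "pearson"),
        "srcc": correlation(pred, truth, "spearman"),
        "rmse": float(np.sqrt(np.mean((pred - truth) ** 2))),
        "mae": float(np.mean(np.abs(pred - truth))),
    }
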
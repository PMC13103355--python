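"""Binary interaction prediction from pooled pair-LM features.

The (frozen) language model supplies five features per pair: the two
chains' final-layer embeddings and the final-layer intra-A, intra-B and
inter attention maps (heads as channels).  Max pooling and mean pooling
along the residue dimension form two parallel branches; in each branch
every pooled feature is linearly projected to a unified width, the
projections are concatenated, and a five-layer MLP (layer norm + ReLU after
the first four layers, sigmoid after the fifth) emits a probability.  The
final score is the average of the two branch probabilities; at inference
the top five cross-validation heads are ensembled by averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from sklearn.model_selection import StratifiedKFold

from .data import ProteinPair, as_rng
from .model import PairLanguageModel
from .nnops import AdamW, layer_norm, layer_norm_init, linear, linear_init, relu, sigmoid

FEATURE_NAMES = ("emb_a", "emb_b", "intra_a", "intra_b", "inter")
POOL_MODES = ("max", "mean")


def extract_features(model: PairLanguageModel, pair: ProteinPair) -> dict:
    """Final-layer embeddings per chain and attention maps with heads as
    channels; special-token positions are dropped."""
    bundle = model.attention_bundle(pair)
    return {
        "emb_a": bundle.embeddings["A"],                      # (La, d)
        "emb_b": bundle.embeddings["B"],                      # (Lb, d)
        "intra_a": np.moveaxis(bundle.intra_a[-1], 0, -1),    # (La, La, H)
        "intra_b": np.moveaxis(bundle.intra_b[-1], 0, -1),    # (Lb, Lb, H)
        "inter": np.moveaxis(bundle.inter[-1], 0, -1),        # (La, Lb, H)
    }


def pool_features(features: dict, mode: str) -> dict:
    """Pool each feature over its residue axes (vectors once; matrices over
    both axes sequentially), leaving channel dimensions."""
    if mode not in POOL_MODES:
        raise ValueError(f"mode must be one of {POOL_MODES}")
    agg = np.max if mode == "max" else np.mean
    out = {}
    for name in FEATURE_NAMES:
        f = features[name]
        if f.size == 0:
            raise ValueError(f"empty feature {name!r}")
        while f.ndim > 1:
            f = agg(f, axis=0)
        out[name] = f
    return out


def pooled_feature_dims(features: dict) -> dict:
    return {name: int(np.atleast_1d(pool_features(features, "max")[name]).shape[0])
            for name in FEATURE_NAMES}


@dataclass
class PPIHeadConfig:
    unified_width: int = 256
    mlp_hidden: int = 512
    n_mlp_layers: int = 5


def init_branch(rng, feature_dims: dict, cfg: PPIHeadConfig) -> dict:
    rng = as_rng(rng)
    proj = {name: linear_init(rng, feature_dims[name], cfg.unified_width)
            for name in FEATURE_NAMES}
    widths = [len(FEATURE_NAMES) * cfg.unified_width] + \
        [cfg.mlp_hidden] * (cfg.n_mlp_layers - 1) + [1]
    mlp = [linear_init(rng, widths[i], widths[i + 1]) for i in range(cfg.n_mlp_layers)]
    norms = [layer_norm_init(widths[i + 1]) for i in range(cfg.n_mlp_layers - 1)]
    return {"proj": proj, "mlp": mlp, "norms": norms}


def init_head(rng, feature_dims: dict, cfg: PPIHeadConfig = None) -> dict:
    cfg = cfg or PPIHeadConfig()
    rng = as_rng(rng)
    return {mode: init_branch(rng, feature_dims, cfg) for mode in POOL_MODES}


def project_and_concat(branch_params, pooled: dict):
    """Per-feature linear projection to the unified width, concatenated.
    Works on single pooled dicts or (batch, d) stacks."""
    return anp.concatenate(
        [linear(branch_params["proj"][name], pooled[name]) for name in FEATURE_NAMES],
        axis=-1,
    )


def branch_mlp(branch_params, vector):
    """Five linear layers; the first four each followed by layer norm and
    ReLU; sigmoid on the final scalar.  Accepts a single vector or a
    (batch, width) stack."""
    h = vector
    for lin, norm in zip(branch_params["mlp"][:-1], branch_params["norms"]):
        h = relu(layer_norm(norm, linear(lin, h)))
    return sigmoid(linear(branch_params["mlp"][-1], h))[..., 0]


@dataclass
class PPIPrediction:
    probability: float
    branch_probs: tuple  # (max branch, mean branch)


def _head_probability(head_params, pooled_by_mode):
    probs = [
        branch_mlp(head_params[mode], project_and_concat(head_params[mode], pooled_by_mode[mode]))
        for mode in POOL_MODES
    ]
    return 0.5 * (probs[0] + probs[1]), probs


def predict(head_params, features: dict) -> PPIPrediction:
    pooled = {mode: pool_features(features, mode) for mode in POOL_MODES}
    p, probs = _head_probability(head_params, pooled)
    return PPIPrediction(float(p), (float(probs[0]), float(probs[1])))


def ensemble_probability(heads: Sequence[dict], features: dict) -> float:
    """Mean of the member heads' averaged branch probabilities."""
    if not heads:
        raise ValueError("empty ensemble")
    return float(np.mean([predict(h, features).probability for h in heads]))


def bce_loss(probs, labels, eps: float = 1e-7):
    """Binary cross-entropy, mean over the batch."""
    probs = anp.clip(probs, eps, 1.0 - eps)
    labels = anp.asarray(labels)
    return -anp.mean(labels * anp.log(probs) + (1.0 - labels) * anp.log(1.0 - probs))


@dataclass
class PPITrainConfig:
    epochs: int = 12
    batch_size: int = 32
    lr: float = 5e-4
    weight_decay: float = 0.0


def _stack_pooled(pooled_list, idx=None):
    """Stack per-sample pooled dicts into (batch, d) arrays per feature."""
    idx = range(len(pooled_list)) if idx is None else idx
    return {
        mode: {
            name: np.stack([np.atleast_1d(pooled_list[i][mode][name]) for i in idx])
            for name in FEATURE_NAMES
        }
        for mode in POOL_MODES
    }


def _batch_probabilities(head_params, stacked):
    probs = [
        branch_mlp(head_params[mode], project_and_concat(head_params[mode], stacked[mode]))
        for mode in POOL_MODES
    ]
    return 0.5 * (probs[0] + probs[1])


def _batch_loss(head_params, stacked, labels):
    return bce_loss(_batch_probabilities(head_params, stacked), labels)


def train_cv(features_list: List[dict], labels, cfg: PPIHeadConfig = None,
             k: int = 10, tc: PPITrainConfig = None, rng=0, n_ensemble: int = 5):
    """Stratified k-fold cross-validation of the interaction head.

    Folds preserve the class ratio (within one sample).  Per fold, the
    epoch checkpoint with the best validation AUPRC is kept; the
    ``n_ensemble`` best heads across folds form the inference ensemble.

    Returns a dict with: heads (ensemble), fold_scores, oof_probs
    (out-of-fold probabilities from each fold's best head), labels."""
    from .metrics import auprc

    cfg = cfg or PPIHeadConfig()
    tc = tc or PPITrainConfig()
    rng = as_rng(rng)
    labels = np.asarray(labels)
    if labels.sum() < k:
        raise ValueError("need at least one positive sample per fold")
    pooled_all = [
        {mode: pool_features(f, mode) for mode in POOL_MODES} for f in features_list
    ]
    dims = pooled_feature_dims(features_list[0])
    vgrad = value_and_grad(_batch_loss)
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    candidates = []  # (val_auprc, fold, head_params)
    oof = np.zeros(len(labels))
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        if labels[va_idx].sum() == 0 or labels[tr_idx].sum() == 0:
            raise ValueError(f"fold {fold} has no positive samples")
        head = init_head(rng, dims, cfg)
        opt = AdamW(head, weight_decay=tc.weight_decay)
        best = (-1.0, None)
        va_stack = _stack_pooled(pooled_all, va_idx)
        for _ in range(tc.epochs):
            order = rng.permutation(tr_idx)
            for s in range(0, len(order), tc.batch_size):
                idx = order[s : s + tc.batch_size]
                loss, grads = vgrad(head, _stack_pooled(pooled_all, idx), labels[idx])
                if not np.isfinite(loss):
                    raise RuntimeError("interaction-head training diverged")
                head = opt.step(head, grads, lr=tc.lr)
            score = auprc(np.asarray(_batch_probabilities(head, va_stack)),
                          labels[va_idx])
            if score > best[0]:
                best = (score, head)
        candidates.append((best[0], fold, best[1]))
        oof[va_idx] = np.asarray(_batch_probabilities(best[1], va_stack))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return {
        "heads": [c[2] for c in candidates[:n_ensemble]],
        "fold_scores": [c[0] for c in sorted(candidates, key=lambda t: t[1])],
        "oof_probs": oof,
        "labels": labels,
    }
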
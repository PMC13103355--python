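"""Paired protein sequences: containers, tokenization, masking plans, cropping, sampling.

A *pair* is two amino-acid chains that are modeled jointly.  Each chain is
tokenized independently with begin/end tokens and the two token runs are
concatenated, so a pair of lengths (La, Lb) becomes La + Lb + 4 tokens.  The
token-level binary matrix ``inter_mask`` marks inter-protein position pairs
(1 when the two tokens belong to different chains) and drives the hybrid
attention rule of the language model.

Masking plans implement the three protocols used for training and perplexity
evaluation: iterative non-overlapping random rounds, interface Dual/Single
masking, and source-dependent pretraining masking (interface-weighted for
structure-derived pairs, uniform for interaction-database pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

# 20 canonical residues + X (unknown) + specials.  Minimal self-contained
# vocabulary; indices are stable and shared by every model in the package.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
X_IDX = 20
BOS_IDX = 21
EOS_IDX = 22
MASK_IDX = 23
PAD_IDX = 24
VOCAB_SIZE = 25
N_RESIDUE_CLASSES = 20  # prediction targets; X never appears as a target
SPECIAL = -1  # residue_index_map entry for BOS/EOS

_ALPHABET = set(CANONICAL_AA) | {"X"}


def as_rng(rng) -> np.random.Generator:
    """Accept a Generator or an integer seed; always return a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class Source(str, Enum):
    PDB = "PDB"
    STRING = "STRING"
    SYNTHETIC = "SYNTHETIC"


class MaskStrategy(str, Enum):
    RANDOM_ROUND = "RANDOM_ROUND"
    PRETRAIN_PDB = "PRETRAIN_PDB"
    PRETRAIN_STRING = "PRETRAIN_STRING"
    INTERFACE_DUAL = "INTERFACE_DUAL"
    INTERFACE_SINGLE_A = "INTERFACE_SINGLE_A"
    INTERFACE_SINGLE_B = "INTERFACE_SINGLE_B"


@dataclass(frozen=True)
class ProteinSequence:
    """One chain: an id, residues over the 20-letter alphabet plus X, and an
    optional set of 0-based interface residue indices."""

    id: str
    residues: str
    interface_positions: Optional[frozenset] = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"chain {self.id!r}: empty residue string")
        for pos, ch in enumerate(self.residues):
            if ch not in _ALPHABET:
                raise ValueError(
                    f"chain {self.id!r}: unknown character {ch!r} at position {pos}"
                )
        if self.interface_positions is not None:
            ifc = frozenset(int(p) for p in self.interface_positions)
            if ifc and (min(ifc) < 0 or max(ifc) >= len(self.residues)):
                raise ValueError(
                    f"chain {self.id!r}: interface positions out of range [0, {len(self.residues)})"
                )
            object.__setattr__(self, "interface_positions", ifc)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinPair:
    chain_a: ProteinSequence
    chain_b: ProteinSequence
    is_homomer: bool = False
    source: Source = Source.SYNTHETIC

    def __post_init__(self):
        if self.is_homomer and self.chain_a.residues != self.chain_b.residues:
            raise ValueError("homomer flag set but chain sequences differ")

    @property
    def total_length(self) -> int:
        return len(self.chain_a) + len(self.chain_b)


@dataclass
class TokenizedPair:
    """Concatenated token layout [BOS_a, a..., EOS_a, BOS_b, b..., EOS_b]."""

    tokens: np.ndarray          # int array, length La+Lb+4
    chain_labels: np.ndarray    # array of 'A'/'B' per token
    residue_index_map: np.ndarray  # 0-based residue index within its chain, SPECIAL for BOS/EOS
    inter_mask: np.ndarray      # square {0,1} matrix over token positions

    def __len__(self) -> int:
        return len(self.tokens)

    def residue_token_positions(self, chain: str) -> np.ndarray:
        """Token positions holding actual residues of the given chain."""
        return np.where((self.chain_labels == chain) & (self.residue_index_map != SPECIAL))[0]


@dataclass(frozen=True)
class MaskPlan:
    masked_a: frozenset
    masked_b: frozenset
    strategy: MaskStrategy

    def validate(self, pair: ProteinPair) -> None:
        if self.masked_a and (min(self.masked_a) < 0 or max(self.masked_a) >= len(pair.chain_a)):
            raise ValueError("masked_a positions out of chain bounds")
        if self.masked_b and (min(self.masked_b) < 0 or max(self.masked_b) >= len(pair.chain_b)):
            raise ValueError("masked_b positions out of chain bounds")


@dataclass(frozen=True)
class CropWindow:
    """0-based half-open residue ranges retained from each chain."""

    start_a: int
    end_a: int
    start_b: int
    end_b: int

    @property
    def length(self) -> int:
        return (self.end_a - self.start_a) + (self.end_b - self.start_b)


# ---------------------------------------------------------------------------
# Tokenization


def encode_residues(residues: str) -> np.ndarray:
    return np.array([AA_TO_INDEX.get(ch, X_IDX) for ch in residues], dtype=np.int64)


def build_inter_mask(chain_labels: Sequence[str]) -> np.ndarray:
    """M[i][j] = 1 iff tokens i and j belong to different chains (0 diagonal,
    symmetric).  Special tokens carry their own chain's label."""
    labels = np.asarray(chain_labels)
    bad = set(labels.tolist()) - {"A", "B"}
    if bad:
        raise ValueError(f"chain labels must be 'A' or 'B', got {sorted(bad)}")
    is_b = (labels == "B").astype(np.int8)
    return (is_b[:, None] != is_b[None, :]).astype(np.float32)


def tokenize_pair(pair: ProteinPair) -> TokenizedPair:
    la, lb = len(pair.chain_a), len(pair.chain_b)
    tokens = np.concatenate(
        [
            [BOS_IDX],
            encode_residues(pair.chain_a.residues),
            [EOS_IDX],
            [BOS_IDX],
            encode_residues(pair.chain_b.residues),
            [EOS_IDX],
        ]
    ).astype(np.int64)
    chain_labels = np.array(["A"] * (la + 2) + ["B"] * (lb + 2))
    rim = np.concatenate(
        [[SPECIAL], np.arange(la), [SPECIAL], [SPECIAL], np.arange(lb), [SPECIAL]]
    ).astype(np.int64)
    return TokenizedPair(
        tokens=tokens,
        chain_labels=chain_labels,
        residue_index_map=rim,
        inter_mask=build_inter_mask(chain_labels),
    )


# ---------------------------------------------------------------------------
# Masking plans


def _round_chunks(L: int, fraction: float, perm: np.ndarray) -> list:
    k = math.ceil(fraction * L)
    return [frozenset(perm[i : i + k].tolist()) for i in range(0, L, k)]


def plan_random_rounds(pair: ProteinPair, fraction: float, rng) -> list:
    """Iterative non-overlapping masking: each round masks ceil(fraction*L)
    fresh positions per chain until every position has been masked exactly
    once.  Homomers use one position set for both chains so the model cannot
    read the answer off the identical partner."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = as_rng(rng)
    la, lb = len(pair.chain_a), len(pair.chain_b)
    if pair.is_homomer:
        perm = rng.permutation(la)
        chunks = _round_chunks(la, fraction, perm)
        return [MaskPlan(c, c, MaskStrategy.RANDOM_ROUND) for c in chunks]
    chunks_a = _round_chunks(la, fraction, rng.permutation(la))
    chunks_b = _round_chunks(lb, fraction, rng.permutation(lb))
    n_rounds = max(len(chunks_a), len(chunks_b))
    empty = frozenset()
    plans = []
    for r in range(n_rounds):
        plans.append(
            MaskPlan(
                chunks_a[r] if r < len(chunks_a) else empty,
                chunks_b[r] if r < len(chunks_b) else empty,
                MaskStrategy.RANDOM_ROUND,
            )
        )
    return plans


def plan_interface_masking(pair: ProteinPair, mode: str) -> MaskPlan:
    """Interface perplexity plans.  ``mode``: 'dual' masks every interface
    residue on both chains; 'single_a'/'single_b' mask one chain's interface
    only.  Single modes are forbidden for homomers (the unmasked identical
    chain would make the task trivial)."""
    mode = mode.lower()
    if mode not in ("dual", "single_a", "single_b"):
        raise ValueError(f"unknown interface masking mode {mode!r}")
    if mode != "dual" and pair.is_homomer:
        raise ValueError("Single-chain interface masking is not defined for homomers")
    ifc_a = pair.chain_a.interface_positions
    ifc_b = pair.chain_b.interface_positions
    if mode in ("dual", "single_a") and ifc_a is None:
        raise ValueError("chain A has no interface annotation")
    if mode in ("dual", "single_b") and ifc_b is None:
        raise ValueError("chain B has no interface annotation")
    if mode == "dual":
        return MaskPlan(frozenset(ifc_a), frozenset(ifc_b), MaskStrategy.INTERFACE_DUAL)
    if mode == "single_a":
        return MaskPlan(frozenset(ifc_a), frozenset(), MaskStrategy.INTERFACE_SINGLE_A)
    return MaskPlan(frozenset(), frozenset(ifc_b), MaskStrategy.INTERFACE_SINGLE_B)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _sample_stratum(rng, positions: np.ndarray, fraction: float) -> set:
    n = _round_half_up(fraction * len(positions))
    if n == 0:
        return set()
    return set(rng.choice(positions, size=min(n, len(positions)), replace=False).tolist())


def plan_pretrain_masking(
    pair: ProteinPair, rng, homomer_joint: bool = True,
    interface_fraction: float = 0.30, background_fraction: float = 0.15,
) -> MaskPlan:
    """Source-dependent pretraining masking.

    Structure-derived (PDB) pairs mask 30% of interface residues and 15% of
    non-interface residues, per chain; interaction-database (STRING) pairs
    mask a uniform 15% per chain.  For homomers the chain-A plan is mirrored
    onto chain B when ``homomer_joint`` (default, avoids copy inference).
    """
    rng = as_rng(rng)

    def plan_chain(chain: ProteinSequence, source: Source) -> set:
        L = len(chain)
        if source == Source.PDB:
            if chain.interface_positions is None:
                raise ValueError(
                    f"PDB chain {chain.id!r} lacks interface annotations required "
                    "for interface-weighted masking"
                )
            ifc = np.array(sorted(chain.interface_positions), dtype=np.int64)
            non = np.setdiff1d(np.arange(L), ifc)
            return _sample_stratum(rng, ifc, interface_fraction) | _sample_stratum(
                rng, non, background_fraction
            )
        return _sample_stratum(rng, np.arange(L), background_fraction)

    strategy = (
        MaskStrategy.PRETRAIN_PDB if pair.source == Source.PDB else MaskStrategy.PRETRAIN_STRING
    )
    masked_a = plan_chain(pair.chain_a, pair.source)
    if pair.is_homomer and homomer_joint:
        masked_b = set(masked_a)
    else:
        masked_b = plan_chain(pair.chain_b, pair.source)
    return MaskPlan(frozenset(masked_a), frozenset(masked_b), strategy)


# ---------------------------------------------------------------------------
# Cropping


def _largest_remainder_split(total: int, weights: Sequence[int]) -> list:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=np.float64)
    quotas = total * weights / weights.sum()
    alloc = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - alloc))[: total - alloc.sum()]:
        alloc[i] += 1
    return alloc.tolist()


def _candidate_starts(L: int, w: int, exhaustive: bool, stride: int = 16) -> np.ndarray:
    if w >= L:
        return np.array([0])
    if exhaustive:
        return np.arange(L - w + 1)
    starts = np.arange(0, L - w + 1, stride)
    if starts[-1] != L - w:
        starts = np.append(starts, L - w)
    return starts


def _best_interface_window(chain: ProteinSequence, w: int, exhaustive: bool, rng) -> int:
    ifc = chain.interface_positions or frozenset()
    marks = np.zeros(len(chain))
    for p in ifc:
        marks[p] += 1
    pref = np.concatenate([[0.0], np.cumsum(marks)])
    starts = _candidate_starts(len(chain), w, exhaustive)
    counts = pref[starts + w] - pref[starts]
    best = starts[counts == counts.max()]
    return int(best[rng.integers(len(best))])


def _window_chain(chain: ProteinSequence, start: int, w: int) -> ProteinSequence:
    ifc = None
    if chain.interface_positions is not None:
        ifc = frozenset(p - start for p in chain.interface_positions if start <= p < start + w)
    return ProteinSequence(chain.id, chain.residues[start : start + w], ifc)


def crop_pair(pair: ProteinPair, max_len: int = 1024, rng=None, exhaustive_limit: int = 2048):
    """Crop an over-length pair down to ``max_len`` combined residues.

    Window lengths are allocated proportionally to the chain lengths
    (largest-remainder rounding).  Interaction-database pairs take a
    uniformly random contiguous window per chain; structure-derived pairs
    take the window that retains the most interface residues (exhaustive
    start scan up to ``exhaustive_limit`` total residues, stride-16 beyond;
    ties broken at random).  Returns ``(cropped_pair, CropWindow)``.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    la, lb = len(pair.chain_a), len(pair.chain_b)
    if la + lb <= max_len:
        return pair, CropWindow(0, la, 0, lb)
    rng = as_rng(rng)
    wa, wb = _largest_remainder_split(max_len, [la, lb])
    # cap a window at its chain length, giving surplus to the other chain
    if wa > la:
        wb, wa = min(lb, wb + (wa - la)), la
    if wb > lb:
        wa, wb = min(la, wa + (wb - lb)), lb
    if pair.source == Source.PDB:
        exhaustive = (la + lb) <= exhaustive_limit
        sa = _best_interface_window(pair.chain_a, wa, exhaustive, rng)
        if pair.is_homomer:
            sb = sa
        else:
            sb = _best_interface_window(pair.chain_b, wb, exhaustive, rng)
    else:
        sa = int(rng.integers(la - wa + 1))
        sb = sa if pair.is_homomer else int(rng.integers(lb - wb + 1))
    cropped = ProteinPair(
        _window_chain(pair.chain_a, sa, wa),
        _window_chain(pair.chain_b, sb, wb),
        is_homomer=pair.is_homomer and sa == sb and wa == wb,
        source=pair.source,
    )
    return cropped, CropWindow(sa, sa + wa, sb, sb + wb)


# ---------------------------------------------------------------------------
# Corpus sampling


def sample_training_pair(pdb_clusters, string_clusters, rng) -> ProteinPair:
    """Draw one training pair: source PDB with probability 1/3 and STRING with
    2/3, then a cluster uniformly, then a member uniformly."""
    if not pdb_clusters or not string_clusters:
        raise ValueError("both cluster collections must be non-empty")
    rng = as_rng(rng)
    clusters = pdb_clusters if rng.random() < (1.0 / 3.0) else string_clusters
    cluster = clusters[rng.integers(len(clusters))]
    if not cluster:
        raise ValueError("empty cluster")
    return cluster[rng.integers(len(cluster))]
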
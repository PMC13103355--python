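"""Multiple sequence alignments: A3M I/O, PSSMs, paired MSAs, coupling scores.

Co-evolution between chains is summarized as mutual information between
inter-chain column pairs with the average product correction (APC),
S_apc(i,j) = S(i,j) - S(i,.)S(.,j)/S(.,.), a desk-scale stand-in for direct
coupling analysis that preserves the rank structure the contact network
consumes.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .data import AA_TO_INDEX

# 21st state lumps X / gaps / unknowns
_N_STATES = 21


@dataclass
class Msa:
    """Aligned rows (uppercase match columns only) with per-row species tags."""

    ids: List[str]
    species: List[Optional[str]]
    rows: List[str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("ragged alignment rows")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass
class PairedMsa:
    """Row-matched alignment spanning two chains."""

    rows_a: List[str]
    rows_b: List[str]

    def __post_init__(self):
        if len(self.rows_a) != len(self.rows_b):
            raise ValueError("paired MSA blocks differ in depth")

    @property
    def depth(self) -> int:
        return len(self.rows_a)


def parse_a3m(text: str) -> Msa:
    """Parse A3M: FASTA-like, lowercase letters are insertions and dropped.
    Species tags are read from headers of the form '>id species:TAG'."""
    ids, species, rows = [], [], []
    name, tag, chunks = None, None, []

    def flush():
        if name is not None:
            seq = "".join(chunks)
            rows.append("".join(ch for ch in seq if not ch.islower()).replace(".", "-"))
            ids.append(name)
            species.append(tag)

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            fields = line[1:].split()
            name = fields[0] if fields else ""
            tag = None
            for f in fields[1:]:
                if f.startswith("species:"):
                    tag = f.split(":", 1)[1]
            chunks = []
        else:
            chunks.append(line)
    flush()
    return Msa(ids, species, rows)


def read_a3m(path) -> Msa:
    with open(path) as fh:
        return parse_a3m(fh.read())


def write_a3m(msa: Msa, path=None) -> str:
    buf = _io.StringIO()
    for name, tag, row in zip(msa.ids, msa.species, msa.rows):
        header = f">{name}"
        if tag is not None:
            header += f" species:{tag}"
        buf.write(header + "\n" + row + "\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _encode_column_states(rows: List[str]) -> np.ndarray:
    """(depth, L) integer states; canonical residues 0..19, everything else 20."""
    depth, L = len(rows), len(rows[0])
    out = np.full((depth, L), _N_STATES - 1, dtype=np.int64)
    for d, row in enumerate(rows):
        for j, ch in enumerate(row):
            out[d, j] = AA_TO_INDEX.get(ch, _N_STATES - 1)
    return out


def pssm_from_msa(msa: Msa, pseudocount: float = 1.0) -> np.ndarray:
    """Per-column 20-dim log-odds profile against a uniform background.

    Counts get +``pseudocount`` per residue class; gaps/X are excluded from
    the counts.  Returns (L, 20)."""
    states = _encode_column_states(msa.rows)
    L = msa.length
    counts = np.zeros((L, 20))
    for aa in range(20):
        counts[:, aa] = (states == aa).sum(axis=0)
    counts += pseudocount
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return np.log(freqs / (1.0 / 20.0))


def pair_msa(msa_a: Msa, msa_b: Msa, mode: str) -> PairedMsa:
    """Build a row-matched paired alignment.

    'homo': the monomer alignment is reused for both blocks (depths must
    match row-for-row).  'hetero': rows are matched by species tag, first
    occurrence per species per block; the two query rows (row 0) are always
    paired.  With no shared species the paired MSA is the query pair alone.
    """
    mode = mode.lower()
    if mode == "homo":
        return PairedMsa(list(msa_a.rows), list(msa_a.rows))
    if mode != "hetero":
        raise ValueError(f"unknown pairing mode {mode!r}")
    rows_a = [msa_a.rows[0]]
    rows_b = [msa_b.rows[0]]
    first_a = {}
    for i in range(1, msa_a.depth):
        tag = msa_a.species[i]
        if tag is not None and tag not in first_a:
            first_a[tag] = i
    seen_b = set()
    for j in range(1, msa_b.depth):
        tag = msa_b.species[j]
        if tag in first_a and tag not in seen_b:
            seen_b.add(tag)
            rows_a.append(msa_a.rows[first_a[tag]])
            rows_b.append(msa_b.rows[j])
    return PairedMsa(rows_a, rows_b)


def coupling_scores(paired: PairedMsa) -> np.ndarray:
    """Inter-chain column-pair co-variation: plug-in mutual information with
    the average product correction.  Returns (L1, L2); all-zero (with a
    warning) when the alignment is too shallow (depth < 2)."""
    L1 = len(paired.rows_a[0])
    L2 = len(paired.rows_b[0])
    if paired.depth < 2:
        warnings.warn("paired MSA depth < 2; coupling scores are zero")
        return np.zeros((L1, L2))
    sa = _encode_column_states(paired.rows_a)  # (d, L1)
    sb = _encode_column_states(paired.rows_b)  # (d, L2)
    d = sa.shape[0]
    oa = (sa.T[:, :, None] == np.arange(_N_STATES)).astype(np.float64)  # (L1,d,S)
    ob = (sb.T[:, :, None] == np.arange(_N_STATES)).astype(np.float64)  # (L2,d,S)
    joint = np.einsum("idx,jdy->ijxy", oa, ob) / d          # (L1,L2,S,S)
    pa = oa.sum(axis=1) / d                                  # (L1,S)
    pb = ob.sum(axis=1) / d                                  # (L2,S)
    outer = pa[:, None, :, None] * pb[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * (np.log(joint) - np.log(outer))
    term[~np.isfinite(term)] = 0.0
    mi = term.sum(axis=(2, 3))
    return apc(mi)


def row_max_coupling(scores: np.ndarray) -> np.ndarray:
    """Per-row maximum coupling broadcast across the row — an interpretive
    stand-in for per-row coupling summaries; available as an optional extra
    feature channel, off by default."""
    return np.broadcast_to(scores.max(axis=1, keepdims=True), scores.shape).copy()


def apc(scores: np.ndarray) -> np.ndarray:
    """Average product correction S(i,j) - S(i,.)S(.,j)/S(.,.)."""
    row = scores.mean(axis=1, keepdims=True)
    col = scores.mean(axis=0, keepdims=True)
    total = scores.mean()
    if total == 0:
        return scores.copy()
    return scores - row * col / total
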
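"""Synthetic ground-truth generators.

Every downstream mechanism is exercised on data with *planted, known*
structure: sequence pairs whose chain-B residues are deterministic functions
of designated chain-A residues (the stand-in for physical interface
dependencies), toy two-chain 3-D complexes built from helical backbone
walks with derivable 8 Å contact maps, co-varying toy alignments, and
labeled interaction / binding-affinity tables.  All generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .contact import ground_truth_contacts, interface_truth, min_distance_map
from .data import CANONICAL_AA, ProteinPair, ProteinSequence, Source, as_rng
from .msa import Msa


@dataclass(frozen=True)
class CouplingSpec:
    """Planted inter-chain couplings: at each (pos_a, pos_b) the chain-B
    residue equals the chain-A residue shifted ``shift`` places along the
    canonical alphabet.  Coupled positions are unique per chain."""

    pairs: Tuple[Tuple[int, int], ...]
    shift: int = 1

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs))
        pos_a = [a for a, _ in self.pairs]
        pos_b = [b for _, b in self.pairs]
        if len(set(pos_a)) != len(pos_a) or len(set(pos_b)) != len(pos_b):
            raise ValueError("coupled positions must be unique within each chain")

    def partner_residue(self, residue_a: str) -> str:
        idx = CANONICAL_AA.index(residue_a)
        return CANONICAL_AA[(idx + self.shift) % 20]

    @property
    def positions_a(self):
        return frozenset(a for a, _ in self.pairs)

    @property
    def positions_b(self):
        return frozenset(b for _, b in self.pairs)


def default_coupling_spec(L1: int, L2: int, n_couplings: int, rng) -> CouplingSpec:
    """Sample a coupling layout: unique positions in each chain, paired."""
    rng = as_rng(rng)
    if n_couplings > min(L1, L2):
        raise ValueError("more couplings than available positions")
    pos_a = rng.choice(L1, size=n_couplings, replace=False)
    pos_b = rng.choice(L2, size=n_couplings, replace=False)
    return CouplingSpec(tuple(zip(pos_a.tolist(), pos_b.tolist())))


def _random_chain(L: int, rng) -> str:
    return "".join(CANONICAL_AA[i] for i in rng.integers(0, 20, size=L))


def gen_coupled_pair(L1: int, L2: int, spec: Optional[CouplingSpec], rng,
                     pair_id: str = "syn", coupled: bool = True,
                     source: Source = Source.SYNTHETIC) -> ProteinPair:
    """Chain A i.i.d. uniform over the 20 residues; chain B likewise except
    that (when ``coupled``) each planted position holds the rule-mapped
    partner of its chain-A source, and (when not) explicitly a non-partner
    residue.  Interface annotations mark the coupled positions."""
    rng = as_rng(rng)
    if spec is not None:
        if spec.pairs and (max(spec.positions_a) >= L1 or max(spec.positions_b) >= L2):
            raise ValueError("coupling positions out of chain bounds")
    a = _random_chain(L1, rng)
    b = list(_random_chain(L2, rng))
    ifc_a, ifc_b = set(), set()
    if spec is not None:
        for pa, pb in spec.pairs:
            partner = spec.partner_residue(a[pa])
            if coupled:
                b[pb] = partner
                ifc_a.add(pa)
                ifc_b.add(pb)
            else:
                others = [ch for ch in CANONICAL_AA if ch != partner]
                b[pb] = others[rng.integers(19)]
    return ProteinPair(
        ProteinSequence(f"{pair_id}_A", a, frozenset(ifc_a) if ifc_a else None),
        ProteinSequence(f"{pair_id}_B", "".join(b), frozenset(ifc_b) if ifc_b else None),
        is_homomer=False,
        source=source,
    )


def gen_homomer_pair(L: int, rng, pair_id: str = "homo") -> ProteinPair:
    rng = as_rng(rng)
    seq = _random_chain(L, rng)
    return ProteinPair(
        ProteinSequence(f"{pair_id}_A", seq),
        ProteinSequence(f"{pair_id}_B", seq),
        is_homomer=True,
        source=Source.SYNTHETIC,
    )


def gen_coupled_corpus(n: int, L1: int, L2: int, spec: CouplingSpec, rng,
                       source: Source = Source.SYNTHETIC) -> list:
    """A corpus of pairs sharing one coupling layout (the pretraining corpus
    for the inter-chain information-recovery experiments).  Tagging the
    corpus as PDB selects the interface-weighted pretraining masking, since
    the planted couplings are the pairs' interface annotations."""
    rng = as_rng(rng)
    return [
        gen_coupled_pair(L1, L2, spec, rng, pair_id=f"pair{i}", source=source)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Toy 3-D complexes


@dataclass
class ToyComplex:
    """Two helical chains docked with a controlled interface; truth objects
    are derived from the coordinates under the 8 Å heavy-atom rule."""

    coords_a: List[np.ndarray]
    coords_b: List[np.ndarray]
    contact_map: np.ndarray
    interface_a: set
    interface_b: set
    dist_a: np.ndarray      # intra-chain min heavy-atom distances
    dist_b: np.ndarray
    inter_dist: np.ndarray  # inter-chain min heavy-atom distances


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _kinked_helix(L: int, rng, rise: float = 1.5, radius: float = 2.3,
                  turn_deg: float = 100.0) -> np.ndarray:
    """Helical backbone walk with kinks: segments of 8-14 residues, each a
    helix whose axis is the previous axis rotated by 40-80° about a random
    perpendicular.  Spatial neighbours are therefore fold-dependent, not
    predictable from sequence separation alone."""
    coords = np.zeros((L, 3))
    axis = np.array([0.0, 0.0, 1.0])
    u = np.array([1.0, 0.0, 0.0])  # spans the plane normal to the axis with v
    origin = np.zeros(3)
    ang = rng.uniform(0, 2 * np.pi)
    i = 0
    while i < L:
        seg = min(int(rng.integers(8, 15)), L - i)
        v = np.cross(axis, u)
        for s in range(seg):
            coords[i] = origin + radius * (np.cos(ang) * u + np.sin(ang) * v) \
                + rise * s * axis
            ang += np.deg2rad(turn_deg)
            i += 1
        origin = origin + rise * seg * axis
        perp = np.cross(axis, rng.normal(size=3))
        if np.linalg.norm(perp) < 1e-8:
            perp = u
        rot = _rotation_about(perp, rng.uniform(np.deg2rad(40), np.deg2rad(80)))
        axis = rot @ axis
        u = rot @ u
        u = u - axis * (u @ axis)
        u /= np.linalg.norm(u)
    return coords


def _complex_coords(L1, L2, geom, z_shift):
    ca = geom["backbone_a"]
    cb = geom["backbone_b"]
    # dock chain B along the approach direction at the given offset
    return ca, cb + geom["approach"] * z_shift + geom["offset0"]


def _interface_fraction(ca, cb, cutoff=8.0):
    cmap = (np.sqrt(((ca[:, None] - cb[None, :]) ** 2).sum(-1)) < cutoff)
    return 0.5 * (cmap.any(1).mean() + cmap.any(0).mean())


def gen_toy_complex(L1: int, L2: int, rng, interface_fraction: float = 0.25,
                    jitter_atoms: int = 0, tol: float = 0.05,
                    max_retries: int = 8) -> ToyComplex:
    """Dock two helices so a target fraction of residues lies within 8 Å of
    the partner chain.

    Helix parameters vary per instance (turn 92-108°, rise 1.45-1.55 Å,
    random phases, axis separation 6.5-8 Å, parallel or antiparallel
    orientation) so contact-map geometry differs between complexes and
    spatial adjacency is not predictable from sequence offsets alone.  The
    axial offset of chain B is found by bisection (contact fraction
    decreases monotonically with offset).  Optional ``jitter_atoms`` adds
    pseudo side-chain atoms so the min-over-atoms path is exercised."""
    if min(L1, L2) < 5:
        raise ValueError("chains must have at least 5 residues")
    rng = as_rng(rng)
    for attempt in range(max_retries):
        backbone_a = _kinked_helix(L1, rng, turn_deg=rng.uniform(92, 108))
        backbone_b = _kinked_helix(L2, rng, turn_deg=rng.uniform(92, 108))
        # random rigid orientation for chain B, centered on chain A
        perp = rng.normal(size=3)
        rot = _rotation_about(perp, rng.uniform(0, 2 * np.pi))
        backbone_b = (backbone_b - backbone_b.mean(0)) @ rot.T + backbone_a.mean(0)
        approach = rng.normal(size=3)
        approach /= np.linalg.norm(approach)
        geom = {"backbone_a": backbone_a, "backbone_b": backbone_b,
                "approach": approach, "offset0": np.zeros(3)}
        span = np.ptp(backbone_a, axis=0).max() + np.ptp(backbone_b, axis=0).max()
        if interface_fraction <= 0:
            ca, cb = _complex_coords(L1, L2, geom, span + 20.0)
            break
        # contact fraction decreases monotonically as B withdraws along the
        # approach direction; bisect the offset
        lo, hi = 0.0, span + 10.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            ca, cb = _complex_coords(L1, L2, geom, mid)
            frac = _interface_fraction(ca, cb)
            if frac > interface_fraction:
                lo = mid
            else:
                hi = mid
        ca, cb = _complex_coords(L1, L2, geom, 0.5 * (lo + hi))
        if abs(_interface_fraction(ca, cb) - interface_fraction) <= tol:
            break
    else:
        raise RuntimeError(
            f"docking failed to reach interface fraction {interface_fraction} "
            f"within ±{tol} after {max_retries} retries (rng state consumed)"
        )

    def atoms(centroids):
        out = []
        for c in centroids:
            pts = [c]
            for _ in range(jitter_atoms):
                pts.append(c + rng.normal(0.0, 0.8, size=3))
            out.append(np.stack(pts))
        return out

    coords_a, coords_b = atoms(ca), atoms(cb)
    cmap = ground_truth_contacts(coords_a, coords_b)
    ifc_a, ifc_b = interface_truth(coords_a, coords_b)
    return ToyComplex(
        coords_a=coords_a, coords_b=coords_b, contact_map=cmap,
        interface_a=ifc_a, interface_b=ifc_b,
        dist_a=min_distance_map(coords_a, coords_a),
        dist_b=min_distance_map(coords_b, coords_b),
        inter_dist=min_distance_map(coords_a, coords_b),
    )


def anchor_couplings_from_contacts(contact_map: np.ndarray, fraction: float, rng) -> CouplingSpec:
    """Plant couplings at a subset of true contact pairs ("anchors"),
    greedily keeping coupled positions unique per chain."""
    rng = as_rng(rng)
    pairs = np.argwhere(contact_map > 0)
    rng.shuffle(pairs)
    target = max(1, int(round(fraction * min(contact_map.shape[0], len(pairs)))))
    chosen, seen_a, seen_b = [], set(), set()
    for i, j in pairs:
        if i not in seen_a and j not in seen_b:
            chosen.append((int(i), int(j)))
            seen_a.add(int(i))
            seen_b.add(int(j))
        if len(chosen) >= target:
            break
    return CouplingSpec(tuple(chosen))


# ---------------------------------------------------------------------------
# Toy MSAs


def gen_toy_msa(pair: ProteinPair, depth: int, mutation_rate: float,
                spec: Optional[CouplingSpec], rng) -> Tuple[Msa, Msa]:
    """Mutated copies of a pair with co-mutation at coupled positions.

    Every row mutates each chain-A position independently with probability
    ``mutation_rate``; chain-B positions mutate independently except coupled
    ones, which always hold the rule-mapped partner of the row's chain-A
    source.  The two alignments share per-row species tags."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = as_rng(rng)
    a0, b0 = pair.chain_a.residues, pair.chain_b.residues
    coupled = dict(spec.pairs) if spec is not None else {}
    b_for_a = {pb: pa for pa, pb in coupled.items()}
    rows_a, rows_b = [a0], [list(b0)]
    for _ in range(depth - 1):
        ra = [
            CANONICAL_AA[rng.integers(20)] if rng.random() < mutation_rate else ch
            for ch in a0
        ]
        rb = [
            CANONICAL_AA[rng.integers(20)] if rng.random() < mutation_rate else ch
            for ch in b0
        ]
        rows_a.append("".join(ra))
        rows_b.append(rb)
    if spec is not None:
        for row_a, row_b in zip(rows_a, rows_b):
            for pb, pa in b_for_a.items():
                row_b[pb] = spec.partner_residue(row_a[pa])
    rows_b = ["".join(r) for r in rows_b]
    species = [f"s{i}" for i in range(depth)]
    ids_a = [f"{pair.chain_a.id}_{i}" for i in range(depth)]
    ids_b = [f"{pair.chain_b.id}_{i}" for i in range(depth)]
    return Msa(ids_a, list(species), rows_a), Msa(ids_b, list(species), rows_b)


# ---------------------------------------------------------------------------
# Labeled tables


def gen_ppi_table(n_pos: int, neg_ratio: int = 10, spec: CouplingSpec = None,
                  rng=0, L1: int = 16, L2: int = 16):
    """Labeled interaction table: positives carry the planted couplings,
    negatives are explicit non-partners at the same positions; exact
    ``neg_ratio`` : 1 class ratio.  Returns (pairs, labels)."""
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    rng = as_rng(rng)
    if spec is None:
        spec = default_coupling_spec(L1, L2, max(2, min(L1, L2) // 2), rng)
    pairs, labels = [], []
    for i in range(n_pos):
        pairs.append(gen_coupled_pair(L1, L2, spec, rng, pair_id=f"pos{i}", coupled=True))
        labels.append(1)
    for i in range(n_pos * neg_ratio):
        pairs.append(gen_coupled_pair(L1, L2, spec, rng, pair_id=f"neg{i}", coupled=False))
        labels.append(0)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order], np.array([labels[i] for i in order])


def gen_affinity_table(n: int, spec: CouplingSpec, rng=0, slope: float = 1.0,
                       noise_sd: float = 0.5, L1: int = 16, L2: int = 16,
                       group_size: int = 4, split_receptor_prob: float = 0.2):
    """Binding-affinity mutation panel: ΔG = -slope * k + ε with k the
    number of intact planted couplings and ε ~ N(0, noise_sd).

    The panel emulates an affinity series against one receptor (the common
    layout of experimental affinity datasets: many ligand variants measured
    against a shared target): chain A is fixed for the whole table, and
    each group of samples shares a base ligand whose coupling-site states
    (intact partner residue vs explicit non-partner) are resampled per
    sample.  Groups exercise grouped folding; some receptors are split into
    two chains to exercise chain concatenation."""
    from .affinity import AffinitySample  # local import to avoid a cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    n_sites = len(spec.pairs)
    receptor_seq = _random_chain(L1, rng)
    samples = []
    group_id = -1
    base_b = None
    for i in range(n):
        if i % group_size == 0:
            group_id += 1
            base_b = _random_chain(L2, rng)
        k = int(rng.integers(0, n_sites + 1))
        active = set(rng.choice(n_sites, size=k, replace=False).tolist())
        b = list(base_b)
        for s, (pa, pb) in enumerate(spec.pairs):
            partner = spec.partner_residue(receptor_seq[pa])
            if s in active:
                b[pb] = partner
            else:
                others = [ch for ch in CANONICAL_AA if ch != partner]
                b[pb] = others[rng.integers(19)]
        dg = -slope * k + rng.normal(0.0, noise_sd)
        if rng.random() < split_receptor_prob and L1 >= 4:
            cut = int(rng.integers(2, L1 - 1))
            receptor = [
                ProteinSequence(f"aff{i}_A1", receptor_seq[:cut]),
                ProteinSequence(f"aff{i}_A2", receptor_seq[cut:]),
            ]
        else:
            receptor = [ProteinSequence(f"aff{i}_A", receptor_seq)]
        samples.append(
            AffinitySample(
                sample_id=f"aff{i}",
                receptor_chains=receptor,
                ligand_chains=[ProteinSequence(f"aff{i}_B", "".join(b))],
                affinity=float(dg),
                group_id=f"g{group_id}",
                n_couplings=k,
            )
        )
    return samples
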
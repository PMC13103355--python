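"""File formats: FASTA chains, pair-list TSV, interface annotations,
PDB ATOM records, contact/distance map TSV, mask-plan audit TSV."""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import MaskPlan, ProteinPair, ProteinSequence, Source


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path):
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Interface annotations: one 1-based residue index per line


def read_interface_file(path) -> frozenset:
    with open(path) as fh:
        indices = [int(line) for line in fh if line.strip()]
    if any(i < 1 for i in indices):
        raise ValueError(f"{path}: interface indices are 1-based; got {min(indices)}")
    return frozenset(i - 1 for i in indices)


def write_interface_file(positions, path):
    with open(path, "w") as fh:
        for p in sorted(positions):
            fh.write(f"{p + 1}\n")


# ---------------------------------------------------------------------------
# Pair-list TSV: pair_id, fasta_id_a, fasta_id_b, source, is_homomer,
# optional interface_a / interface_b file paths (relative to the TSV)


PAIR_COLUMNS = ["pair_id", "fasta_id_a", "fasta_id_b", "source", "is_homomer",
                "interface_a", "interface_b"]


def read_pair_list(tsv_path, fasta: Dict[str, str]) -> List[ProteinPair]:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"pair_id", "fasta_id_a", "fasta_id_b", "source", "is_homomer"} - set(df.columns)
    if missing:
        raise ValueError(f"pair list missing columns: {sorted(missing)}")
    base = os.path.dirname(os.fspath(tsv_path))
    pairs = []
    for row in df.itertuples(index=False):
        def chain(fasta_id, ifc_col):
            if fasta_id not in fasta:
                raise KeyError(f"pair {row.pair_id}: fasta id {fasta_id!r} not found")
            ifc = None
            rel = getattr(row, ifc_col, "")
            if rel:
                ifc = read_interface_file(os.path.join(base, rel))
            return ProteinSequence(fasta_id, fasta[fasta_id], ifc)

        pairs.append(
            ProteinPair(
                chain(row.fasta_id_a, "interface_a"),
                chain(row.fasta_id_b, "interface_b"),
                is_homomer=str(row.is_homomer).lower() in ("1", "true", "yes"),
                source=Source(row.source),
            )
        )
    return pairs


def write_pair_list(rows: Sequence[dict], path):
    pd.DataFrame(rows, columns=PAIR_COLUMNS).fillna("").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mask-plan audit TSV: pair_id, round, chain, position


def write_mask_plans(plans_by_pair: Dict[str, Sequence[MaskPlan]], path):
    rows = []
    for pair_id, plans in plans_by_pair.items():
        for rnd, plan in enumerate(plans):
            for p in sorted(plan.masked_a):
                rows.append((pair_id, rnd, "A", p))
            for p in sorted(plan.masked_b):
                rows.append((pair_id, rnd, "B", p))
    pd.DataFrame(rows, columns=["pair_id", "round", "chain", "position"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PDB ATOM records


def read_pdb_chains(path) -> Dict[str, List[np.ndarray]]:
    """Heavy-atom coordinates per chain: chain id -> list of per-residue
    (n_atoms, 3) arrays, in residue order.  Hydrogens and heteroatoms are
    skipped."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {}
    for chain in model:
        residues = []
        for res in chain:
            if res.id[0] != " ":
                continue
            coords = [atom.coord for atom in res if atom.element != "H"]
            residues.append(np.array(coords, dtype=float).reshape(-1, 3))
        if residues:
            chains[chain.id] = residues
    return chains


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_pdb(chains: Dict[str, Sequence[np.ndarray]], path,
              sequences: Optional[Dict[str, str]] = None):
    """Write per-residue heavy-atom coordinates as standard ATOM records.
    The first atom of each residue is named CA; extra atoms CB, CG, ...
    Residue names come from ``sequences`` when given (one-letter mapped to
    UNK-safe three-letter codes), else ALA."""
    from Bio.Data.IUPACData import protein_letters_1to3

    names = ["CA", "CB", "CG", "CD", "CE", "CZ"]
    with open(path, "w") as fh:
        serial = 1
        for chain_id, residues in chains.items():
            seq = (sequences or {}).get(chain_id)
            for ri, atoms in enumerate(residues):
                resname = "ALA"
                if seq is not None and ri < len(seq):
                    resname = protein_letters_1to3.get(seq[ri].upper(), "Unk").upper()
                for ai, xyz in enumerate(np.atleast_2d(atoms)):
                    fh.write(_PDB_ATOM.format(
                        serial=serial, name=names[min(ai, len(names) - 1)], altloc=" ",
                        resname=resname, chain=chain_id, resseq=ri + 1, icode=" ",
                        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0, element="C",
                    ))
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Contact / distance maps as (i, j, value) TSV, 0-based, optionally gzipped


def write_map_tsv(matrix: np.ndarray, path, keep_zeros: bool = False):
    mat = np.asarray(matrix)
    if keep_zeros:
        ii, jj = np.meshgrid(np.arange(mat.shape[0]), np.arange(mat.shape[1]), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
    else:
        ii, jj = np.nonzero(mat)
    pd.DataFrame({"i": ii, "j": jj, "value": mat[ii, jj]}).to_csv(
        path, sep="\t", index=False
    )


def read_map_tsv(path, shape) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    out = np.zeros(shape)
    out[df["i"].to_numpy(), df["j"].to_numpy()] = df["value"].to_numpy()
    return out
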
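"""Protein physicochemical properties computed from first principles.

Implements the ProtParam-style quantities reported for gene-family surveys:
average-isotopic molecular weight and atom counts, Kyte-Doolittle GRAVY,
Ikai aliphatic index, Guruprasad instability index with the stable/unstable
call at II < 40, and Henderson-Hasselbalch net charge / isoelectric point.

The pKa table defaults to Bjellqvist's (the ProtParam convention); an EMBOSS
alternative is selectable. Masses are average, not monoisotopic.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import DIWV  # published dipeptide table

from .seqio import AMINO_ACIDS, SequenceRecord

WATER_MASS = 18.0153

#: Average residue (chain) masses, g/mol.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: Atoms per chain residue (C,H,N,O,S summed); free water adds 3 atoms.
RESIDUE_ATOMS = {
    "G": 7, "A": 10, "S": 11, "P": 14, "V": 16, "T": 14, "C": 11, "L": 19,
    "I": 19, "N": 14, "D": 13, "Q": 17, "K": 21, "E": 16, "M": 17, "H": 17,
    "F": 20, "R": 23, "Y": 21, "W": 24,
}
WATER_ATOMS = 3

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Side-chain and termini pKa sets. Sign: + groups protonate, - deprotonate.
PKA_TABLES = {
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
}
_NEGATIVE = "DECY"
_POSITIVE = "HKR"


class ResidueError(ValueError):
    """Raised for a non-standard residue, naming its position."""


@dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    length: int
    mol_weight: float          # kDa, average isotopic
    avg_residue_weight: float  # g/mol (chain residue, water excluded)
    atom_count: int
    pI: float
    net_charge: float          # at the report pH
    gravy: float
    aliphatic_index: float
    instability_index: float
    stability_call: str        # "stable" iff II < 40


def _validated(protein: SequenceRecord) -> str:
    seq = protein.residues.upper()
    for i, aa in enumerate(seq, 1):
        if aa not in AMINO_ACIDS:
            raise ResidueError(
                f"{protein.id}: non-standard residue {aa!r} at position {i}")
    return seq


def molecular_weight(protein: SequenceRecord
                     ) -> tuple[float, int, float]:
    """(MW in kDa, atom count, average chain-residue weight in g/mol).

    MW sums average residue masses plus one water; the atom count adds the
    per-residue atomic compositions plus the terminal water's 3 atoms
    (equivalently: free amino-acid atoms minus (L-1) condensation waters).
    """
    seq = _validated(protein)
    mass = sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    atoms = sum(RESIDUE_ATOMS[aa] for aa in seq) + WATER_ATOMS
    avg = (mass - WATER_MASS) / len(seq)
    return mass / 1000.0, atoms, avg


def gravy(protein: SequenceRecord) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = _validated(protein)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def aliphatic_index(protein: SequenceRecord) -> float:
    """Ikai's aliphatic index from mole percents of A, V, I and L."""
    seq = _validated(protein)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(protein: SequenceRecord) -> tuple[float, str]:
    """Guruprasad II = (10/L) * sum of DIWV over consecutive dipeptides.

    Returns (II, call) with call "stable" iff II < 40. A single-residue
    sequence has no dipeptide and is an error.
    """
    seq = _validated(protein)
    if len(seq) < 2:
        raise ResidueError(
            f"{protein.id}: instability index needs >= 2 residues")
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    ii = 10.0 * total / len(seq)
    return ii, ("stable" if ii < 40 else "unstable")


def net_charge(protein: SequenceRecord, pH: float = 7.0,
               pka: str | dict = "bjellqvist") -> float:
    """Henderson-Hasselbalch net charge at ``pH`` (termini included)."""
    seq = _validated(protein)
    table = PKA_TABLES[pka] if isinstance(pka, str) else pka
    charge = 1.0 / (1.0 + 10 ** (pH - table["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (table["Cterm"] - pH))
    for aa in seq:
        if aa in _POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (pH - table[aa]))
        elif aa in _NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (table[aa] - pH))
    return charge


def isoelectric_point(protein: SequenceRecord,
                      pka: str | dict = "bjellqvist",
                      tol: float = 1e-4) -> float:
    """pI as the bisection root of charge(pH) on [0, 14], |charge| < tol.

    charge(pH) is strictly decreasing, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(protein, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charge_and_pI(protein: SequenceRecord, pH: float = 7.0,
                  pka: str | dict = "bjellqvist") -> tuple[float, float]:
    return net_charge(protein, pH, pka), isoelectric_point(protein, pka)


def protein_properties(protein: SequenceRecord, pH: float = 7.0,
                       pka: str | dict = "bjellqvist") -> ProteinProperties:
    """All report columns for one protein."""
    mw_kda, atoms, avg = molecular_weight(protein)
    q, pi = charge_and_pI(protein, pH, pka)
    ii, call = instability_index(protein)
    return ProteinProperties(
        protein_id=protein.id, length=len(protein), mol_weight=mw_kda,
        avg_residue_weight=avg, atom_count=atoms, pI=pi, net_charge=q,
        gravy=gravy(protein), aliphatic_index=aliphatic_index(protein),
        instability_index=ii, stability_call=call)


def properties_table(proteins: list[SequenceRecord], pH: float = 7.0,
                     pka: str | dict = "bjellqvist"):
    """Properties for a proteome as a DataFrame mirroring survey tables."""
    import pandas as pd

    rows = []
    for p in proteins:
        pr = protein_properties(p, pH, pka)
        rows.append({
            "protein_id": pr.protein_id,
            "length_aa": pr.length,
            "mol_wt_kda": round(pr.mol_weight, 2),
            "pI": round(pr.pI, 2),
            "gravy": round(pr.gravy, 3),
            "aliphatic_index": round(pr.aliphatic_index, 2),
            "instability_index": round(pr.instability_index, 2),
            "stability": pr.stability_call,
            "total_atoms": pr.atom_count,
            "avg_residue_wt": round(pr.avg_residue_weight, 1),
            "net_charge": round(pr.net_charge, 1),
        })
    return pd.DataFrame(rows)
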
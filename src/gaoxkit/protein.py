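"""Physicochemical protein properties: molecular weight, isoelectric point,
and acid/base classification.

Both quantities follow the ExPASy Compute pI/Mw conventions so that values
are comparable with the web tool commonly used in gene-family surveys:
average (not monoisotopic) residue masses, and the Bjellqvist pKa set with
residue-specific N-terminal pKa values, cysteines treated as free.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ProteinProperties",
    "molecular_weight",
    "isoelectric_point",
    "classify_acid_base",
    "properties_table",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
]

# Average residue masses (Da), ExPASy convention (residue = amino acid - water).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Bjellqvist pKa values as used by the ExPASy tool.
_PKA_CTERM = 3.55
_PKA_CTERM_SIDE = {"D": 4.55, "E": 4.75}
_PKA_NTERM_DEFAULT = 7.50
_PKA_NTERM = {"A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.70}
_PKA_POSITIVE = {"K": 10.00, "R": 12.00, "H": 5.98}
_PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}


def _check_sequence(protein: str) -> str:
    protein = protein.upper()
    for i, aa in enumerate(protein):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise ValueError(f"non-standard amino acid {aa!r} at position {i + 1}")
    if not protein:
        raise ValueError("empty protein sequence")
    return protein


def molecular_weight(protein: str) -> float:
    """Average molecular mass in daltons: sum of residue masses plus one water."""
    protein = _check_sequence(protein)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in protein) + WATER_MASS


def net_charge(protein: str, ph: float) -> float:
    """Net charge at ``ph`` by Henderson-Hasselbalch over the ionisable groups:
    both termini plus D, E, C, Y (acidic) and H, K, R (basic) side chains."""
    protein = _check_sequence(protein)
    pos = [_PKA_NTERM.get(protein[0], _PKA_NTERM_DEFAULT)]
    pos += [_PKA_POSITIVE[aa] for aa in protein if aa in _PKA_POSITIVE]
    neg = [_PKA_CTERM_SIDE.get(protein[-1], _PKA_CTERM)]
    neg += [_PKA_NEGATIVE[aa] for aa in protein if aa in _PKA_NEGATIVE]
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg)
    return charge


def isoelectric_point(protein: str, tol: float = 0.001) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def classify_acid_base(pi: float) -> str:
    """'basic' iff pI > 7.0 (a pI of exactly 7.0 is classified acidic)."""
    if not 0 < pi < 14:
        raise ValueError(f"pI out of range: {pi}")
    return "basic" if pi > 7.0 else "acidic"


@dataclass(frozen=True)
class ProteinProperties:
    gene_id: str
    length_aa: int
    mw_kda: float
    pi: float
    acid_base_class: str


def compute_properties(gene_id: str, protein: str) -> ProteinProperties:
    pi = isoelectric_point(protein)
    return ProteinProperties(
        gene_id=gene_id,
        length_aa=len(protein),
        mw_kda=round(molecular_weight(protein) / 1000.0, 3),
        pi=round(pi, 2),
        acid_base_class=classify_acid_base(pi),
    )


def properties_table(proteins: list[tuple[str, str]]) -> pd.DataFrame:
    """Property table for ``[(gene_id, protein_sequence), ...]``.

    Columns: gene_id, length_aa, mw_kda (3 decimals), pi (2 decimals), class.
    """
    rows = [compute_properties(g, p) for g, p in proteins]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "length_aa": [r.length_aa for r in rows],
            "mw_kda": [r.mw_kda for r in rows],
            "pi": [r.pi for r in rows],
            "class": [r.acid_base_class for r in rows],
        }
    )
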
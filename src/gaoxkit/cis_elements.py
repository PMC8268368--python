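"""Promoter cis-regulatory element scanning.

Promoters are scanned on both strands for IUPAC consensus motifs
(hormone- and stress-responsive elements such as ABRE, G-Box, GARE-motif,
P-box, LTR). Every occurrence is reported — overlapping matches included —
and counts are rolled up per gene and per functional category (ABA, GA, SA,
auxin, MeJA, light, low-temperature, defense-and-stress).

Conventions: positions are 1-based on the promoter's coding-strand
orientation; an ``N`` in the promoter never matches anything; a palindromic
consensus planted once yields one hit per strand at the same locus (both are
counted by default; ``dedupe_palindromes`` collapses them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .seqio import reverse_complement

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "IUPAC",
    "load_motif_library",
    "default_motif_library",
    "save_motif_library",
    "scan_sequence",
    "scan_promoter",
    "count_matrix",
    "category_rollup",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

CATEGORIES = (
    "ABA", "GA", "SA", "auxin", "MeJA", "light", "low-temperature", "defense-and-stress",
)


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str
    category: str

    def __post_init__(self):
        if not self.consensus:
            raise ValueError(f"motif {self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: non-IUPAC letters {sorted(bad)}")
        object.__setattr__(self, "consensus", self.consensus.upper())

    def is_palindromic(self) -> bool:
        return self.consensus == reverse_complement(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_name: str
    position: int  # 1-based on the promoter's coding-strand orientation
    strand: str


def _parse_library(obj: dict) -> list[MotifDefinition]:
    motifs = [MotifDefinition(m["name"], m["consensus"], m["category"]) for m in obj["motifs"]]
    names = [m.name for m in motifs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate motif names: {sorted(dupes)}")
    return motifs


def load_motif_library(path: str | Path) -> list[MotifDefinition]:
    """Load a JSON motif library ({"motifs": [{name, consensus, category}]})."""
    with open(path) as fh:
        return _parse_library(json.load(fh))


def default_motif_library() -> list[MotifDefinition]:
    """The bundled library: published consensus strings covering all eight
    hormone/stress categories; replaceable via ``load_motif_library``."""
    text = resources.files("gaoxkit.data").joinpath("motifs.json").read_text()
    return _parse_library(json.loads(text))


def save_motif_library(motifs: Iterable[MotifDefinition], path: str | Path) -> None:
    obj = {
        "motifs": [
            {"name": m.name, "consensus": m.consensus, "category": m.category}
            for m in motifs
        ]
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def _matches_at(seq: str, pattern: str, start: int) -> bool:
    for p_char, s_char in zip(pattern, seq[start : start + len(pattern)]):
        if s_char not in IUPAC[p_char]:  # promoter N never matches: N not in any set but IUPAC['N'] contains ACGT only
            return False
    return True


def scan_sequence(seq: str, motif: MotifDefinition, gene_id: str = "") -> list[MotifHit]:
    """All occurrences of one motif in ``seq``, both strands, overlaps
    included. Positions are 1-based offsets of the match start on the given
    (coding-strand) orientation, for both strands."""
    seq = seq.upper()
    k = len(motif.consensus)
    fwd = motif.consensus
    rev = reverse_complement(motif.consensus)
    hits: list[MotifHit] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        if _matches_at(seq, fwd, i):
            hits.append(MotifHit(gene_id, motif.name, i + 1, "+"))
        if _matches_at(seq, rev, i):
            hits.append(MotifHit(gene_id, motif.name, i + 1, "-"))
    return hits


def scan_promoter(
    promoter: str,
    library: list[MotifDefinition],
    gene_id: str = "",
    dedupe_palindromes: bool = False,
) -> list[MotifHit]:
    """Scan one promoter against a motif library.

    With ``dedupe_palindromes`` the +/- hit pair a palindromic consensus
    produces at a single locus is collapsed to the + hit.
    """
    hits: list[MotifHit] = []
    for motif in library:
        mh = scan_sequence(promoter, motif, gene_id)
        if dedupe_palindromes and motif.is_palindromic():
            mh = [h for h in mh if h.strand == "+"]
        hits.extend(mh)
    return hits


def count_matrix(
    hits: list[MotifHit],
    genes: list[str],
    library: list[MotifDefinition],
) -> pd.DataFrame:
    """Gene x motif occurrence counts, zero-filled over ``genes`` and the
    library's motifs. A hit naming an unknown gene is an error."""
    known = set(genes)
    for h in hits:
        if h.gene_id not in known:
            raise ValueError(f"hit references unknown gene {h.gene_id!r}")
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                       columns=[m.name for m in library], dtype=int)
    for h in hits:
        mat.loc[h.gene_id, h.motif_name] += 1
    return mat


def category_rollup(matrix: pd.DataFrame, library: list[MotifDefinition]) -> pd.DataFrame:
    """Gene x category counts: column sums of the motif matrix within each
    category."""
    by_cat: dict[str, list[str]] = {}
    for m in library:
        by_cat.setdefault(m.category, []).append(m.name)
    out = pd.DataFrame(index=matrix.index)
    for cat, names in by_cat.items():
        out[cat] = matrix[names].sum(axis=1)
    return out
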
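"""Sequence and annotation I/O: FASTA reading, CDS extraction, translation,
and promoter-window extraction.

Coordinate convention: 1-based, inclusive on both ends (GFF3 style) at every
public interface. The stop codon is *not* considered part of a coding
sequence; a trailing stop found during extraction is stripped with a warning.
Codons containing ``N`` translate to ``X`` and are excluded from downstream
codon statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "CodingSequence",
    "PromoterSequence",
    "SeqioError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "extract_cds",
    "translate_cds",
    "extract_promoter",
    "STANDARD_TABLE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_TO_AA",
]

# Standard genetic code (NCBI table 1), shared by every module downstream.
STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(STANDARD_TABLE.stop_codons)
CODON_TO_AA = dict(STANDARD_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # 61 codons

_VALID_NT = frozenset("ACGTN")


class SeqioError(ValueError):
    """Raised on malformed sequence or annotation input.

    ``code`` distinguishes machine-checkable failure modes:
    ``duplicate-id``, ``empty-file``, ``out-of-bounds``, ``bad-frame``,
    ``internal-stop``, ``bad-letter``.
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class GeneRecord:
    """A gene model: chromosome location plus ordered CDS segments.

    ``cds_segments`` are (start, end) pairs, 1-based inclusive, given in
    genomic (plus-strand) order; for minus-strand genes they are re-ordered
    into transcription order during extraction.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds_segments: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise SeqioError("bad-strand", f"strand must be + or -, got {self.strand!r}")
        segs = tuple(tuple(s) for s in self.cds_segments) or ((self.start, self.end),)
        for s, e in segs:
            if s > e:
                raise SeqioError("bad-segment", f"{self.gene_id}: segment start {s} > end {e}")
        ordered = sorted(segs)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise SeqioError("bad-segment", f"{self.gene_id}: overlapping CDS segments")
        object.__setattr__(self, "cds_segments", ordered if self.strand == "+" else ordered)


@dataclass(frozen=True)
class CodingSequence:
    gene_id: str
    nucleotides: str

    def __post_init__(self):
        bad = set(self.nucleotides) - _VALID_NT
        if bad:
            raise SeqioError("bad-letter", f"{self.gene_id}: invalid nucleotides {sorted(bad)}")
        if len(self.nucleotides) % 3:
            raise SeqioError(
                "bad-frame",
                f"{self.gene_id}: CDS length {len(self.nucleotides)} not divisible by 3",
            )

    @property
    def length_nt(self) -> int:
        return len(self.nucleotides)

    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class PromoterSequence:
    gene_id: str
    sequence: str
    clipped: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``. Duplicate
    record ids and empty files are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqioError("duplicate-id", f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not records:
        raise SeqioError("empty-file", f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(genome: dict[str, str], gene: GeneRecord) -> CodingSequence:
    """Splice a gene's CDS out of ``genome`` (contig name -> sequence).

    Minus-strand genes are reverse-complemented; segments are concatenated in
    transcription order. A trailing stop codon is stripped with a warning
    (the coding sequence proper excludes the stop); an internal in-frame stop
    is an error.
    """
    if gene.chromosome not in genome:
        raise SeqioError("out-of-bounds", f"{gene.gene_id}: contig {gene.chromosome!r} absent")
    contig = genome[gene.chromosome]
    parts = []
    for s, e in gene.cds_segments:
        if s < 1 or e > len(contig):
            raise SeqioError(
                "out-of-bounds",
                f"{gene.gene_id}: segment {s}-{e} outside contig of length {len(contig)}",
            )
        parts.append(contig[s - 1 : e].upper())
    seq = "".join(parts)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    if len(seq) % 3:
        raise SeqioError("bad-frame", f"{gene.gene_id}: spliced CDS length {len(seq)} not /3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        warnings.warn(f"{gene.gene_id}: trailing stop codon stripped from CDS", stacklevel=2)
        codons = codons[:-1]
        seq = "".join(codons)
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise SeqioError("internal-stop", f"{gene.gene_id}: stop codon {c} at codon {i + 1}")
    return CodingSequence(gene.gene_id, seq)


def translate_cds(cds: CodingSequence | str) -> str:
    """Translate an in-frame coding sequence with the standard code.

    One letter per codon; a terminal stop (if present) is dropped; codons
    containing ``N`` become ``X``; an internal stop is an error.
    """
    seq = cds.nucleotides if isinstance(cds, CodingSequence) else cds.upper()
    if len(seq) % 3:
        raise SeqioError("bad-frame", f"length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    out = []
    for i, c in enumerate(codons):
        if "N" in c:
            out.append("X")
        elif c in STOP_CODONS:
            raise SeqioError("internal-stop", f"stop codon {c} at codon {i + 1}")
        else:
            out.append(CODON_TO_AA[c])
    return "".join(out)


def extract_promoter(genome: dict[str, str], gene: GeneRecord, window: int = 3000) -> PromoterSequence:
    """Return the ``window`` bases immediately 5' of the translation start,
    on the coding strand.

    At a contig edge the window is clipped and ``clipped`` is set; clipping is
    never fatal.
    """
    if gene.chromosome not in genome:
        raise SeqioError("out-of-bounds", f"{gene.gene_id}: contig {gene.chromosome!r} absent")
    contig = genome[gene.chromosome]
    if gene.strand == "+":
        tss = gene.cds_segments[0][0]  # first coding base, 1-based
        lo = max(1, tss - window)
        seq = contig[lo - 1 : tss - 1].upper()
        clipped = tss - window < 1
    else:
        tss = gene.cds_segments[-1][1]  # first coding base on - strand
        hi = min(len(contig), tss + window)
        seq = reverse_complement(contig[tss : hi].upper())
        clipped = tss + window > len(contig)
    return PromoterSequence(gene.gene_id, seq, clipped=clipped)
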
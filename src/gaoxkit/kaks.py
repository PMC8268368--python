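"""Pairwise Ka/Ks estimation by the Nei-Gojobori (1986) method with
Jukes-Cantor correction.

The estimator counts, per codon, how many of the three possible
single-nucleotide changes at each position are synonymous (fractional
synonymous sites), and classifies observed between-codon differences by
averaging over all mutational pathways with equal weight. Changes that
create a stop codon are excluded from both site denominators and pathway
sets. Proportions of synonymous (ps) and nonsynonymous (pn) differences are
corrected for multiple hits with JC69, d = -(3/4)ln(1 - 4p/3), giving Ks and
Ka; Ka/Ks < 1 indicates purifying selection.

Codon alignments are obtained by globally aligning the translated proteins
(BLOSUM62, affine gaps) and threading the alignment back onto codons;
columns containing a gap in either sequence are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import CODON_TO_AA, STOP_CODONS, CodingSequence, translate_cds

__all__ = [
    "CodonAlignment",
    "SubstitutionEstimate",
    "align_codons",
    "ng86_sites",
    "ng86_differences",
    "jukes_cantor",
    "kaks",
    "kaks_pair",
    "purifying_selection_report",
]

_BASES = "ACGT"
JC_SATURATION = 0.75


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codons from two coding sequences."""

    gene_a: str
    gene_b: str
    codon_pairs: tuple[tuple[str, str], ...]
    n_dropped_columns: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codon_pairs)


@dataclass(frozen=True)
class SubstitutionEstimate:
    """NG86 counts and JC-corrected distances for one aligned pair.

    ``ks``/``ka`` are NaN beyond JC saturation (p >= 3/4, ``saturated``
    set); ``ratio`` is NaN when Ks is 0 or unavailable.
    """

    gene_a: str
    gene_b: str
    n_codons: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float
    saturated: bool = False


def _default_aligner(gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_codons(
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> CodonAlignment:
    """Protein-guided codon alignment of two coding sequences.

    The translated proteins are globally aligned and the alignment is
    threaded back onto codons; columns with a gap in either sequence are
    dropped. Fixed default scoring (BLOSUM62, open -10, extend -0.5) keeps
    results reproducible bit-for-bit.
    """
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aln = _default_aligner(gap_open, gap_extend).align(prot_a, prot_b)[0]
    codons_a, codons_b = cds_a.codons(), cds_b.codons()
    pairs: list[tuple[str, str]] = []
    n_matched = 0
    dropped = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            n_matched += 1
            ca, cb = codons_a[i], codons_b[j]
            if "N" in ca or "N" in cb:
                dropped += 1
            else:
                pairs.append((ca, cb))
    dropped += aln.length - n_matched  # gap columns
    if not pairs:
        raise ValueError(f"{cds_a.gene_id}/{cds_b.gene_id}: empty overlap after gap removal")
    return CodonAlignment(cds_a.gene_id, cds_b.gene_id, tuple(pairs), dropped)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one sense codon.

    At each position the synonymous fraction is the number of the three
    single-nucleotide changes that preserve the amino acid, over the number
    that do not create a stop codon; s sums the three fractions and
    n = 3 - s.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        legal = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            legal += 1
            if CODON_TO_AA[mut] == aa:
                syn += 1
        if legal:
            s += syn / legal
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two
    sense codons over all equal-weight mutational pathways.

    Pathways passing through a stop codon are excluded; when every pathway
    is excluded (cannot happen for sense codons under the standard code at
    m <= 3, but guarded anyway) stop-passing pathways are readmitted so a
    count is always produced. sd + nd equals the number of differing
    positions.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} in difference counting")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    m = len(diff_pos)
    if m == 0:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for r in (walk(p) for p in permutations(diff_pos)) if r is not None]
    if not results:  # pragma: no cover - unreachable for sense codons
        def walk_any(order):
            cur, sd, nd = codon_a, 0.0, 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if cur not in STOP_CODONS and nxt not in STOP_CODONS:
                    if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                        sd += 1.0
                    else:
                        nd += 1.0
                cur = nxt
            return sd, nd
        results = [walk_any(p) for p in permutations(diff_pos)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4)ln(1 - 4p/3).

    NaN (saturation) for p >= 3/4.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= JC_SATURATION:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks(alignment: CodonAlignment) -> SubstitutionEstimate:
    """NG86 + JC69 estimate for one codon alignment.

    S and N are per-sequence site sums averaged over the two sequences;
    ps = Sd/S, pn = Nd/N; Ks = JC(ps), Ka = JC(pn); ratio = Ka/Ks (NaN when
    Ks is 0 or either distance is saturated).
    """
    if alignment.n_codons == 0:
        raise ValueError("empty alignment")
    s_a = s_b = sd = nd = 0.0
    for ca, cb in alignment.codon_pairs:
        s_a += ng86_sites(ca)[0]
        s_b += ng86_sites(cb)[0]
        d_s, d_n = ng86_differences(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * alignment.n_codons - s_sites
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks, ka = jukes_cantor(ps), jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    ratio = ka / ks if (not saturated and ks > 0) else float("nan")
    return SubstitutionEstimate(
        gene_a=alignment.gene_a,
        gene_b=alignment.gene_b,
        n_codons=alignment.n_codons,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        ratio=ratio,
        saturated=saturated,
    )


def kaks_pair(cds_a: CodingSequence, cds_b: CodingSequence) -> SubstitutionEstimate:
    """Convenience: align then estimate."""
    return kaks(align_codons(cds_a, cds_b))


def purifying_selection_report(estimates: list[SubstitutionEstimate]) -> pd.DataFrame:
    """Table-shaped report (one row per pair) with a ``purifying`` flag
    (Ka/Ks < 1). Empty input yields a header-only frame."""
    cols = [
        "gene_a", "gene_b", "n_codons", "s_sites", "n_sites", "sd", "nd",
        "ka", "ks", "ka_ks", "saturated", "purifying",
    ]
    rows = [
        {
            "gene_a": e.gene_a, "gene_b": e.gene_b, "n_codons": e.n_codons,
            "s_sites": e.s_sites, "n_sites": e.n_sites, "sd": e.sd, "nd": e.nd,
            "ka": e.ka, "ks": e.ks, "ka_ks": e.ratio, "saturated": e.saturated,
            "purifying": bool(e.ratio < 1) if not math.isnan(e.ratio) else False,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=cols)
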
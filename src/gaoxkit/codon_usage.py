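"""Codon-usage-bias statistics.

Implements the classical bias toolbox for coding sequences:

* per-gene codon counts over the 61 sense codons;
* RSCU (relative synonymous codon usage): observed count of a codon divided
  by the mean count of its synonymous family, 1 meaning no preference;
* third-position composition A3s/T3s/G3s/C3s over synonymous codons (the
  single-codon families Met/ATG and Trp/TGG carry no synonymous signal and
  are excluded), with GC3s = G3s + C3s;
* positional GC content GC1/GC2/GC3 over all sense codons, GC12 their
  first-and-second-position mean;
* Wright's effective number of codons (ENC), range 20 (one codon per amino
  acid) to 61 (uniform use), plus the mutation-only expectation
  ENC_exp(s) = 2 + s + 29/(s^2 + (1-s)^2) used in ENC plots;
* parity-rule-2 (PR2) coordinates x = G3s/(G3s+C3s), y = A3s/(A3s+T3s);
* Pearson correlation analysis across genes between composition indices.

A note on conventions: the third-position fractions here are plain base
fractions over synonymous codons and sum to one. CodonW, the program that
popularised these indices, uses idiosyncratic per-base denominators; the
two conventions preserve every qualitative ordering but are not numerically
identical. GC3s here is G3s + C3s under the same convention.

All operations are deterministic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import CODON_TO_AA, SENSE_CODONS, CodingSequence

__all__ = [
    "CodonCountTable",
    "CodonUsageSummary",
    "SYNONYMOUS_FAMILIES",
    "count_codons",
    "rscu",
    "base_composition_3s",
    "gc_partition",
    "enc",
    "enc_expected",
    "pr2_coordinates",
    "summarize_gene",
    "correlation_analysis",
    "batch_summary",
    "rscu_matrix",
    "enc_plot_table",
    "pr2_table",
]

# amino acid -> sorted tuple of synonymous codons (standard code, 61 sense)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
SYNONYMOUS_FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in SYNONYMOUS_FAMILIES
}
# families with >1 codon carry synonymous-choice information
_INFORMATIVE_AAS = tuple(aa for aa, fam in SYNONYMOUS_FAMILIES.items() if len(fam) > 1)
_SINGLE_CODONS = frozenset(
    c for aa, fam in SYNONYMOUS_FAMILIES.items() if len(fam) == 1 for c in fam
)  # ATG, TGG

MIN_CODONS_FOR_ENC = 50


@dataclass(frozen=True)
class CodonCountTable:
    """Per-gene counts over the 61 sense codons; N-containing codons are
    excluded from ``counts`` and tallied in ``n_skipped``."""

    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, aa: str) -> list[int]:
        return [self.counts.get(c, 0) for c in SYNONYMOUS_FAMILIES[aa]]


@dataclass(frozen=True)
class CodonUsageSummary:
    gene_id: str
    a3s: float
    t3s: float
    g3s: float
    c3s: float
    gc3s: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    enc: float
    rscu: dict[str, float]
    group_label: str = ""
    taxon_label: str = ""


def count_codons(cds: CodingSequence | str, gene_id: str | None = None) -> CodonCountTable:
    """In-frame codon counts. Stop codons are rejected upstream by
    CodingSequence validation; N-containing codons are skipped and tallied."""
    if isinstance(cds, str):
        cds = CodingSequence(gene_id or "seq", cds.upper())
    counts: Counter[str] = Counter()
    skipped = 0
    for codon in cds.codons():
        if "N" in codon:
            skipped += 1
        else:
            counts[codon] += 1
    return CodonCountTable(gene_id or cds.gene_id, dict(counts), skipped)


def rscu(table: CodonCountTable) -> dict[str, float]:
    """RSCU_ij = x_ij * k_i / sum_j x_ij per synonymous family of size k_i.

    Families with zero total usage yield NaN for each member codon.
    Single-codon families (ATG, TGG) are omitted (RSCU is trivially 1).
    """
    out: dict[str, float] = {}
    for aa in _INFORMATIVE_AAS:
        fam = SYNONYMOUS_FAMILIES[aa]
        total = sum(table.counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = table.counts.get(c, 0) * len(fam) / total if total else float("nan")
    return out


def base_composition_3s(table: CodonCountTable) -> tuple[float, float, float, float, float]:
    """(a3s, t3s, g3s, c3s, gc3s): third-position base fractions over
    synonymous codons only. Sums to 1 across A/T/G/C; gc3s = g3s + c3s.

    Raises ValueError when the gene contains no synonymous codons.
    """
    third = Counter()
    for codon, n in table.counts.items():
        if codon not in _SINGLE_CODONS:
            third[codon[2]] += n
    total = sum(third.values())
    if total == 0:
        raise ValueError(f"{table.gene_id}: no synonymous codons; X3s undefined")
    a, t, g, c = (third[b] / total for b in "ATGC")
    return a, t, g, c, g + c


def gc_partition(table: CodonCountTable) -> tuple[float, float, float, float, float]:
    """(gc, gc1, gc2, gc3, gc12) over all sense codons; gc12 = (gc1+gc2)/2."""
    pos_gc = [0, 0, 0]
    total = table.n_codons
    if total == 0:
        raise ValueError(f"{table.gene_id}: empty codon table")
    for codon, n in table.counts.items():
        for i in range(3):
            if codon[i] in "GC":
                pos_gc[i] += n
    gc1, gc2, gc3 = (p / total for p in pos_gc)
    return (gc1 + gc2 + gc3) / 3.0, gc1, gc2, gc3, (gc1 + gc2) / 2.0


def _family_f(counts: list[int]) -> float | None:
    """Wright's codon-homozygosity F = (n*sum(p^2) - 1)/(n - 1) for one
    family; None when the family is unusable (n < 2 or F <= 0)."""
    n = sum(counts)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in counts)
    f = (n * sum_p2 - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc(table: CodonCountTable) -> float:
    """Wright's effective number of codons.

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the mean homozygosity of the
    degeneracy-k families (2-fold: 9 families; 3-fold: Ile; 4-fold: 5;
    6-fold: Leu/Ser/Arg). A degeneracy class with no usable family borrows
    the mean of the observed classes' means (F3 preferentially borrows
    (F2+F4)/2). Capped at 61.
    """
    if table.n_codons < MIN_CODONS_FOR_ENC:
        warnings.warn(
            f"{table.gene_id}: only {table.n_codons} codons; ENC has high variance",
            stacklevel=2,
        )
    class_fs: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa in _INFORMATIVE_AAS:
        fam = SYNONYMOUS_FAMILIES[aa]
        f = _family_f(table.family_counts(aa))
        if f is not None:
            class_fs[len(fam)].append(f)
    means: dict[int, float] = {k: float(np.mean(v)) for k, v in class_fs.items() if v}
    if not means:
        raise ValueError(f"{table.gene_id}: too few codons in every family; ENC undefined")
    # impute missing degeneracy classes
    fbar: dict[int, float] = {}
    for k in (2, 3, 4, 6):
        if k in means:
            fbar[k] = means[k]
        elif k == 3 and 2 in means and 4 in means:
            fbar[k] = (means[2] + means[4]) / 2.0
        else:
            fbar[k] = float(np.mean(list(means.values())))
    nc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return min(nc, 61.0)


def enc_expected(gc3s: float) -> float:
    """Mutation-only ENC expectation for a gene with third-position GC
    content ``gc3s``: 2 + s + 29/(s^2 + (1-s)^2)."""
    s = gc3s
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def pr2_coordinates(table: CodonCountTable) -> tuple[float, float]:
    """PR2-plot point (x, y) = (G3s/(G3s+C3s), A3s/(A3s+T3s)).

    (0.5, 0.5) marks parity (no strand/selection asymmetry at silent sites).
    Raises ValueError on a zero denominator.
    """
    a, t, g, c, _ = base_composition_3s(table)
    if (g + c) == 0 or (a + t) == 0:
        raise ValueError(f"{table.gene_id}: PR2 undefined (zero denominator)")
    return g / (g + c), a / (a + t)


def summarize_gene(
    cds: CodingSequence | str,
    gene_id: str | None = None,
    group_label: str = "",
    taxon_label: str = "",
) -> CodonUsageSummary:
    """All bias indices for one coding sequence."""
    table = count_codons(cds, gene_id)
    a3s, t3s, g3s, c3s, gc3s = base_composition_3s(table)
    gc, gc1, gc2, gc3, gc12 = gc_partition(table)
    return CodonUsageSummary(
        gene_id=table.gene_id,
        a3s=a3s, t3s=t3s, g3s=g3s, c3s=c3s, gc3s=gc3s,
        gc=gc, gc1=gc1, gc2=gc2, gc3=gc3, gc12=gc12,
        enc=enc(table),
        rscu=rscu(table),
        group_label=group_label,
        taxon_label=taxon_label,
    )


_CORR_COLUMNS = ("a3s", "t3s", "g3s", "c3s", "gc3s", "gc", "gc12")


def correlation_analysis(summaries: pd.DataFrame | list[CodonUsageSummary]) -> pd.DataFrame:
    """Pearson correlation (and two-sided p) between composition indices
    across genes.

    Returns a long-format frame with columns index_a, index_b, pearson_r,
    p_value; symmetric with unit diagonal. A constant column yields NaN for
    its pairs.
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summary_frame(summaries)
    if len(df) < 3:
        raise ValueError("correlation analysis needs at least 3 genes")
    rows = []
    for ia in _CORR_COLUMNS:
        for ib in _CORR_COLUMNS:
            x, y = df[ia].to_numpy(float), df[ib].to_numpy(float)
            if ia == ib:
                r, p = 1.0, 0.0
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                res = stats.pearsonr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            rows.append({"index_a": ia, "index_b": ib, "pearson_r": r, "p_value": p})
    return pd.DataFrame(rows)


def summary_frame(summaries: list[CodonUsageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "group": s.group_label,
                "taxon": s.taxon_label,
                "a3s": s.a3s, "t3s": s.t3s, "g3s": s.g3s, "c3s": s.c3s,
                "gc3s": s.gc3s, "gc": s.gc, "gc1": s.gc1, "gc2": s.gc2,
                "gc3": s.gc3, "gc12": s.gc12, "enc": s.enc,
            }
            for s in summaries
        ]
    )


def batch_summary(
    records: list[tuple[str, str]],
    labels: dict[str, tuple[str, str]] | None = None,
) -> list[CodonUsageSummary]:
    """Summaries for a panel of (gene_id, cds) records.

    ``labels`` maps gene_id -> (group_label, taxon_label); unlabeled genes
    get the default label with a warning.
    """
    labels = labels or {}
    out = []
    for gene_id, seq in records:
        if gene_id not in labels and labels:
            warnings.warn(f"{gene_id}: no label supplied; using default", stacklevel=2)
        group, taxon = labels.get(gene_id, ("unlabeled", "unlabeled"))
        out.append(summarize_gene(seq, gene_id, group, taxon))
    return out


def rscu_matrix(summaries: list[CodonUsageSummary]) -> pd.DataFrame:
    """Gene x codon RSCU matrix, codons ordered by amino acid then
    alphabetically; NaN where a family is unused (exported blank, not 0)."""
    codon_order = [
        c for aa in sorted(_INFORMATIVE_AAS) for c in SYNONYMOUS_FAMILIES[aa]
    ]
    data = {s.gene_id: [s.rscu.get(c, float("nan")) for c in codon_order] for s in summaries}
    return pd.DataFrame(data, index=codon_order).T.rename_axis("gene_id")


def enc_plot_table(summaries: list[CodonUsageSummary], curve_points: int = 101) -> pd.DataFrame:
    """Plot-ready ENC-plot data: observed (gc3s, enc) points plus samples of
    the expected curve, distinguished by the ``kind`` column."""
    pts = pd.DataFrame(
        {
            "kind": "observed",
            "gene_id": [s.gene_id for s in summaries],
            "group": [s.group_label for s in summaries],
            "gc3s": [s.gc3s for s in summaries],
            "enc": [s.enc for s in summaries],
        }
    )
    grid = np.linspace(0.0, 1.0, curve_points)
    curve = pd.DataFrame(
        {
            "kind": "expected",
            "gene_id": "",
            "group": "",
            "gc3s": grid,
            "enc": [enc_expected(s) for s in grid],
        }
    )
    return pd.concat([pts, curve], ignore_index=True)


def pr2_table(summaries: list[CodonUsageSummary]) -> pd.DataFrame:
    """PR2-plot points per gene: x = G3s/(G3s+C3s), y = A3s/(A3s+T3s)."""
    rows = []
    for s in summaries:
        gc_den, at_den = s.g3s + s.c3s, s.a3s + s.t3s
        rows.append(
            {
                "gene_id": s.gene_id,
                "group": s.group_label,
                "x_gc_bias": s.g3s / gc_den if gc_den else float("nan"),
                "y_at_bias": s.a3s / at_den if at_den else float("nan"),
            }
        )
    return pd.DataFrame(rows)
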
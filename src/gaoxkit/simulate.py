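"""Synthetic-data generators with known ground truth.

Every pipeline stage gets a generator that emulates the statistical
structure of the real study inputs — codon-biased CDS panels, ortholog
pairs diverged under a controlled dN/dS, promoters with planted motifs,
RNA-seq count matrices, and qPCR Ct tables — together with a
machine-readable truth object, so the full analysis is testable offline.

Determinism: a single integer seed plus a fixed per-generator stream id
feeds ``numpy.random.default_rng([seed, stream_id])``, so identical
(config, seed) always reproduce byte-identical outputs and adding a new
generator never perturbs existing ones.

Default conditions mirror the study system: genes of ~350 codons (the real
family spans 244-430 aa), 3000-bp promoters, qPCR sampled at 0/6/12/24/48 h
with three biological x three technical replicates, and a two-regime codon
panel contrasting a strongly GC3-biased (monocot-like) and an unbiased
(basal-angiosperm-like) sub-panel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cis_elements import IUPAC, MotifDefinition, scan_sequence
from .kaks import ng86_sites
from .seqio import CODON_TO_AA, CodingSequence, reverse_complement
from .codon_usage import SYNONYMOUS_FAMILIES

__all__ = [
    "SimulationConfig",
    "simulate_cds",
    "simulate_taxon_panel",
    "simulate_ortholog_pair",
    "simulate_promoter",
    "simulate_qpcr",
    "simulate_counts",
]

_STREAMS = {"cds": 1, "panel": 2, "orthologs": 3, "promoters": 4, "qpcr": 5, "counts": 6}
_AAS = tuple(sorted(SYNONYMOUS_FAMILIES))  # 20 amino acids


def _rng(seed: int, stream: str, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream], int(offset)])


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of generator settings for an end-to-end synthetic study."""

    seed: int = 0
    n_genes: int = 20
    n_codons: int = 350
    gc3_target: float = 0.9
    bias_strength: float = 3.0
    omega: float = 0.2
    syn_divergence_target: float = 0.1
    promoter_length: int = 3000
    motif_plan: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    qpcr_truth: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.2
    library_size: int = 10_000_000


def _codon_weights(gc3_target: float, bias_strength: float) -> dict[str, float]:
    """Per-codon selection weight: exp(bias_strength) when the third base
    falls in the targeted class (GC when gc3_target > 0.5, AT when < 0.5),
    1 otherwise. gc3_target = 0.5 or bias_strength = 0 gives uniform use."""
    if not 0.0 <= gc3_target <= 1.0:
        raise ValueError("gc3_target must be in [0, 1]")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    target = "GC" if gc3_target > 0.5 else ("AT" if gc3_target < 0.5 else "")
    return {
        codon: float(np.exp(bias_strength)) if codon[2] in target else 1.0
        for codon in CODON_TO_AA
    }


def simulate_cds(
    n_genes: int = 20,
    n_codons: int = 350,
    gc3_target: float = 0.5,
    bias_strength: float = 0.0,
    seed: int = 0,
    prefix: str = "gene",
) -> list[tuple[str, str]]:
    """Coding sequences with controllable third-position bias.

    Amino acids are drawn uniformly; within each synonymous family the codon
    is chosen with probability proportional to its weight (see
    ``_codon_weights``). No stop codons can occur; output is deterministic
    under (arguments, seed).
    """
    rng = _rng(seed, "cds")
    weights = _codon_weights(gc3_target, bias_strength)
    fam_probs = {
        aa: np.array([weights[c] for c in fam]) / sum(weights[c] for c in fam)
        for aa, fam in SYNONYMOUS_FAMILIES.items()
    }
    records = []
    for g in range(n_genes):
        aas = rng.choice(len(_AAS), size=n_codons)
        codons = []
        for ai in aas:
            aa = _AAS[ai]
            fam = SYNONYMOUS_FAMILIES[aa]
            codons.append(fam[rng.choice(len(fam), p=fam_probs[aa])])
        records.append((f"{prefix}{g:03d}", "".join(codons)))
    return records


def simulate_taxon_panel(
    n_genes: int = 20,
    n_codons: int = 350,
    gc3_target: float = 0.9,
    bias_strength: float = 3.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, str]]]:
    """Two-regime panel: a GC3-biased (monocot-like) and an unbiased
    (basal-like) sub-panel, with labels ready for ``batch_summary``.

    Returns (records, labels) where labels maps gene_id ->
    (group_label, taxon_label).
    """
    rng_split = _rng(seed, "panel")
    seed_a, seed_b = (int(x) for x in rng_split.integers(0, 2**31 - 1, size=2))
    biased = simulate_cds(n_genes, n_codons, gc3_target, bias_strength, seed_a, "biased_")
    unbiased = simulate_cds(n_genes, n_codons, 0.5, 0.0, seed_b, "unbiased_")
    labels = {g: ("GC3-biased", "monocot-like") for g, _ in biased}
    labels.update({g: ("unbiased", "basal-like") for g, _ in unbiased})
    return biased + unbiased, labels


def simulate_ortholog_pair(
    n_codons: int = 500,
    omega: float = 0.2,
    syn_divergence_target: float = 0.1,
    seed: int = 0,
    pair_id: str = "pair",
) -> dict:
    """An ancestor/descendant CDS pair diverged under dN/dS = ``omega``.

    The ancestor comes from ``simulate_cds`` (unbiased); the descendant is
    produced by proposing uniform random single-nucleotide changes and
    accepting synonymous ones always, nonsynonymous ones with probability
    ``omega``, rejecting stop-creating changes, until the accepted
    synonymous changes reach ``syn_divergence_target`` substitutions per
    synonymous site (NG86 site count of the ancestor). This acceptance
    sampler matches omega only at low divergence, the regime it is meant
    to validate.

    Returns a truth dict with both sequences and the realised substitution
    counts.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = _rng(seed, "orthologs")
    (anc_id, anc_seq), = simulate_cds(1, n_codons, 0.5, 0.0,
                                      int(rng.integers(0, 2**31 - 1)), f"{pair_id}_anc")
    codons = [anc_seq[i: i + 3] for i in range(0, len(anc_seq), 3)]
    s_anc = sum(ng86_sites(c)[0] for c in codons)
    target_syn = max(1, round(syn_divergence_target * s_anc))
    syn_count = nonsyn_count = 0
    max_attempts = 10_000 + 4000 * target_syn
    attempts = 0
    while syn_count < target_syn:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"divergence target unreachable after {max_attempts} proposals"
            )
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        cur = codons[ci]
        new_base = "ACGT"[int(rng.integers(0, 4))]
        if new_base == cur[pos]:
            continue
        mut = cur[:pos] + new_base + cur[pos + 1:]
        if mut not in CODON_TO_AA:  # stop codon
            continue
        if CODON_TO_AA[mut] == CODON_TO_AA[cur]:
            codons[ci] = mut
            syn_count += 1
        elif rng.random() < omega:
            codons[ci] = mut
            nonsyn_count += 1
    return {
        "pair_id": pair_id,
        "ancestor": (anc_id, anc_seq),
        "descendant": (f"{pair_id}_des000", "".join(codons)),
        "omega": omega,
        "syn_substitutions": syn_count,
        "nonsyn_substitutions": nonsyn_count,
        "syn_sites_ancestor": s_anc,
    }


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """One concrete DNA instance of an IUPAC consensus."""
    return "".join(sorted(IUPAC[ch])[int(rng.integers(0, len(IUPAC[ch])))] for ch in consensus)


def simulate_promoter(
    motif_plan: list[tuple[MotifDefinition, int]],
    library: list[MotifDefinition],
    length: int = 3000,
    seed: int = 0,
    gene_id: str = "promoter",
    max_clean_iterations: int = 300,
) -> tuple[str, pd.DataFrame]:
    """A promoter with motifs planted at known counts on a motif-free
    background.

    Motifs from ``motif_plan`` are planted at non-overlapping random
    positions on random strands over a uniform background; the background
    is then iteratively re-randomised until it contains no occurrence of
    any library motif outside the planted intervals (spurious matches
    arising by chance are scrubbed; matches inside a planted instance —
    e.g. an ABRE core inside a planted G-Box — are inherent and kept).

    Returns (sequence, truth) where truth lists, per library motif, the
    number of occurrences the planted instances account for (both strands).
    """
    gene_tag = zlib.crc32(gene_id.encode()) % (2**31)  # stable across processes
    rng = _rng(seed, "promoters", gene_tag)
    planted: list[tuple[int, str]] = []  # (0-based start, inserted string)
    max_k = max((len(m.consensus) for m in library), default=0)
    # choose non-overlapping positions with a buffer of max_k on each side
    intervals: list[tuple[int, int]] = []
    total_span = sum(len(m.consensus) + 2 * max_k for m, n in motif_plan for _ in range(n))
    if total_span > length:
        raise ValueError("motif plan too dense for the promoter window")
    instances: list[tuple[MotifDefinition, str]] = []
    for motif, n in motif_plan:
        for _ in range(n):
            inst = _realize_consensus(motif.consensus, rng)
            if rng.random() < 0.5:
                inst = reverse_complement(inst)
            instances.append((motif, inst))
    for motif, inst in instances:
        k = len(inst)
        for _attempt in range(10_000):
            start = int(rng.integers(0, length - k + 1))
            if all(start + k + max_k <= s or start >= e + max_k for s, e in intervals):
                intervals.append((start, start + k))
                planted.append((start, inst))
                break
        else:
            raise ValueError("motif plan too dense: could not place all instances")

    seq = list("".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=length)))
    for start, inst in planted:
        seq[start: start + len(inst)] = inst
    planted_cover = set()
    for s, e in intervals:
        planted_cover.update(range(s, e))

    for _ in range(max_clean_iterations):
        text = "".join(seq)
        dirty: set[int] = set()
        for motif in library:
            for hit in scan_sequence(text, motif, gene_id):
                lo = hit.position - 1
                span = set(range(lo, lo + len(motif.consensus)))
                if not span <= planted_cover:
                    dirty |= span - planted_cover
        if not dirty:
            break
        for i in sorted(dirty):
            seq[i] = "ACGT"[int(rng.integers(0, 4))]
    else:
        raise RuntimeError("could not scrub spurious motif matches from background")

    # ground truth: occurrences each planted instance accounts for
    counts = {m.name: 0 for m in library}
    for _start, inst in planted:
        for motif in library:
            counts[motif.name] += len(scan_sequence(inst, motif))
    truth = pd.DataFrame(
        {"gene_id": gene_id, "motif": list(counts), "count": list(counts.values())}
    )
    return "".join(seq), truth


def simulate_qpcr(
    qpcr_truth: dict[tuple[str, str], float],
    reference_gene: str = "REF",
    calibrator_condition: str = "0h",
    noise_sd: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 3,
    baseline_ct: float = 28.0,
    reference_ct: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table with known fold changes.

    ``qpcr_truth`` maps (gene, condition) -> true fold change relative to
    the calibrator condition (where the fold is forced to 1). Target Ct is
    baseline - log2(fold) + N(0, noise_sd) per technical replicate; the
    reference gene sits at a constant baseline plus noise.
    """
    rng = _rng(seed, "qpcr")
    genes = sorted({g for g, _ in qpcr_truth})
    conditions = sorted({c for _, c in qpcr_truth})
    if calibrator_condition not in conditions:
        conditions = [calibrator_condition] + conditions
    rows = []
    for gene in genes + [reference_gene]:
        for cond in conditions:
            if gene == reference_gene:
                base = reference_ct
            else:
                fold = 1.0 if cond == calibrator_condition else qpcr_truth.get((gene, cond), 1.0)
                if fold <= 0:
                    raise ValueError(f"fold must be positive: {gene}/{cond}")
                base = baseline_ct - float(np.log2(fold))
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                    rows.append(
                        {"gene": gene, "condition": cond, "bio_rep": b,
                         "tech_rep": t, "ct": base + noise}
                    )
    return pd.DataFrame(rows)


def simulate_counts(
    true_tpm: pd.Series,
    lengths: pd.Series,
    library_size: int = 10_000_000,
    n_samples: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial read counts whose expectation recovers ``true_tpm``.

    ``true_tpm`` must sum to 1e6; read probabilities are proportional to
    TPM x length, the standard length-biased sampling of RNA-seq.
    """
    if not np.isclose(true_tpm.sum(), 1e6, rtol=1e-6):
        raise ValueError(f"true TPM must sum to 1e6, got {true_tpm.sum()}")
    lengths = lengths.reindex(true_tpm.index)
    rng = _rng(seed, "counts")
    p = (true_tpm * lengths).to_numpy(float)
    p = p / p.sum()
    data = {
        f"sample{j + 1}": rng.multinomial(int(library_size), p)
        for j in range(n_samples)
    }
    return pd.DataFrame(data, index=true_tpm.index.rename("gene_id"))
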
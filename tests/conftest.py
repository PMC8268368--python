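"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from gaoxkit.seqio import write_fasta
from gaoxkit import simulate as sim


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*ENC has high variance")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """A complete study-shaped input bundle on disk: CDS FASTA, promoter
    FASTA, count matrix, Ct table, and a Ka/Ks pair list."""
    root = tmp_path_factory.mktemp("bundle")

    cds = sim.simulate_cds(n_genes=6, n_codons=200, seed=7, prefix="LcGAox")
    pair = sim.simulate_ortholog_pair(n_codons=200, omega=0.3, seed=7, pair_id="orth")
    cds += [pair["ancestor"], pair["descendant"]]
    write_fasta(cds, root / "cds.fasta")

    from gaoxkit.cis_elements import default_motif_library

    library = default_motif_library()
    abre = next(m for m in library if m.name == "ABRE")
    promoters, truths = [], []
    for i, (gene_id, _) in enumerate(cds):
        seq, truth = sim.simulate_promoter(
            [(abre, i % 3)], library, length=1200, seed=7, gene_id=gene_id
        )
        promoters.append((gene_id, seq))
        truths.append(truth)
    write_fasta(promoters, root / "promoters.fasta")
    pd.concat(truths, ignore_index=True).to_csv(
        root / "promoter_truth.tsv", sep="\t", index=False
    )

    genes = [g for g, _ in cds]
    lengths = pd.Series([len(s) for _, s in cds], index=genes, dtype=float)
    tpm_true = pd.Series(
        np.linspace(1, 4, len(genes)) * 1e6 / np.linspace(1, 4, len(genes)).sum(),
        index=genes,
    )
    counts = sim.simulate_counts(tpm_true, lengths, library_size=500_000,
                                 n_samples=3, seed=7)
    counts.insert(0, "length", lengths.astype(int))
    counts.to_csv(root / "counts.tsv", sep="\t")

    qpcr_truth = {
        (genes[0], "6h"): 8.0, (genes[0], "12h"): 16.0,
        (genes[1], "6h"): 0.5, (genes[1], "12h"): 2.0,
    }
    sim.simulate_qpcr(qpcr_truth, noise_sd=0.1, seed=7).to_csv(
        root / "ct.tsv", sep="\t", index=False
    )

    pd.DataFrame({"gene_a": [pair["ancestor"][0]],
                  "gene_b": [pair["descendant"][0]]}).to_csv(
        root / "pairs.tsv", sep="\t", index=False
    )
    return {
        "root": root,
        "cds": cds,
        "genes": genes,
        "qpcr_truth": qpcr_truth,
        "tpm_true": tpm_true,
        "pair": pair,
    }
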
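"""End-to-end orchestration: run every analysis stage over one input bundle
and emit the study-shaped tables.

Outputs (tab-separated, UTF-8, '.' decimal, NA for missing) in the chosen
directory:

* properties.tsv  — gene, length, Mw (kDa), pI, acid/base class
* kaks.tsv        — pairwise Ka, Ks, Ka/Ks with a purifying flag
* codon_usage.tsv — per-gene composition indices and ENC
* enc_plot.tsv    — observed (GC3s, ENC) points plus the expected curve
* pr2.tsv         — parity-rule-2 coordinates per gene
* rscu_matrix.tsv — gene x codon RSCU values (NA = unused family)
* cis_counts.tsv  — gene x motif occurrence counts
* tpm.tsv         — genes x samples TPM
* ddct.tsv        — qPCR relative expression with responsiveness calls

Every stage is deterministic; the run log records the config hash and seed
so a run can be reproduced exactly. Inputs may be real files or the bundled
synthetic generators.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cis_elements import (category_rollup, count_matrix, default_motif_library,
                           load_motif_library, scan_promoter)
from .codon_usage import (batch_summary, enc_plot_table, pr2_table,
                          rscu_matrix, summary_frame)
from .expression import (delta_delta_ct, relative_expression_frame, tpm)
from .kaks import kaks_pair, purifying_selection_report
from .protein import properties_table
from .seqio import CodingSequence, read_fasta, translate_cds

__all__ = ["RunConfig", "run_all", "validate_outputs", "PipelineError"]

logger = logging.getLogger("gaoxkit")

OUTPUT_FILES = (
    "properties.tsv", "kaks.tsv", "codon_usage.tsv", "enc_plot.tsv", "pr2.tsv",
    "rscu_matrix.tsv", "cis_counts.tsv", "tpm.tsv", "ddct.tsv",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one full run. All paths must exist."""

    cds_fasta: str
    promoter_fasta: str
    counts_tsv: str          # genes x samples with a 'length' column
    ct_tsv: str              # long-format Ct table
    pairs_tsv: str           # two-column gene id pairs for Ka/Ks
    out_dir: str
    motif_library: str = ""  # empty = bundled default
    reference_gene: str = "REF"
    calibrator_condition: str = "0h"
    log2fd_threshold: float = 3.0
    promoter_window: int = 3000
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage; any failure aborts with the stage name and
    removes partial outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Path] = {}
    for f in OUTPUT_FILES:
        (out / f).unlink(missing_ok=True)
    try:
        # --- seqio / protein properties -------------------------------
        stage = "seqio"
        for p in (config.cds_fasta, config.promoter_fasta, config.counts_tsv,
                  config.ct_tsv, config.pairs_tsv):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        cds_records = read_fasta(config.cds_fasta)
        promoters = read_fasta(config.promoter_fasta)

        stage = "protein_props"
        proteins = [(g, translate_cds(CodingSequence(g, s))) for g, s in cds_records]
        _write(properties_table(proteins), out / "properties.tsv")
        produced["properties.tsv"] = out / "properties.tsv"

        stage = "codon_usage"
        summaries = batch_summary(cds_records)
        _write(summary_frame(summaries), out / "codon_usage.tsv")
        _write(enc_plot_table(summaries), out / "enc_plot.tsv")
        _write(pr2_table(summaries), out / "pr2.tsv")
        _write(rscu_matrix(summaries), out / "rscu_matrix.tsv", index=True)
        produced.update({f: out / f for f in
                         ("codon_usage.tsv", "enc_plot.tsv", "pr2.tsv", "rscu_matrix.tsv")})

        stage = "kaks"
        pairs = pd.read_csv(config.pairs_tsv, sep="\t")
        by_id = {g: CodingSequence(g, s) for g, s in cds_records}
        estimates = []
        for _, row in pairs.iterrows():
            a, b = row.iloc[0], row.iloc[1]
            if a not in by_id or b not in by_id:
                raise KeyError(f"pair {a}/{b}: sequence missing from CDS FASTA")
            estimates.append(kaks_pair(by_id[a], by_id[b]))
        _write(purifying_selection_report(estimates), out / "kaks.tsv")
        produced["kaks.tsv"] = out / "kaks.tsv"

        stage = "cis_elements"
        library = (load_motif_library(config.motif_library)
                   if config.motif_library else default_motif_library())
        hits = []
        for g, seq in promoters:
            hits.extend(scan_promoter(seq, library, g))
        genes = [g for g, _ in promoters]
        mat = count_matrix(hits, genes, library)
        rollup = category_rollup(mat, library)
        combined = pd.concat([mat, rollup.add_prefix("category:")], axis=1)
        _write(combined, out / "cis_counts.tsv", index=True)
        produced["cis_counts.tsv"] = out / "cis_counts.tsv"

        stage = "expression"
        counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        lengths = counts.pop("length")
        _write(tpm(counts, lengths), out / "tpm.tsv", index=True)
        ct = pd.read_csv(config.ct_tsv, sep="\t")
        rel = delta_delta_ct(ct, config.reference_gene, config.calibrator_condition,
                             config.log2fd_threshold)
        _write(relative_expression_frame(rel), out / "ddct.tsv")
        produced["tpm.tsv"] = out / "tpm.tsv"
        produced["ddct.tsv"] = out / "ddct.tsv"

        stage = "logging"
        (out / "run_log.json").write_text(json.dumps(
            {"gaoxkit_version": __version__, "config": asdict(config),
             "config_hash": config.config_hash(), "seed": config.seed,
             "outputs": sorted(produced)}, indent=2))
        logger.info("run complete: %d outputs, config hash %s",
                    len(produced), config.config_hash())
        return produced
    except Exception as exc:
        for p in produced.values():
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc


def validate_outputs(out_dir: str | Path) -> tuple[bool, list[str]]:
    """Schema and cross-file invariant checks on a completed run.

    Verifies: all nine outputs present; TPM columns sum to 1e6; ENC within
    [20, 61]; RSCU family sums equal family size; ddct calibrator folds
    equal 1. Returns (ok, messages)."""
    out = Path(out_dir)
    problems: list[str] = []
    for f in OUTPUT_FILES:
        if not (out / f).exists():
            problems.append(f"missing output {f}")
    if problems:
        return False, problems

    tpm_df = pd.read_csv(out / "tpm.tsv", sep="\t", index_col=0)
    for col in tpm_df.columns:
        total = tpm_df[col].sum()
        if not np.isclose(total, 1e6, rtol=1e-6):
            problems.append(f"tpm.tsv column {col!r} sums to {total}, not 1e6")

    cu = pd.read_csv(out / "codon_usage.tsv", sep="\t")
    bad_enc = cu[(cu["enc"] < 20) | (cu["enc"] > 61)]
    for g in bad_enc["gene_id"]:
        problems.append(f"codon_usage.tsv: ENC out of [20, 61] for {g}")

    from .codon_usage import SYNONYMOUS_FAMILIES
    rscu_df = pd.read_csv(out / "rscu_matrix.tsv", sep="\t", index_col=0)
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if len(fam) < 2 or not set(fam) <= set(rscu_df.columns):
            continue
        sums = rscu_df[list(fam)].sum(axis=1, skipna=False)
        ok = sums.isna() | np.isclose(sums, len(fam), atol=1e-6)
        for g in rscu_df.index[~ok]:
            problems.append(f"rscu_matrix.tsv: family {aa} does not sum to {len(fam)} for {g}")

    run_log = json.loads((out / "run_log.json").read_text())
    calibrator = run_log["config"]["calibrator_condition"]
    ddct = pd.read_csv(out / "ddct.tsv", sep="\t")
    cal = ddct[ddct["condition"] == calibrator]
    for _, row in cal.iterrows():
        if abs(row["fold"] - 1.0) > 1e-9:
            problems.append(f"ddct.tsv: calibrator fold != 1 for {row['gene']}")

    return (not problems), problems
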
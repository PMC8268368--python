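"""Expression analysis: TPM normalisation of count matrices and qPCR
relative expression by the comparative-threshold (delta-delta-Ct) method.

TPM (transcripts per million): counts are divided by effective length in
kilobases and the per-sample rates rescaled to sum to 1e6, so TPM columns
are comparable across samples and always sum to one million.

Delta-delta-Ct: technical replicates are averaged within each biological
replicate; dCt = Ct(target) - Ct(reference) per condition and replicate;
ddCt = dCt(condition) - mean dCt(calibrator); fold change = 2^(-ddCt).
Biological replicates are summarised on the log2 scale (mean ddCt, standard
error), i.e. the reported fold is a geometric mean. A gene is called
stress-responsive when log2 fold change exceeds a threshold (default 3,
strict inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RelativeExpression",
    "tpm",
    "delta_delta_ct",
    "responsiveness_call",
    "heatmap_table",
]

LOG2FD_THRESHOLD = 3.0


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM matrix from a genes x samples count matrix.

    ``lengths`` gives each gene's effective length in nucleotides (> 0).
    An all-zero sample column becomes NaN with a warning.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"no length for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    dead = totals == 0
    if dead.any():
        warnings.warn(f"all-zero sample column(s): {list(totals[dead].index)}", stacklevel=2)
        totals = totals.replace(0, np.nan)
    return rate.div(totals, axis=1) * 1e6


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    condition: str
    delta_ct: float          # mean across biological replicates
    delta_delta_ct: float    # mean across biological replicates
    se_log2: float           # SE of -ddCt across biological replicates
    fold: float              # 2 ** (-delta_delta_ct)
    log2_fold: float         # -delta_delta_ct
    responsive: bool


_REQUIRED_CT_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "ct")


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
    threshold: float = LOG2FD_THRESHOLD,
) -> list[RelativeExpression]:
    """Relative expression for every target gene x condition.

    ``records`` is a long-format Ct table with columns gene, condition,
    bio_rep, tech_rep, ct. The reference gene must be measured in every
    condition and the calibrator condition must be present.
    """
    missing = set(_REQUIRED_CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    # average technical replicates within each biological replicate
    ct = (
        records.groupby(["gene", "condition", "bio_rep"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    conditions = sorted(ct["condition"].unique())
    if calibrator_condition not in conditions:
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent")
    ref = ct[ct["gene"] == reference_gene].set_index(["condition", "bio_rep"])["ct"]
    for cond in conditions:
        if cond not in ref.index.get_level_values(0):
            raise ValueError(f"reference gene {reference_gene!r} not measured in {cond!r}")

    out: list[RelativeExpression] = []
    targets = [g for g in sorted(ct["gene"].unique()) if g != reference_gene]
    for gene in targets:
        sub = ct[ct["gene"] == gene].set_index(["condition", "bio_rep"])["ct"]
        # per-replicate dCt where target and reference share a replicate
        dct = (sub - ref).dropna()
        if calibrator_condition not in dct.index.get_level_values(0):
            raise ValueError(f"gene {gene!r} not measured in calibrator condition")
        cal = dct.loc[calibrator_condition].mean()
        for cond in sorted(dct.index.get_level_values(0).unique()):
            vals = dct.loc[cond]
            ddct = vals - cal
            mean_ddct = float(ddct.mean())
            n = len(ddct)
            se = float(ddct.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            log2_fold = -mean_ddct
            out.append(
                RelativeExpression(
                    gene=gene,
                    condition=cond,
                    delta_ct=float(vals.mean()),
                    delta_delta_ct=mean_ddct,
                    se_log2=se,
                    fold=float(2.0 ** (-mean_ddct)),
                    log2_fold=log2_fold,
                    responsive=bool(log2_fold > threshold),
                )
            )
    return out


def relative_expression_frame(results: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "condition": r.condition, "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct, "se_log2": r.se_log2,
                "fold": r.fold, "log2_fold": r.log2_fold, "responsive": r.responsive,
            }
            for r in results
        ]
    )


def responsiveness_call(
    results: list[RelativeExpression] | pd.DataFrame,
    threshold: float = LOG2FD_THRESHOLD,
) -> pd.DataFrame:
    """Boolean responsiveness per gene x condition: log2 fold change strictly
    greater than ``threshold`` (a gene exactly at the threshold is not
    called)."""
    df = results if isinstance(results, pd.DataFrame) else relative_expression_frame(results)
    out = df[["gene", "condition", "log2_fold"]].copy()
    out["responsive"] = out["log2_fold"] > threshold
    return out


def heatmap_table(expression: pd.DataFrame, scaling: str = "none") -> pd.DataFrame:
    """Plot-ready matrix with deterministic row/column order.

    ``scaling``: 'none' (identity), 'log2' (log2(x+1)), or 'zscore'
    (per-gene standardisation; constant rows become 0 with a warning).
    """
    mat = expression.sort_index(axis=0).sort_index(axis=1)
    if scaling == "none":
        return mat
    if scaling == "log2":
        return np.log2(mat + 1.0)
    if scaling == "zscore":
        mu = mat.mean(axis=1)
        sd = mat.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(f"constant gene row(s) z-scored to 0: {list(mat.index[flat])}",
                          stacklevel=2)
            sd = sd.replace(0, 1.0)
        return mat.sub(mu, axis=0).div(sd, axis=0)
    raise ValueError(f"unknown scaling {scaling!r}")
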
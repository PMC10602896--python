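"""Expression-table thresholds and qPCR relative quantification.

Differential-expression statistics are consumed, not computed: this module
applies the expressed-gene (mean TPM >= 1) and DEG (fold change >= 2,
adjusted p <= 0.05) filters to a results table, and implements the Livak
2^-ddCt relative-expression formula for qPCR Ct tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TPM_EXPRESSED = 1.0
DEG_MIN_FOLD = 2.0
DEG_MAX_ADJ_P = 0.05


class ExpressionError(ValueError):
    pass


def filter_expressed_genes(
    records: pd.DataFrame,
    tpm_threshold: float = TPM_EXPRESSED,
    tpm_column: str = "mean_tpm",
) -> pd.DataFrame:
    """Genes with mean TPM >= threshold (boundary inclusive).

    ``records`` needs a ``gene_id`` column and either ``tpm_column`` or a
    set of per-sample ``tpm_*`` columns to average.
    """
    df = records.copy()
    if tpm_column not in df.columns:
        sample_cols = [c for c in df.columns if c.startswith("tpm_")]
        if not sample_cols:
            raise ExpressionError(
                f"no {tpm_column!r} column and no tpm_* sample columns"
            )
        df[tpm_column] = df[sample_cols].mean(axis=1)
    return df[df[tpm_column] >= tpm_threshold].reset_index(drop=True)


def call_deg(
    records: pd.DataFrame,
    min_fold: float = DEG_MIN_FOLD,
    max_adj_p: float = DEG_MAX_ADJ_P,
) -> dict[str, set[str]]:
    """Differentially expressed genes: |log2FC| >= log2(min_fold) AND
    adjusted p <= max_adj_p, both boundaries inclusive.

    Returns ``{"up": ..., "down": ...}`` by the sign of log2FC
    (treatment vs control). Genes with missing adjusted p are excluded
    with a warning.
    """
    if min_fold < 1:
        raise ExpressionError("min_fold must be >= 1")
    df = records
    missing = df["padj"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} genes lack adjusted p and were excluded",
            stacklevel=2,
        )
        df = df[~missing]
    min_l2fc = math.log2(min_fold)
    is_deg = (df["log2fc"].abs() >= min_l2fc) & (df["padj"] <= max_adj_p)
    deg = df[is_deg]
    return {
        "up": set(deg.loc[deg["log2fc"] > 0, "gene_id"]),
        "down": set(deg.loc[deg["log2fc"] < 0, "gene_id"]),
    }


@dataclass
class DdctResult:
    fold_change: float  # 2^-ddCt for the treatment group
    ddct: float
    per_replicate: pd.DataFrame  # relative expression per sample


def ddct_relative_expression(
    measurements: pd.DataFrame,
    control_label: str = "control",
    treatment_label: str = "treatment",
) -> DdctResult:
    """Livak 2^-ddCt relative expression from a qPCR Ct table.

    ``measurements`` columns: ``sample_id``, ``condition``, ``target_ct``,
    ``reference_ct``. Per sample dCt = target_ct - reference_ct;
    ddCt = mean dCt(treatment) - mean dCt(control); fold change = 2^-ddCt.
    Per-replicate values are 2^-(dCt - mean dCt(control)), so the control
    group averages near 1.
    """
    df = measurements.copy()
    for col in ("condition", "target_ct", "reference_ct"):
        if col not in df.columns:
            raise ExpressionError(f"missing column {col!r}")
    df["dct"] = df["target_ct"] - df["reference_ct"]
    groups = {
        label: df.loc[df["condition"] == label, "dct"]
        for label in (control_label, treatment_label)
    }
    for label, vals in groups.items():
        if vals.empty:
            raise ExpressionError(f"condition {label!r} has no replicates")
    control_mean = float(groups[control_label].mean())
    ddct = float(groups[treatment_label].mean()) - control_mean
    per_rep = df[df["condition"].isin(groups)].copy()
    per_rep["relative_expression"] = np.power(2.0, -(per_rep["dct"] - control_mean))
    return DdctResult(
        fold_change=float(2.0 ** -ddct),
        ddct=ddct,
        per_replicate=per_rep,
    )
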
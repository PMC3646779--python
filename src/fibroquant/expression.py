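"""Relative gene expression by the 2^-ΔΔCT method.

ΔCT1 is a sample's (replicate-averaged) target-gene CT minus its
housekeeping CT; ΔCT2 is the mean ΔCT of the control group; the fold
induction is 2^-(ΔCT1 - ΔCT2). Housekeeping normalization makes the result
invariant to a constant CT shift of a sample, and the geometric mean of the
control-group folds is exactly 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("fibroquant")

__all__ = ["delta_ct", "fold_induction", "ddct_analysis"]

_REQUIRED = {"sample_id", "group", "gene", "ct"}


def _validate(table: pd.DataFrame, housekeeping: str) -> pd.DataFrame:
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ValueError(f"CT table is missing columns {sorted(missing)}")
    table = table.copy()
    bad = ~np.isfinite(table["ct"]) | (table["ct"] <= 0)
    if bad.any():
        logger.warning("excluding %d undetermined/invalid CT wells",
                       int(bad.sum()))
        table = table.loc[~bad]
    hk_samples = set(table.loc[table["gene"] == housekeeping, "sample_id"])
    missing_hk = set(table["sample_id"]) - hk_samples
    if missing_hk:
        raise ValueError(
            f"samples missing housekeeping ({housekeeping}) CT: "
            f"{sorted(missing_hk)}")
    return table


def delta_ct(table: pd.DataFrame, housekeeping: str = "HPRT") -> pd.DataFrame:
    """Per-sample, per-gene ΔCT = mean ct(gene) − mean ct(housekeeping).

    Technical replicates are averaged on the CT scale first. The
    housekeeping gene itself yields ΔCT = 0.

    Returns columns: sample_id, group, gene, delta_ct.
    """
    table = _validate(table, housekeeping)
    means = (table.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
             .mean().reset_index())
    hk = means.loc[means["gene"] == housekeeping,
                   ["sample_id", "ct"]].rename(columns={"ct": "ct_hk"})
    out = means.merge(hk, on="sample_id", how="left")
    out["delta_ct"] = out["ct"] - out["ct_hk"]
    return out[["sample_id", "group", "gene", "delta_ct"]]


def fold_induction(delta_cts: pd.DataFrame,
                   control_group: str = "Saline") -> pd.DataFrame:
    """Per-sample fold induction 2^-(ΔCT − control-group mean ΔCT).

    Returns columns: sample_id, group, gene, delta_ct,
    control_mean_delta_ct, delta_delta_ct, fold.
    """
    if "delta_ct" not in delta_cts.columns:
        raise ValueError("expected output of delta_ct()")
    out = delta_cts.copy()
    ctrl = out.loc[out["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    ref = (ctrl.groupby("gene")["delta_ct"].mean()
           .rename("control_mean_delta_ct"))
    missing = set(out["gene"]) - set(ref.index)
    if missing:
        raise ValueError(
            f"control group has no measurements for genes {sorted(missing)}")
    out = out.merge(ref, on="gene", how="left")
    out["delta_delta_ct"] = out["delta_ct"] - out["control_mean_delta_ct"]
    out["fold"] = np.exp2(-out["delta_delta_ct"])
    return out


def ddct_analysis(table: pd.DataFrame,
                  housekeeping: str = "HPRT",
                  control_group: str = "Saline") -> pd.DataFrame:
    """Full 2^-ΔΔCT analysis of a tidy CT table; excludes the housekeeping
    gene from the output (its fold is identically 1)."""
    folds = fold_induction(delta_ct(table, housekeeping), control_group)
    return folds.loc[folds["gene"] != housekeeping].reset_index(drop=True)
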
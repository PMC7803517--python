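"""Relative quantification of qPCR data by the 2^-ΔΔCt method.

ΔCt = mean-over-replicates Ct(target) − mean Ct(reference);
ΔΔCt = ΔCt − mean ΔCt of the calibrator group;
relative expression = 2^(−ΔΔCt).

Replicates are averaged on the Ct scale before differencing by default; the
per-replicate alternative aggregates 2^-ΔΔCt values by geometric mean, which
is identical when replicate counts are balanced.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CT_COLUMNS = [
    "sample_id", "group", "target_gene", "reference_gene",
    "ct_target", "ct_reference", "replicate",
]


def _check_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {', '.join(missing)}")
    if (table["ct_target"] <= 0).any() or (table["ct_reference"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per (target_gene, sample): ΔCt with replicate Ct values averaged first."""
    table = _check_ct_table(table)
    grouped = table.groupby(["target_gene", "sample_id"], sort=True)
    rows = []
    for (gene, sample), chunk in grouped:
        if chunk["ct_reference"].isna().any():
            raise ValueError(f"missing reference Ct for sample {sample!r}")
        rows.append(
            {
                "target_gene": gene,
                "sample_id": sample,
                "group": chunk["group"].iloc[0],
                "delta_ct": chunk["ct_target"].mean() - chunk["ct_reference"].mean(),
                "n_replicates": len(chunk),
            }
        )
    return pd.DataFrame(rows)


def delta_delta_ct(
    table: pd.DataFrame,
    calibrator_group: str = "normal",
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Relative expression 2^-ΔΔCt per (gene, sample).

    The calibrator is each gene's mean ΔCt over the calibrator group, so a
    sample identical to the calibrator mean reports relative expression 1.
    ``per_replicate=True`` computes 2^-ΔΔCt per replicate and aggregates by
    geometric mean.
    """
    table = _check_ct_table(table)
    if not (table["group"] == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    if per_replicate:
        rep = table.copy()
        rep["delta_ct"] = rep["ct_target"] - rep["ct_reference"]
        cal = rep[rep["group"] == calibrator_group].groupby("target_gene")["delta_ct"].mean()
        rep = rep.join(cal.rename("cal_delta_ct"), on="target_gene")
        rep["rel_expr"] = 2.0 ** -(rep["delta_ct"] - rep["cal_delta_ct"])
        agg = rep.groupby(["target_gene", "sample_id"], sort=True).agg(
            group=("group", "first"),
            relative_expression=("rel_expr", lambda v: float(stats.gmean(v))),
        )
        out = agg.reset_index()
        out["delta_delta_ct"] = -np.log2(out["relative_expression"])
        return out[["target_gene", "sample_id", "group", "delta_delta_ct", "relative_expression"]]
    dct = delta_ct(table)
    cal = dct[dct["group"] == calibrator_group].groupby("target_gene")["delta_ct"].mean()
    missing = set(dct["target_gene"]) - set(cal.index)
    if missing:
        raise ValueError(f"no calibrator samples for gene {sorted(missing)[0]!r}")
    dct = dct.join(cal.rename("cal_delta_ct"), on="target_gene")
    dct["delta_delta_ct"] = dct["delta_ct"] - dct["cal_delta_ct"]
    dct["relative_expression"] = 2.0 ** -dct["delta_delta_ct"]
    return dct[["target_gene", "sample_id", "group", "delta_delta_ct", "relative_expression"]]


def group_comparison(
    table: pd.DataFrame,
    group_a: str = "keloid",
    group_b: str = "normal",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test on per-sample ΔCt values, per target gene."""
    dct = delta_ct(_check_ct_table(table))
    rows = []
    for gene, chunk in dct.groupby("target_gene", sort=True):
        a = chunk.loc[chunk["group"] == group_a, "delta_ct"]
        b = chunk.loc[chunk["group"] == group_b, "delta_ct"]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 samples per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "target_gene": gene,
                "mean_delta_ct_a": a.mean(),
                "mean_delta_ct_b": b.mean(),
                "log2_ratio": b.mean() - a.mean(),
                "tstat": float(t),
                "pvalue": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
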
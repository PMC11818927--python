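"""Statistics for the wet-lab validation experiments.

Relative qPCR quantification by 2^-ddCt against a calibrator group,
dual-luciferase firefly/Renilla normalization relative to the mimic
control, protein-normalized glucose production, and the two-group t-test /
one-way ANOVA comparisons with the conventional star flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def ddct(ct_table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per-sample relative expression 2^-ddCt.

    ``ct_table`` columns: sample_id, group, target_gene, target_ct,
    reference_gene, reference_ct. dCt = Ct_target - Ct_reference; ddCt is
    taken against the mean dCt of the calibrator group per target gene
    (amplification efficiency fixed at 2). The calibrator group's
    geometric mean expression is 1 by construction.
    """
    required = {"sample_id", "group", "target_gene", "target_ct",
                "reference_gene", "reference_ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if ct_table["reference_ct"].isna().any():
        bad = ct_table.loc[ct_table["reference_ct"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"missing reference Ct for sample {bad!r}")
    if ct_table["target_ct"].isna().any():
        bad = ct_table.loc[ct_table["target_ct"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"missing target Ct for sample {bad!r}")

    out = ct_table.copy()
    out["dct"] = out["target_ct"] - out["reference_ct"]
    frames = []
    for gene, sub in out.groupby("target_gene", sort=False):
        cal = sub.loc[sub["group"] == calibrator, "dct"]
        if cal.empty:
            raise ValueError(f"no calibrator samples ({calibrator!r}) for "
                             f"target {gene!r}")
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - cal.mean()
        sub["relative_expression"] = 2.0 ** (-sub["ddct"])
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def luciferase_relative_activity(table: pd.DataFrame) -> pd.DataFrame:
    """Firefly/Renilla activity normalized to each construct's mimic control.

    ``table`` columns: construct, treatment, firefly, renilla. The mean
    relative activity of every construct's control wells is 1.
    """
    required = {"construct", "treatment", "firefly", "renilla"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"luciferase table missing columns {sorted(missing)}")
    if (table["renilla"] <= 0).any():
        raise ValueError("non-positive Renilla signal")
    out = table.copy()
    out["ratio"] = out["firefly"] / out["renilla"]
    frames = []
    for construct, sub in out.groupby("construct", sort=False):
        control = sub.loc[sub["treatment"] == "mimic_control", "ratio"]
        if control.empty:
            raise ValueError(f"construct {construct!r} has no mimic_control wells")
        sub = sub.copy()
        sub["relative_activity"] = sub["ratio"] / control.mean()
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def glucose_output(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-normalized glucose production plus per-group mean +- SD.

    ``table`` columns: group, glucose_raw, protein (protein must be > 0).
    """
    required = {"group", "glucose_raw", "protein"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"glucose table missing columns {sorted(missing)}")
    if (table["protein"] <= 0).any():
        raise ValueError("non-positive protein content")
    out = table.copy()
    out["glucose_normalized"] = out["glucose_raw"] / out["protein"]
    summary = (
        out.groupby("group", sort=False)["glucose_normalized"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out, summary


def significance_flag(p: float) -> str:
    """Conventional star notation: ** for p < 0.01, * for p < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_compare(values, labels, equal_var: bool = True) -> dict:
    """Two groups -> two-sided t-test; more -> one-way ANOVA.

    Returns a dict with test name, statistic, p-value and the star flag.
    Every group needs at least two values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, arr in zip(pd.unique(labels), groups):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if len(groups) == 2:
        statistic, p = stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        test = "t-test"
    else:
        statistic, p = stats.f_oneway(*groups)
        test = "anova"
    p = float(p) if np.isfinite(p) else 1.0
    return {
        "test": test,
        "statistic": float(statistic) if np.isfinite(statistic) else 0.0,
        "pvalue": p,
        "flag": significance_flag(p),
    }
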
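"""Tissue-specificity scoring of miRNA expression profiles.

Two complementary metrics over per-tissue mean expression:

* **TSI** (tissue-specificity index): ``sum_i (1 - x_i / x_max) / (N - 1)``
  over N tissues — 0 for a perfectly uniform profile, 1 for expression
  confined to a single tissue. Profiles with TSI < 0.15 are called
  housekeeping, > 0.85 tissue-specific, anything else (boundaries
  included) nonspecific.
* **TSS** (tissue-specificity score): an entropy-based similarity between
  the expression distribution p and the indicator pattern e_t of being
  expressed only in tissue t, ``TSS_t = 1 - sqrt(JSD(p, e_t))`` with the
  Jensen-Shannon divergence taken in bits. TSS_t = 1 iff p = e_t.

A miRNA called tissue-specific is assigned the tissue with the highest
TSS (ties broken by lexicographic tissue name). TSI is computed three
ways — prenatal samples only, postnatal samples only, and all samples —
to expose stage effects on specificity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TSI_HOUSEKEEPING = 0.15
TSI_SPECIFIC = 0.85


def tsi(x) -> float:
    """Tissue-specificity index of a per-tissue mean expression vector.

    Returns NaN (undefined) for an all-zero vector.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (len(x) - 1))


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits (bounded by 1)."""
    m = 0.5 * (p + q)
    return _entropy_bits(m) - 0.5 * (_entropy_bits(p) + _entropy_bits(q))


def tss(p, tissue_index: int) -> float:
    """Tissue-specificity score of distribution ``p`` toward one tissue."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("profile entries must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"profile must sum to 1, got {p.sum()}")
    e = np.zeros_like(p)
    e[tissue_index] = 1.0
    d = max(jsd_bits(p, e), 0.0)
    return float(1.0 - np.sqrt(d))


def categorize(value: float) -> str:
    """housekeeping | tissue_specific | nonspecific (boundaries nonspecific)."""
    if np.isnan(value):
        return "nonspecific"
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"TSI must be in [0, 1], got {value}")
    if value < TSI_HOUSEKEEPING:
        return "housekeeping"
    if value > TSI_SPECIFIC:
        return "tissue_specific"
    return "nonspecific"


def assign_tissue(tss_by_tissue: pd.Series) -> str:
    """Tissue with the highest TSS; exact ties go to the lexicographically
    smallest tissue name."""
    scores = tss_by_tissue.dropna()
    if scores.empty:
        raise ValueError("all TSS values undefined")
    best = scores.max()
    return sorted(scores.index[scores == best])[0]


# ---------------------------------------------------------------------------
# matrix-level driver

def tissue_means(
    expr: pd.DataFrame, manifest: pd.DataFrame, stage: str | None = None
) -> pd.DataFrame:
    """miRNA x tissue mean expression, optionally within one stage."""
    sub = manifest if stage is None else manifest[manifest["stage"] == stage]
    if sub["tissue"].nunique() < 2:
        raise ValueError("need >= 2 tissues to score specificity")
    cols = [s for s in sub["sample_id"] if s in expr.columns]
    groups = dict(zip(sub["sample_id"], sub["tissue"]))
    return expr[cols].T.groupby(lambda s: groups[s]).mean().T


def tsi_variants(
    expr: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per-miRNA TSI from prenatal-only, postnatal-only and all samples."""
    out = {}
    for name, stage in (("tsi_prenatal", "prenatal"),
                        ("tsi_postnatal", "postnatal"),
                        ("tsi_all", None)):
        means = tissue_means(expr, manifest, stage)
        out[name] = means.apply(tsi, axis=1)
    return pd.DataFrame(out)[["tsi_all", "tsi_prenatal", "tsi_postnatal"]]


def score_specificity(
    expr: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Full specificity table: TSI variants, per-tissue TSS, category,
    assigned tissue (``none`` unless the miRNA is called tissue-specific)."""
    variants = tsi_variants(expr, manifest)
    means = tissue_means(expr, manifest, None)
    tissues = list(means.columns)
    profile = means.div(means.sum(axis=1), axis=0)

    tss_table = pd.DataFrame(index=means.index, columns=tissues, dtype=float)
    for mid in means.index:
        p = profile.loc[mid].to_numpy()
        if np.isnan(p).any():
            continue
        for j, t in enumerate(tissues):
            tss_table.loc[mid, t] = tss(p, j)

    result = variants.copy()
    for t in tissues:
        result[f"tss_{t}"] = tss_table[t]
    result["category"] = result["tsi_all"].map(categorize)
    assigned = []
    for mid in result.index:
        if result.loc[mid, "category"] == "tissue_specific":
            assigned.append(assign_tissue(tss_table.loc[mid]))
        else:
            assigned.append("none")
    result["assigned_tissue"] = assigned
    return result
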
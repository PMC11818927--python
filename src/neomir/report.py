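"""Machine-readable census tables and the end-to-end pipeline report.

All percentages are 100 * numerator / denominator rounded half-up to two
decimals; rendering trims trailing zeros ("53.14" but "13.9", "0.1").
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

CONTEXT_ORDER = ("intronic", "intergenic", "exonic", "intron_exon")
CATEGORY_ORDER = ("tissue_specific", "nonspecific", "housekeeping")


def percent(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals."""
    if denominator == 0:
        return float("nan")
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_percent(value: float) -> str:
    """Render a percentage with trailing zeros trimmed (13.9 not 13.90)."""
    if np.isnan(value):
        return "NA"
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return text if text else "0"


# ---------------------------------------------------------------------------
# census tables

def class_census_table(census: pd.DataFrame) -> pd.DataFrame:
    """Add a Total row and the mature-share percentage to an arm census."""
    table = census.copy()
    total = table.sum(axis=0)
    table.loc["total"] = total
    table["pct_matures"] = [
        percent(v, total["matures"]) for v in table["matures"]
    ]
    return table


def de_count_table(de_counts: dict[str, int]) -> pd.DataFrame:
    """Per-tissue DE event counts with their total."""
    table = pd.DataFrame(
        {"n_de": pd.Series(de_counts, dtype=int)}
    ).rename_axis("tissue")
    table.loc["total"] = table["n_de"].sum()
    return table


def overlap_table(counts_by_k: dict[int, int]) -> pd.DataFrame:
    """DE-overlap distribution with unique total and per-k percentages."""
    ks = sorted(counts_by_k)
    total = sum(counts_by_k.values())
    return pd.DataFrame(
        {
            "n_tissues": ks,
            "n_mirnas": [counts_by_k[k] for k in ks],
            "pct": [percent(counts_by_k[k], total) for k in ks],
        }
    )


def context_table(context_counts: dict[str, int]) -> pd.DataFrame:
    """Genomic-context counts with percentages of the precursor total."""
    total = sum(context_counts.values())
    labels = [c for c in CONTEXT_ORDER if c in context_counts]
    labels += [c for c in context_counts if c not in labels]
    return pd.DataFrame(
        {
            "context": labels,
            "n_precursors": [context_counts[c] for c in labels],
            "pct": [percent(context_counts[c], total) for c in labels],
        }
    )


def specificity_census(category_counts: dict[str, int]) -> pd.DataFrame:
    total = sum(category_counts.values())
    labels = [c for c in CATEGORY_ORDER if c in category_counts]
    labels += [c for c in category_counts if c not in labels]
    return pd.DataFrame(
        {
            "category": labels,
            "n_mirnas": [category_counts[c] for c in labels],
            "pct": [percent(category_counts[c], total) for c in labels],
        }
    )


def summarize_tables(
    class_census: pd.DataFrame,
    de_counts: dict[str, int],
    overlap_counts: dict[int, int],
    context_counts: dict[str, int],
    category_counts: dict[str, int],
) -> dict[str, pd.DataFrame]:
    """The four census tables (plus specificity) with their percentages."""
    return {
        "classes": class_census_table(class_census),
        "de_counts": de_count_table(de_counts),
        "overlap": overlap_table(overlap_counts),
        "contexts": context_table(context_counts),
        "specificity": specificity_census(category_counts),
    }


# ---------------------------------------------------------------------------
# report assembly and validation

def config_hash(config) -> str:
    payload = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_percent_block(counts: dict, total: float, pcts: dict, where: str):
    for key, value in pcts.items():
        expected = percent(counts[key], total)
        if not (np.isnan(value) and np.isnan(expected)) and value != expected:
            raise AssertionError(
                f"{where}: percentage for {key} is {value}, expected {expected}"
            )


def validate_report(report: dict) -> None:
    """Internal consistency of every count/percentage in a pipeline report."""
    ctx = report["genomic_context"]
    if sum(ctx["counts"].values()) != ctx["total"]:
        raise AssertionError("genomic_context counts do not sum to total")
    _check_percent_block(ctx["counts"], ctx["total"], ctx["pct"], "genomic_context")

    ann = report["annotation"]
    if sum(ann["matures_by_class"].values()) != ann["n_matures"]:
        raise AssertionError("class counts do not sum to mature total")
    if sum(ann["precursors_by_class"].values()) != ann["n_precursors"]:
        raise AssertionError("precursor class counts do not sum to total")

    spec = report["specificity"]
    if sum(spec["counts"].values()) != spec["n_scored"]:
        raise AssertionError("specificity categories do not partition miRNAs")
    _check_percent_block(spec["counts"], spec["n_scored"], spec["pct"],
                         "specificity")

    ov = report["overlap"]
    if sum(ov["counts"].values()) != ov["total_unique"]:
        raise AssertionError("overlap counts do not sum to unique DE total")
    _check_percent_block(
        {int(k): v for k, v in ov["counts"].items()},
        ov["total_unique"],
        {int(k): v for k, v in ov["pct"].items()},
        "overlap",
    )

    de = report["differential_expression"]
    if sum(de["per_tissue"].values()) != de["total_events"]:
        raise AssertionError("per-tissue DE counts do not sum to event total")


def report_to_json(report: dict, path) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, default=default)
        handle.write("\n")
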
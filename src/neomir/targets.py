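"""Cross-tissue DE structure, seed-based target prediction, and networks.

Covers: the distribution of DE miRNAs over the number of tissues they are
DE in; conservation of up/down direction across tissues; the chi-square
association between tissue specificity and differential expression;
canonical seed-site scanning of 3'UTRs (8mer, 7mer-m8, 7mer-A1);
hypergeometric over-representation of gene sets; and the miRNA-mRNA
repression network (edges require a predicted site and opposite
directions in the same tissue).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import normalize_seq, revcomp
from .de import bh_fdr

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_SITE_PRIORITY = {t: i for i, t in enumerate(SITE_TYPES)}


# ---------------------------------------------------------------------------
# DE overlap and direction conservation

@dataclass
class OverlapDistribution:
    """Count of miRNAs DE in exactly k tissues, k = 1..n_tissues."""

    counts: dict[int, int]
    total_unique: int

    def percentage(self, k: int) -> float:
        if self.total_unique == 0:
            return 0.0
        return 100.0 * self.counts.get(k, 0) / self.total_unique


def overlap_distribution(de_sets: dict[str, set[str]]) -> OverlapDistribution:
    """Bucket DE miRNAs by the exact number of tissues calling them DE."""
    membership: Counter = Counter()
    for _tissue, mirnas in de_sets.items():
        for m in mirnas:
            membership[m] += 1
    counts = Counter(membership.values())
    n_tissues = len(de_sets)
    full = {k: counts.get(k, 0) for k in range(1, max(n_tissues, 1) + 1)}
    return OverlapDistribution(counts=full, total_unique=len(membership))


def direction_conservation(de_table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Direction-conservation calls and the signed log2FC heatmap table.

    ``de_table`` is the long per-(miRNA, tissue) DE table. A miRNA is
    conserved when it is DE in at least two tissues with the same direction
    in every tissue where it is DE; the heatmap holds signed log2FC where
    DE and NaN elsewhere.
    """
    de_rows = de_table[de_table["is_de"]]
    heat = de_rows.pivot(index="mirna_id", columns="tissue", values="log2fc")
    conserved = {}
    for mid, sub in de_rows.groupby("mirna_id"):
        directions = set(sub["direction"])
        conserved[mid] = len(sub) >= 2 and len(directions) == 1
    return pd.Series(conserved, dtype=bool), heat


def specificity_enrichment(
    de_flags: pd.Series, specific_flags: pd.Series
) -> tuple[np.ndarray, float, float]:
    """2x2 chi-square (1 df, no continuity correction) of DE vs specificity.

    Both inputs are boolean Series over the same miRNA universe. Returns
    (observed table, statistic, p). An all-zero margin makes the statistic
    undefined (NaN).
    """
    idx = de_flags.index
    if not idx.equals(specific_flags.index):
        specific_flags = specific_flags.reindex(idx)
        if specific_flags.isna().any():
            raise ValueError("flag series cover different miRNA universes")
    de = de_flags.to_numpy(bool)
    sp = specific_flags.to_numpy(bool)
    table = np.array(
        [
            [np.sum(de & sp), np.sum(de & ~sp)],
            [np.sum(~de & sp), np.sum(~de & ~sp)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return table, float("nan"), float("nan")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    statistic = float(np.sum((table - expected) ** 2 / expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return table, statistic, p


# ---------------------------------------------------------------------------
# canonical seed-site prediction

@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    gene_id: str
    start: int  # 0-based position of the site in the UTR
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1


def seed_match_patterns(mirna_seq: str) -> dict[str, str]:
    """UTR motifs for the three canonical site classes of one miRNA.

    With the miRNA written 5'->3', a 7mer-m8 site is the exact reverse
    complement of miRNA positions 2-8; a 7mer-A1 site is the reverse
    complement of positions 2-7 followed by an A in the target; an 8mer
    satisfies both.
    """
    seq = normalize_seq(mirna_seq)
    if len(seq) < 8:
        raise ValueError("miRNA shorter than 8 nt has no seed")
    match_2_8 = revcomp(seq[1:8])  # 7 nt
    match_2_7 = revcomp(seq[1:7])  # 6 nt
    return {
        "8mer": match_2_8 + "A",
        "7mer-m8": match_2_8,
        "7mer-A1": match_2_7 + "A",
    }


def predict_targets(
    mirna_id: str,
    mirna_seq: str,
    utrs: dict[str, str],
) -> list[TargetSite]:
    """Scan 3'UTRs for canonical seed sites of one miRNA.

    Overlapping matches of several classes at one locus are reported once,
    as the strongest class (8mer > 7mer-m8 > 7mer-A1). UTRs shorter than
    8 nt yield no sites.
    """
    patterns = seed_match_patterns(mirna_seq)
    sites: list[TargetSite] = []
    for gene_id, utr in utrs.items():
        seq = normalize_seq(utr)
        if len(seq) < 8:
            continue
        claimed: dict[int, TargetSite] = {}
        for site_type in SITE_TYPES:  # strongest class first
            motif = patterns[site_type]
            start = seq.find(motif)
            while start >= 0:
                # anchor every site at the start of the 7mer-m8 core; the
                # 7mer-A1 motif starts one base into that core
                core_start = start if site_type != "7mer-A1" else start - 1
                if core_start not in claimed:
                    claimed[core_start] = TargetSite(
                        mirna_id, gene_id, start, site_type
                    )
                start = seq.find(motif, start + 1)
        sites.extend(sorted(claimed.values(), key=lambda s: s.start))
    return sites


def predict_all_targets(
    mirna_seqs: dict[str, str], utrs: dict[str, str]
) -> pd.DataFrame:
    rows = [
        (s.mirna_id, s.gene_id, s.start, s.site_type)
        for mid, seq in mirna_seqs.items()
        for s in predict_targets(mid, seq, utrs)
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "start",
                                       "site_type"])


# ---------------------------------------------------------------------------
# repression network

@dataclass(frozen=True)
class NetworkEdge:
    mirna_id: str
    gene_id: str
    mirna_direction: str
    gene_direction: str
    tissue: str


def build_network(
    de_table: pd.DataFrame,
    gene_directions: pd.DataFrame,
    target_pairs: pd.DataFrame,
) -> list[NetworkEdge]:
    """miRNA-mRNA edges: predicted site + opposite directions in a tissue.

    ``gene_directions`` has columns gene_id / tissue / direction;
    ``target_pairs`` has columns mirna_id / gene_id.
    """
    pairs = set(zip(target_pairs["mirna_id"], target_pairs["gene_id"]))
    gene_dir = {
        (r.gene_id, r.tissue): r.direction for r in gene_directions.itertuples()
    }
    edges = []
    for row in de_table[de_table["is_de"]].itertuples():
        for (mid, gid) in pairs:
            if mid != row.mirna_id:
                continue
            gdir = gene_dir.get((gid, row.tissue))
            if gdir is None or gdir == row.direction:
                continue
            edges.append(
                NetworkEdge(mid, gid, row.direction, gdir, row.tissue)
            )
    return sorted(edges, key=lambda e: (e.tissue, e.mirna_id, e.gene_id))


# ---------------------------------------------------------------------------
# gene-set over-representation

def geneset_enrichment(
    gene_list: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    p is the upper-tail probability of drawing at least the observed
    overlap when sampling ``len(gene_list)`` genes from the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    extra = gene_list - universe
    if extra:
        raise ValueError(f"gene list not contained in universe: {sorted(extra)[:3]}")
    M = len(universe)
    N = len(gene_list)
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        k = len(gene_list & in_universe)
        n = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((name, n, k, p))
    table = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap",
                                        "pvalue"])
    table["fdr"] = bh_fdr(table["pvalue"]) if len(table) else []
    return table.sort_values("pvalue", kind="stable").reset_index(drop=True)
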
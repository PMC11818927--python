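"""Annotation-class, arm-of-origin and genomic-context assignment.

A mature miRNA is *known* when its full sequence exactly matches a
same-species reference entry, *conserved* when its seed (nucleotides 2-8)
matches the seed of an other-mammal reference mature, and *novel* otherwise
(precedence known > conserved > novel). Precursors are classified by where
they fall relative to gene models: intergenic, exonic, intronic, or
straddling an exon-intron junction of one gene.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .containers import (
    GeneModel,
    GenomicInterval,
    MatureMiRNA,
    PrecursorMiRNA,
    normalize_seq,
)

SEED_START, SEED_END = 1, 8  # python slice of positions 2-8 (1-based)


def seed_of(sequence: str, start: int = SEED_START, end: int = SEED_END) -> str:
    """Seed region of a mature miRNA: positions 2-8 (1-based), T-normalized."""
    seq = normalize_seq(sequence)
    if len(seq) < end:
        raise ValueError(f"sequence of length {len(seq)} has no {end}-nt prefix")
    return seq[start:end]


def classify_mirna(
    sequence: str,
    same_species_ref: dict[str, str] | list[str],
    other_species_ref: dict[str, str] | list[str],
) -> str:
    """known | conserved | novel for one candidate mature sequence."""
    seq = normalize_seq(sequence)
    same = same_species_ref.values() if isinstance(same_species_ref, dict) else same_species_ref
    other = other_species_ref.values() if isinstance(other_species_ref, dict) else other_species_ref
    same_seqs = {normalize_seq(s) for s in same}
    if seq in same_seqs:
        return "known"
    other_seeds = {seed_of(s) for s in other if len(normalize_seq(s)) >= SEED_END}
    if seed_of(seq) in other_seeds:
        return "conserved"
    return "novel"


def classify_all(
    matures: list[MatureMiRNA],
    same_species_ref: dict[str, str],
    other_species_ref: dict[str, str],
) -> dict[str, str]:
    return {
        m.id: classify_mirna(m.sequence, same_species_ref, other_species_ref)
        for m in matures
    }


def arm_census(
    precursors: list[PrecursorMiRNA],
    matures: list[MatureMiRNA],
    classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-class counts of precursors producing 5p-only / 3p-only / both arms.

    ``classes`` maps mature id -> class; a precursor takes the class of its
    matures (which agree by construction). Returns a table indexed by class
    with columns precursors / mirna_5p / mirna_3p / both / matures.
    """
    pre_ids = {p.id for p in precursors}
    arms_by_pre: dict[str, set[str]] = {}
    class_by_pre: dict[str, str] = {}
    n_matures: Counter = Counter()
    for m in matures:
        if m.precursor_id not in pre_ids:
            raise ValueError(f"mature {m.id} references unknown precursor "
                             f"{m.precursor_id}")
        arms_by_pre.setdefault(m.precursor_id, set()).add(m.arm)
        cls = (classes or {}).get(m.id, m.annotation_class or "unclassified")
        class_by_pre[m.precursor_id] = cls
        n_matures[cls] += 1

    rows: dict[str, Counter] = {}
    for pid, arms in arms_by_pre.items():
        cls = class_by_pre[pid]
        row = rows.setdefault(cls, Counter())
        row["precursors"] += 1
        if arms == {"5p"}:
            row["mirna_5p"] += 1
        elif arms == {"3p"}:
            row["mirna_3p"] += 1
        else:
            row["both"] += 1
    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    for col in ("precursors", "mirna_5p", "mirna_3p", "both"):
        if col not in table:
            table[col] = 0
    table = table[["precursors", "mirna_5p", "mirna_3p", "both"]]
    table["matures"] = pd.Series(n_matures)
    order = [c for c in ("known", "conserved", "novel") if c in table.index]
    order += [c for c in table.index if c not in order]
    return table.loc[order]


# ---------------------------------------------------------------------------
# genomic context

def _gene_context(interval: GenomicInterval, gene: GeneModel) -> str | None:
    """Context of an interval w.r.t. one gene, or None when not overlapping."""
    if not gene.span.overlaps(interval):
        return None
    in_exon = any(
        interval.start < e and s < interval.end for (s, e) in gene.exons
    )
    in_intron = any(
        interval.start < e and s < interval.end for (s, e) in gene.introns
    )
    # interior placements reduce to containment; a precursor hanging off the
    # gene edge is called by the feature it actually overlaps
    if in_exon and in_intron:
        return "intron_exon"
    return "exonic" if in_exon else "intronic"


_CONTEXT_PRIORITY = {"intron_exon": 0, "exonic": 1, "intronic": 2}


def genomic_context(
    interval: GenomicInterval, genes: list[GeneModel]
) -> str:
    """intronic | exonic | intergenic | intron_exon for one precursor.

    Strand is ignored; when the precursor overlaps several genes, each gene
    is classified separately and the call with the highest priority
    (intron_exon > exonic > intronic) is reported.
    """
    calls = []
    for gene in genes:
        ctx = _gene_context(interval, gene)
        if ctx is not None:
            calls.append(ctx)
    if not calls:
        return "intergenic"
    return min(calls, key=lambda c: _CONTEXT_PRIORITY[c])


def context_census(
    precursors: list[PrecursorMiRNA], genes: list[GeneModel]
) -> tuple[dict[str, str], Counter]:
    """Assign genomic context to every precursor; return calls and counts."""
    calls: dict[str, str] = {}
    for p in precursors:
        if p.interval is None:
            raise ValueError(f"precursor {p.id} has no genomic interval")
        calls[p.id] = genomic_context(p.interval, genes)
    counts = Counter(calls.values())
    for label in ("intronic", "intergenic", "exonic", "intron_exon"):
        counts.setdefault(label, 0)
    return calls, counts
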
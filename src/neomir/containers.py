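"""Core in-memory objects shared across the pipeline.

The central object is :class:`CountMatrix`, an integer miRNA x sample table
whose per-sample library size is defined as the column sum of assigned reads.
Sequence records (:class:`MatureMiRNA`, :class:`PrecursorMiRNA`) carry
T-normalized DNA strings; genomic intervals are 0-based half-open internally
and converted to 1-based inclusive only at the disk boundary (GFF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CLASSES = ("known", "conserved", "novel")
VALID_CONTEXTS = ("intronic", "intergenic", "exonic", "intron_exon")

_RC = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T.

    All sequence comparison in the package happens in this single DNA
    alphabet, so mature "RNA" sequences and DNA references never diverge.
    """
    return seq.strip().upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA arm excised from a hairpin precursor."""

    id: str
    sequence: str
    precursor_id: str
    arm: str  # "5p" | "3p"
    annotation_class: str | None = None  # known | conserved | novel

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(
                f"mature {self.id}: length {len(self.sequence)} outside 18-26 nt"
            )

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (1-based, inclusive) of the mature sequence."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"malformed interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class PrecursorMiRNA:
    """A pre-miRNA hairpin with its genomic placement."""

    id: str
    sequence: str
    interval: GenomicInterval | None = None
    context: str | None = None  # intronic | intergenic | exonic | intron_exon

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if self.context is not None and self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown genomic context {self.context!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene as a sorted list of non-overlapping exons; introns are the gaps."""

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s, e) in exons:
            if s >= e:
                raise ValueError(f"gene {self.id}: malformed exon [{s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.id}: overlapping exons")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0][0], self.exons[-1][1], self.strand
        )


@dataclass
class CountMatrix:
    """Integer miRNA x sample read-count table.

    The per-sample library size is *defined* as the column sum of assigned
    reads, so it is exposed as a derived property rather than stored.
    """

    counts: pd.DataFrame  # rows = miRNA ids, columns = sample ids, int

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate miRNA ids in count matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (df.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = df.astype(np.int64)

    @property
    def mirnas(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)].copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class TruthTables:
    """Ground truth emitted by the synthetic generator, for recovery tests."""

    true_de: dict[tuple[str, str], float] = field(default_factory=dict)
    #: miRNA id -> tissue name, or "none"
    true_specific: dict[str, str] = field(default_factory=dict)
    true_targets: dict[str, set[str]] = field(default_factory=dict)
    true_class: dict[str, str] = field(default_factory=dict)
    true_context: dict[str, str] = field(default_factory=dict)

    def validate_against(
        self, matures: list[MatureMiRNA], precursors: list[PrecursorMiRNA],
        gene_ids: set[str],
    ) -> None:
        mat_ids = {m.id for m in matures}
        pre_ids = {p.id for p in precursors}
        for (mid, _t) in self.true_de:
            if mid not in mat_ids:
                raise ValueError(f"true_de references unknown miRNA {mid}")
        for mid in self.true_specific:
            if mid not in mat_ids:
                raise ValueError(f"true_specific references unknown miRNA {mid}")
        for mid, genes in self.true_targets.items():
            if mid not in mat_ids:
                raise ValueError(f"true_targets references unknown miRNA {mid}")
            missing = genes - gene_ids
            if missing:
                raise ValueError(f"true_targets references unknown genes {missing}")
        for pid in self.true_context:
            if pid not in pre_ids:
                raise ValueError(f"true_context references unknown precursor {pid}")
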
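"""Raw small-RNA FASTQ to filtered miRNA count matrix.

Reads are adapter-trimmed, quality- and length-filtered, collapsed to
unique inserts, and assigned by direct matching against the mature miRNA
reference (optionally tolerating a few templated nucleotides of 3'-end
trimming/extension, the dominant isomiR mode). Inserts matching more than
one mature are discarded as ambiguous; the per-sample library size is the
total of assigned reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import io as _io
from .containers import CountMatrix, normalize_seq

DEFAULT_LENGTH_WINDOW = (18, 26)
DEFAULT_MIN_MEAN_QUALITY = 20.0
DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class CollapsedRead:
    """A unique insert sequence with its read multiplicity."""

    sequence: str
    multiplicity: int

    def __post_init__(self):
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise ValueError(f"invalid insert sequence {self.sequence!r}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class SampleQuantification:
    """Per-sample quantification output and bookkeeping tallies."""

    counts: dict[str, int]
    assigned: int
    ambiguous: int
    unmatched: int
    n_raw: int
    n_clean: int
    length_distribution: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# adapter trimming

def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    keep_untrimmed: bool = False,
) -> str | None:
    """Strip the 3' adapter from a read; return the insert or None.

    The first exact occurrence of the full adapter wins; otherwise the
    longest adapter prefix of length >= ``min_overlap`` found at the read's
    3' end is removed. Reads without any adapter evidence are dropped
    (returned as None) unless ``keep_untrimmed`` is set.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 5:
        raise ValueError(f"min_overlap must be >= 5, got {min_overlap}")
    pos = read.find(adapter)
    if pos >= 0:
        return read[:pos]
    for k in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return read if keep_untrimmed else None


# ---------------------------------------------------------------------------
# quality/length filter + collapse

def _mean_quality(qual: str) -> float:
    return float(np.mean(np.frombuffer(qual.encode(), dtype=np.uint8))) - 33.0


def clean_and_collapse(
    inserts: Iterable[tuple[str, str | None]],
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
) -> tuple[list[CollapsedRead], dict[int, float]]:
    """Filter (insert, quality) pairs and merge identical inserts.

    Inserts outside the length window or below the mean Phred quality are
    dropped; the length distribution is computed over retained inserts,
    weighted by multiplicity.
    """
    lo, hi = length_window
    if not (15 <= lo <= hi <= 35):
        raise ValueError(f"length window {length_window} outside [15, 35]")
    tally: dict[str, int] = {}
    for insert, qual in inserts:
        if not lo <= len(insert) <= hi:
            continue
        if qual is not None and _mean_quality(qual[: len(insert)]) < min_mean_quality:
            continue
        tally[insert] = tally.get(insert, 0) + 1
    collapsed = [CollapsedRead(seq, n) for seq, n in tally.items()]
    total = sum(tally.values())
    dist: dict[int, float] = {}
    for seq, n in tally.items():
        dist[len(seq)] = dist.get(len(seq), 0) + n
    if total:
        dist = {L: n / total for L, n in sorted(dist.items())}
    return collapsed, dist


# ---------------------------------------------------------------------------
# assignment against the mature reference

def build_variant_index(
    mature_ref: dict[str, str],
    three_prime_tolerance: int = 0,
    hairpins: dict[str, str] | None = None,
    mature_positions: dict[str, tuple[str, int]] | None = None,
) -> dict[str, set[str]]:
    """Map every acceptable insert sequence to the mature ids it matches.

    3'-trimmed variants come from the mature itself; 3'-extended variants
    require the hairpin template (extension bases are read off the
    precursor downstream of the mature).
    """
    if len(set(mature_ref)) != len(mature_ref):
        raise ValueError("duplicate mature ids")
    index: dict[str, set[str]] = {}

    def add(seq: str, mid: str) -> None:
        index.setdefault(seq, set()).add(mid)

    for mid, seq in mature_ref.items():
        seq = normalize_seq(seq)
        add(seq, mid)
        for t in range(1, three_prime_tolerance + 1):
            if len(seq) - t >= 15:
                add(seq[:-t], mid)
            if hairpins and mature_positions and mid in mature_positions:
                pre_id, off = mature_positions[mid]
                hp = normalize_seq(hairpins[pre_id])
                if off + len(seq) + t <= len(hp):
                    add(hp[off: off + len(seq) + t], mid)
    return index


def assign_reads(
    collapsed: Iterable[CollapsedRead],
    mature_ref: dict[str, str],
    three_prime_tolerance: int = 0,
    hairpins: dict[str, str] | None = None,
    mature_positions: dict[str, tuple[str, int]] | None = None,
) -> tuple[dict[str, int], int, int]:
    """Assign collapsed inserts to matures; return (counts, ambiguous, unmatched).

    An insert matching exactly one mature contributes its multiplicity to
    that miRNA; inserts matching several matures are discarded and tallied
    as ambiguous.
    """
    if not mature_ref:
        raise ValueError("empty mature reference")
    index = build_variant_index(mature_ref, three_prime_tolerance, hairpins,
                                mature_positions)
    counts = {mid: 0 for mid in mature_ref}
    ambiguous = 0
    unmatched = 0
    for read in collapsed:
        hits = index.get(read.sequence)
        if hits is None:
            unmatched += read.multiplicity
        elif len(hits) == 1:
            counts[next(iter(hits))] += read.multiplicity
        else:
            ambiguous += read.multiplicity
    return counts, ambiguous, unmatched


# ---------------------------------------------------------------------------
# per-sample driver and matrix assembly

def quantify_sample(
    records: Iterable[tuple[str, str, str]],
    mature_ref: dict[str, str],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    three_prime_tolerance: int = 0,
    hairpins: dict[str, str] | None = None,
    mature_positions: dict[str, tuple[str, int]] | None = None,
) -> SampleQuantification:
    """FASTQ records -> assigned counts for one sample."""
    n_raw = 0

    def trimmed() -> Iterator[tuple[str, str]]:
        nonlocal n_raw
        for _title, seq, qual in records:
            n_raw += 1
            insert = trim_adapter(seq.upper(), adapter, min_overlap)
            if insert:
                yield insert, qual

    collapsed, dist = clean_and_collapse(trimmed(), length_window,
                                         min_mean_quality)
    n_clean = sum(r.multiplicity for r in collapsed)
    counts, ambiguous, unmatched = assign_reads(
        collapsed, mature_ref, three_prime_tolerance, hairpins, mature_positions
    )
    return SampleQuantification(
        counts=counts,
        assigned=sum(counts.values()),
        ambiguous=ambiguous,
        unmatched=unmatched,
        n_raw=n_raw,
        n_clean=n_clean,
        length_distribution=dist,
    )


def quantify_samples(
    fastq_by_sample: dict[str, str | os.PathLike | Iterable[tuple[str, str, str]]],
    mature_ref: dict[str, str],
    adapter: str,
    **kwargs,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Quantify several samples into one CountMatrix plus a stats table.

    ``fastq_by_sample`` maps sample id to a FASTQ path or an iterable of
    (title, sequence, quality) records.
    """
    columns = {}
    stats = []
    for sample, source in fastq_by_sample.items():
        if isinstance(source, (str, os.PathLike)):
            records = _io.read_fastq(source)
        else:
            records = iter(source)
        q = quantify_sample(records, mature_ref, adapter, **kwargs)
        columns[sample] = q.counts
        stats.append((sample, q.n_raw, q.n_clean, q.assigned, q.ambiguous,
                      q.unmatched))
    counts = pd.DataFrame(columns, dtype=np.int64)
    counts = counts.loc[sorted(counts.index), list(fastq_by_sample)]
    stats_df = pd.DataFrame(
        stats, columns=["sample_id", "n_raw", "n_clean", "assigned",
                        "ambiguous", "unmatched"],
    )
    return CountMatrix(counts), stats_df


# ---------------------------------------------------------------------------
# detection filter and RPM

def detection_filter(
    cm: CountMatrix, min_count: int = 3, min_samples: int = 1
) -> CountMatrix:
    """Keep miRNAs with >= ``min_count`` reads in >= ``min_samples`` samples."""
    if min_count < 1 or min_samples < 1:
        raise ValueError("detection thresholds must be >= 1")
    keep = (cm.counts >= min_count).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep].copy())


def rpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Reads-per-million table: count / library size * 1e6 per sample."""
    lib = cm.library_sizes
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    return cm.counts / lib * 1e6
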
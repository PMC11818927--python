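"""Turn a count matrix into per-sample small-RNA FASTQ files.

Each clean read is the mature sequence (DNA alphabet) followed by the 3'
adapter, padded with random bases to a fixed raw length (reads longer than
the raw length are truncated). A configurable fraction of junk reads --
adapter dimers and <18 nt inserts -- is appended and tallied; there is no
base-call error by default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .. import io as _io
from ..containers import CountMatrix
from .config import SyntheticConfig

_BASES = np.array(list("ACGT"))


def _pad(rng: np.random.Generator, seq: str, length: int) -> str:
    if len(seq) >= length:
        return seq[:length]
    tail = "".join(_BASES[rng.integers(0, 4, size=length - len(seq))])
    return seq + tail


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _BASES[rng.integers(0, 4)].encode()
    return arr.tobytes().decode()


@dataclass
class ReadSet:
    """Synthesized reads for one sample plus the junk-read tally."""

    sample_id: str
    records: list[tuple[str, str, str]]
    n_clean: int
    n_junk: int


def synthesize_sample_reads(
    sample_id: str,
    counts: dict[str, int],
    mature_seqs: dict[str, str],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> ReadSet:
    """Build the read multiset for one sample (sizes equal the counts)."""
    missing = [m for m, c in counts.items() if c > 0 and m not in mature_seqs]
    if missing:
        raise ValueError(f"no mature sequence for miRNA {missing[0]!r}")
    qual_clean = "I" * config.read_length  # Q40
    records: list[tuple[str, str, str]] = []
    for mid in counts:
        c = counts[mid]
        if c <= 0:
            continue
        insert = mature_seqs[mid]
        for _ in range(c):
            seq = _mutate(rng, insert, config.base_error)
            read = _pad(rng, seq + config.adapter, config.read_length)
            records.append((f"{sample_id}:{len(records)}", read, qual_clean))
    n_clean = len(records)
    n_junk = round(config.junk_frac * n_clean)
    for j in range(n_junk):
        if rng.random() < 0.5:  # adapter dimer: empty insert
            read = _pad(rng, config.adapter + config.adapter, config.read_length)
        else:  # short insert (<18 nt)
            insert = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(8, 18)))])
            read = _pad(rng, insert + config.adapter, config.read_length)
        records.append((f"{sample_id}:junk:{j}", read, qual_clean))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return ReadSet(sample_id=sample_id, records=records, n_clean=n_clean,
                   n_junk=n_junk)


def synthesize_reads(
    counts: CountMatrix,
    mature_seqs: dict[str, str],
    config: SyntheticConfig,
    outdir: str | os.PathLike | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, ReadSet]:
    """Synthesize FASTQ reads for every sample of a count matrix.

    When ``outdir`` is given, one ``<sample_id>.fastq`` file per sample is
    written (Phred+33). Returns the in-memory read sets keyed by sample.
    """
    if rng is None:
        rng = config.rng(2)
    out: dict[str, ReadSet] = {}
    for sample in counts.samples:
        col = counts.counts[sample]
        readset = synthesize_sample_reads(
            sample, dict(col[col > 0]), mature_seqs, config, rng
        )
        out[sample] = readset
        if outdir is not None:
            os.makedirs(outdir, exist_ok=True)
            _io.write_fastq(os.path.join(outdir, f"{sample}.fastq"),
                            readset.records)
    return out
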
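"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; FASTQ reading uses Biopython's fast tuple
iterator and FASTQ writing is plain 4-line records (Phred+33). The gene
annotation is a GFF-like TSV with 1-based inclusive coordinates on disk,
converted to the 0-based half-open convention used in memory.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, GeneModel, TruthTables


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | os.PathLike, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) tuples from a Phred+33 FASTQ file."""
    with open(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(
    path: str | os.PathLike, records: Iterable[tuple[str, str, str]]
) -> None:
    """Write (title, sequence, quality) tuples as 4-line FASTQ records."""
    with open(path, "w") as handle:
        for title, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"record {title!r}: sequence/quality length mismatch")
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Gene annotation (GFF-like TSV, 1-based inclusive on disk)

_ANNOT_COLS = ["gene_id", "chrom", "strand", "feature", "start", "end"]


def write_gene_annotation(path: str | os.PathLike, genes: list[GeneModel]) -> None:
    rows = []
    for g in genes:
        for (s, e) in g.exons:
            # internal 0-based half-open -> disk 1-based inclusive
            rows.append((g.id, g.chrom, g.strand, "exon", s + 1, e))
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns {sorted(missing)}")
    genes = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        exons = [
            (int(r.start) - 1, int(r.end))  # disk 1-based inclusive -> half-open
            for r in sub.itertuples()
            if r.feature == "exon"
        ]
        genes.append(
            GeneModel(
                id=str(gene_id),
                chrom=str(sub.iloc[0]["chrom"]),
                strand=str(sub.iloc[0]["strand"]),
                exons=tuple(exons),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, ``name <tab> description <tab> genes...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for i, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {i + 1}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(path: str | os.PathLike, sets: dict[str, set[str]]) -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, name] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Sample manifest and count matrices (TSV)

MANIFEST_COLS = ["sample_id", "tissue", "stage", "replicate"]


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    missing = set(MANIFEST_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"manifest {path} has duplicate sample ids")
    bad = set(df["stage"]) - {"prenatal", "postnatal"}
    if bad:
        raise ValueError(f"manifest {path}: unknown stages {sorted(bad)}")
    return df


def write_manifest(path: str | os.PathLike, manifest: pd.DataFrame) -> None:
    manifest.loc[:, MANIFEST_COLS].to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_count_matrix(path: str | os.PathLike, cm: CountMatrix) -> None:
    cm.counts.rename_axis("mirna_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Truth tables (one TSV per table, stacked into a directory)

def write_truth_tables(outdir: str | os.PathLike, truth: TruthTables) -> None:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame(
        [(m, t, fc) for (m, t), fc in sorted(truth.true_de.items())],
        columns=["mirna_id", "tissue", "log2fc"],
    ).to_csv(os.path.join(outdir, "true_de.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_specific.items()), columns=["mirna_id", "tissue"]
    ).to_csv(os.path.join(outdir, "true_specific.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(m, g) for m, genes in sorted(truth.true_targets.items()) for g in sorted(genes)],
        columns=["mirna_id", "gene_id"],
    ).to_csv(os.path.join(outdir, "true_targets.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_class.items()), columns=["mirna_id", "class"]
    ).to_csv(os.path.join(outdir, "true_class.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.true_context.items()), columns=["precursor_id", "context"]
    ).to_csv(os.path.join(outdir, "true_context.tsv"), sep="\t", index=False)


def read_truth_tables(outdir: str | os.PathLike) -> TruthTables:
    outdir = str(outdir)
    de = pd.read_csv(os.path.join(outdir, "true_de.tsv"), sep="\t")
    spec = pd.read_csv(os.path.join(outdir, "true_specific.tsv"), sep="\t")
    targ = pd.read_csv(os.path.join(outdir, "true_targets.tsv"), sep="\t")
    clas = pd.read_csv(os.path.join(outdir, "true_class.tsv"), sep="\t")
    ctx = pd.read_csv(os.path.join(outdir, "true_context.tsv"), sep="\t")
    targets: dict[str, set[str]] = {}
    for r in targ.itertuples():
        targets.setdefault(r.mirna_id, set()).add(r.gene_id)
    return TruthTables(
        true_de={(r.mirna_id, r.tissue): float(r.log2fc) for r in de.itertuples()},
        true_specific=dict(zip(spec["mirna_id"], spec["tissue"])),
        true_targets=targets,
        true_class=dict(zip(clas["mirna_id"], clas["class"])),
        true_context=dict(zip(ctx["precursor_id"], ctx["context"])),
    )
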
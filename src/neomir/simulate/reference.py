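"""Generation of the synthetic miRNA reference world.

Produces, from one seeded configuration: mature and hairpin sequences with
known/conserved/novel class structure against a same-species and an
other-mammal reference, hairpins placed intronic / intergenic / exonic /
intron-exon against generated gene models, 3'UTRs with planted canonical
seed sites, GMT gene sets, and the ground-truth tables.

The miR-22-3p / AKT3 pair is wired in explicitly: the generated world
contains the real ssc-miR-22-3p mature sequence and an AKT3 gene whose 3'UTR
embeds, verbatim, the wild-type reporter fragment carrying its 8mer seed
site; the mutant fragment (site destroyed) is emitted alongside as a
synthetic control entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .. import io as _io
from ..containers import (
    GeneModel,
    GenomicInterval,
    MatureMiRNA,
    PrecursorMiRNA,
    TruthTables,
    normalize_seq,
    revcomp,
)
from .config import STAGES, SyntheticConfig

#: Mature ssc-miR-22-3p (miRBase), T-normalized.
MIR_22_3P_SEQUENCE = normalize_seq("AAGCUGCCAGUUGAAGAACUGU")
MIR_22_3P_ID = "ssc-miR-22-3p"
MIR_22_PRECURSOR_ID = "ssc-mir-22"
AKT3_GENE_ID = "AKT3"
AKT3_MUT_ID = "AKT3_mut_control"

#: Wild-type AKT3 3'UTR reporter fragment (contains the miR-22-3p 8mer site)
AKT3_UTR_WT = "GAGCTCGGGTTCAAGGGCATTTTACTAAGGCAGCTAAGACATATGCAGACATAGATCTCGAG"
#: Mutant fragment: the seed-match core is destroyed by site-directed mutation
AKT3_UTR_MUT = "GAGCTCGGGTTCAAGGGCATTTTACTAATAGCTAGAAGACATATGCAGACATAGATCTCGAG"

_BASES = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def apportion(n: int, props: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items over proportions."""
    raw = [p * n for p in props]
    counts = [math.floor(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(props)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


@dataclass
class SyntheticReference:
    """Everything :func:`generate_reference` produces, ready to serialize."""

    matures: list[MatureMiRNA]
    precursors: list[PrecursorMiRNA]
    genes: list[GeneModel]
    #: gene id -> 3'UTR sequence (DNA)
    utrs: dict[str, str]
    gene_sets: dict[str, set[str]]
    same_species_ref: dict[str, str]
    other_species_ref: dict[str, str]
    truth: TruthTables
    #: mature id -> (precursor id, offset of the mature within the hairpin)
    mature_positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    @property
    def mature_seqs(self) -> dict[str, str]:
        return {m.id: m.sequence for m in self.matures}

    @property
    def hairpin_seqs(self) -> dict[str, str]:
        return {p.id: p.sequence for p in self.precursors}

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        _io.write_fasta(os.path.join(outdir, "mature.fa"), self.mature_seqs)
        _io.write_fasta(os.path.join(outdir, "hairpin.fa"), self.hairpin_seqs)
        _io.write_fasta(os.path.join(outdir, "same_species_mature.fa"),
                        self.same_species_ref)
        _io.write_fasta(os.path.join(outdir, "other_species_mature.fa"),
                        self.other_species_ref)
        _io.write_fasta(os.path.join(outdir, "utr.fa"), self.utrs)
        _io.write_gene_annotation(os.path.join(outdir, "genes.tsv"), self.genes)
        _io.write_gmt(os.path.join(outdir, "gene_sets.gmt"), self.gene_sets)
        _io.write_truth_tables(os.path.join(outdir, "truth"), self.truth)


# ---------------------------------------------------------------------------
# internals

def _plan_precursors(config: SyntheticConfig, rng: np.random.Generator):
    """Decide arm type, class and genomic context per precursor.

    Arm counts are chosen so total matures equals ``n_mirnas`` exactly;
    class and context apportionments hit their proportions within +-1 count.
    """
    n = config.n_mirnas
    p_both = config.arm_props[2]
    n_pre = max(1, round(n / (1.0 + p_both)))
    c5, c3, cb = apportion(n_pre, config.arm_props)
    total = c5 + c3 + 2 * cb
    while total < n:
        if c5 + c3 > 0:  # promote a single-arm precursor to both arms
            if c5 >= c3:
                c5 -= 1
            else:
                c3 -= 1
            cb += 1
        else:
            c5 += 1
        total = c5 + c3 + 2 * cb
    while total > n:
        if cb > 0:
            cb -= 1
            c5 += 1
        elif c5 > 0:
            c5 -= 1
        else:
            c3 -= 1
        total = c5 + c3 + 2 * cb
    n_pre = c5 + c3 + cb

    arms = np.array(["5p"] * c5 + ["3p"] * c3 + ["both"] * cb)
    arms = arms[rng.permutation(n_pre)]
    k_known, k_cons, k_nov = apportion(n_pre, config.class_props)
    classes = np.array(["known"] * k_known + ["conserved"] * k_cons + ["novel"] * k_nov)
    classes = classes[rng.permutation(n_pre)]
    contexts = []
    for label, count in zip(
        ("intronic", "intergenic", "exonic", "intron_exon"),
        apportion(n_pre, config.context_props),
    ):
        contexts.extend([label] * count)
    contexts = np.array(contexts)[rng.permutation(n_pre)]
    return arms.tolist(), classes.tolist(), contexts.tolist()


def _pick_mir22_slot(arms: list[str], classes: list[str]) -> int | None:
    """Index of a known precursor with a 3p arm to host ssc-miR-22-3p."""
    for i, (a, c) in enumerate(zip(arms, classes)):
        if c == "known" and a in ("3p", "both"):
            return i
    return None


def _draw_mature(rng, existing: set[str], length: int | None = None,
                 forbidden_seeds: set[str] | None = None) -> str:
    for _ in range(10_000):
        L = int(length if length is not None else rng.integers(20, 25))
        seq = _rand_seq(rng, L)
        if seq in existing:
            continue
        if forbidden_seeds and seq[1:8] in forbidden_seeds:
            continue
        return seq
    raise RuntimeError("could not draw a fresh mature sequence")


def _homolog_sharing_seed(rng, mature: str, existing: set[str]) -> str:
    """Other-mammal mature with the same seed but a different full sequence."""
    for _ in range(10_000):
        L = int(rng.integers(20, 25))
        seq = list(_rand_seq(rng, L))
        seq[1:8] = mature[1:8]
        seq = "".join(seq)
        if seq != mature and seq not in existing:
            return seq
    raise RuntimeError("could not draw a homolog sequence")


def _build_hairpin(rng, arm_type: str, seq5: str | None, seq3: str | None):
    """Hairpin = 5' flank + 5p arm + loop + 3p arm + 3' flank (60-120 nt).

    The absent arm of a single-arm precursor is an unprocessed random
    segment. Returns (sequence, offset of 5p arm, offset of 3p arm).
    """
    flank5 = _rand_seq(rng, int(rng.integers(4, 11)))
    flank3 = _rand_seq(rng, int(rng.integers(4, 11)))
    loop = _rand_seq(rng, int(rng.integers(12, 21)))
    arm5 = seq5 if seq5 is not None else _rand_seq(rng, 22)
    arm3 = seq3 if seq3 is not None else _rand_seq(rng, 22)
    seq = flank5 + arm5 + loop + arm3 + flank3
    off5 = len(flank5)
    off3 = len(flank5) + len(arm5) + len(loop)
    assert 60 <= len(seq) <= 120
    return seq, off5, off3


def _build_genes(rng, n_genes: int):
    """Lay genes end to end on one synthetic chromosome.

    Returns the gene models and each gene's downstream gap start (used to
    place intergenic precursors). Exons are 200-500 nt, introns 400-1500 nt,
    intergenic gaps at least 2 kb, so a <=120 nt hairpin fits anywhere.
    """
    genes = []
    gap_starts = []
    cursor = 1_000
    for i in range(n_genes):
        n_exons = int(rng.integers(3, 6))
        exons = []
        pos = cursor
        for j in range(n_exons):
            exon_len = int(rng.integers(200, 501))
            exons.append((pos, pos + exon_len))
            pos += exon_len
            if j < n_exons - 1:
                pos += int(rng.integers(400, 1501))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(id=f"GENE{i:04d}", chrom="chr1", strand=strand,
                               exons=tuple(exons)))
        gap_starts.append(pos)
        cursor = pos + int(rng.integers(2_000, 4_001))
    return genes, gap_starts


def _place_hairpin(rng, gene: GeneModel, gap_start: int, context: str,
                   hp_len: int) -> int:
    """Start coordinate realizing ``context`` relative to the host gene."""
    if context == "intronic":
        s0, e0 = gene.introns[0]
        return s0 + int(rng.integers(10, e0 - s0 - hp_len - 10))
    if context == "exonic":
        s0, e0 = gene.exons[0]
        return s0 + int(rng.integers(5, e0 - s0 - hp_len - 5))
    if context == "intron_exon":
        # straddle the first exon/intron junction by >=10 nt on each side
        overhang = int(rng.integers(10, hp_len - 9))
        return gene.exons[0][1] - overhang
    # intergenic: inside the >=2 kb gap downstream of the host gene
    return gap_start + 400


# ---------------------------------------------------------------------------

def generate_reference(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticReference:
    """Generate the full synthetic reference world for one configuration.

    Deterministic given ``config`` (byte-identical artifacts across runs
    with the same seed).
    """
    if rng is None:
        rng = config.rng(0)

    arms, classes, contexts = _plan_precursors(config, rng)
    n_pre = len(arms)
    mir22_idx = _pick_mir22_slot(arms, classes)

    # -- sequences ---------------------------------------------------------
    all_seqs: set[str] = set()
    same_species: dict[str, str] = {}
    other_species: dict[str, str] = {}

    # first pass: known + conserved (reference seed pool), then novel
    order = sorted(range(n_pre), key=lambda i: ("known", "conserved", "novel").index(classes[i]))
    arm_seqs: dict[int, dict[str, str]] = {}
    ref_seeds: set[str] = set()
    for i in order:
        wanted = ["5p", "3p"] if arms[i] == "both" else [arms[i]]
        arm_seqs[i] = {}
        for arm in wanted:
            if i == mir22_idx and arm == "3p":
                seq = MIR_22_3P_SEQUENCE
            elif classes[i] == "novel":
                seq = _draw_mature(rng, all_seqs, forbidden_seeds=ref_seeds)
            else:
                seq = _draw_mature(rng, all_seqs)
            all_seqs.add(seq)
            arm_seqs[i][arm] = seq
    for i in order:
        for arm, seq in arm_seqs[i].items():
            if classes[i] == "known":
                name = (MIR_22_3P_ID if i == mir22_idx and arm == "3p"
                        else f"ssc-ref-miR-{i:04d}-{arm}")
                same_species[name] = seq
                ref_seeds.add(seq[1:8])
            elif classes[i] == "conserved":
                hom = _homolog_sharing_seed(rng, seq, all_seqs | set(other_species.values()))
                other_species[f"hsa-ref-miR-{i:04d}-{arm}"] = hom
                ref_seeds.add(hom[1:8])

    # -- hairpins, gene models, genomic placement --------------------------
    n_extra_genes = 50
    genes, gap_starts = _build_genes(rng, n_pre + n_extra_genes)

    matures: list[MatureMiRNA] = []
    precursors: list[PrecursorMiRNA] = []
    mature_positions: dict[str, tuple[str, int]] = {}
    truth = TruthTables()
    for i in range(n_pre):
        pre_id = MIR_22_PRECURSOR_ID if i == mir22_idx else f"syn-mir-{i:04d}"
        seq5 = arm_seqs[i].get("5p")
        seq3 = arm_seqs[i].get("3p")
        hp_seq, off5, off3 = _build_hairpin(rng, arms[i], seq5, seq3)
        start = _place_hairpin(rng, genes[i], gap_starts[i], contexts[i],
                               len(hp_seq))
        interval = GenomicInterval("chr1", start, start + len(hp_seq),
                                   "+" if rng.random() < 0.5 else "-")
        precursors.append(
            PrecursorMiRNA(id=pre_id, sequence=hp_seq, interval=interval,
                           context=contexts[i])
        )
        truth.true_context[pre_id] = contexts[i]
        for arm, seq, off in (("5p", seq5, off5), ("3p", seq3, off3)):
            if seq is None:
                continue
            mid = (MIR_22_3P_ID if i == mir22_idx and arm == "3p"
                   else f"syn-miR-{i:04d}-{arm}")
            matures.append(
                MatureMiRNA(id=mid, sequence=seq, precursor_id=pre_id, arm=arm,
                            annotation_class=classes[i])
            )
            mature_positions[mid] = (pre_id, off)
            truth.true_class[mid] = classes[i]

    # rename one extra gene to AKT3 and embed the wild-type reporter fragment
    akt3 = genes[n_pre] if len(genes) > n_pre else genes[-1]
    genes[genes.index(akt3)] = GeneModel(id=AKT3_GENE_ID, chrom=akt3.chrom,
                                         strand=akt3.strand, exons=akt3.exons)
    gene_ids = [g.id for g in genes]

    # -- 3'UTRs with planted seed sites ------------------------------------
    utrs = {gid: _rand_seq(rng, int(rng.integers(300, 801))) for gid in gene_ids}
    utrs[AKT3_GENE_ID] = (
        _rand_seq(rng, 150) + AKT3_UTR_WT + _rand_seq(rng, 150)
    )
    has_mir22 = any(m.id == MIR_22_3P_ID for m in matures)
    if has_mir22:
        truth.true_targets[MIR_22_3P_ID] = {AKT3_GENE_ID}

    n_targeted = round(config.frac_targeted * len(matures))
    mature_ids = [m.id for m in matures]
    seeds_by_id = {m.id: m.seed for m in matures}
    plantable = [g for g in gene_ids if g != AKT3_GENE_ID]
    chosen = rng.choice(len(mature_ids), size=min(n_targeted, len(mature_ids)),
                        replace=False)
    used_windows: dict[str, list[tuple[int, int]]] = {}
    for idx in sorted(chosen):
        mid = mature_ids[idx]
        site = revcomp(seeds_by_id[mid]) + "A"  # 8mer site
        n_genes_hit = int(rng.integers(1, 4))
        hit = rng.choice(len(plantable), size=n_genes_hit, replace=False)
        for gi in sorted(hit):
            gid = plantable[gi]
            seq = utrs[gid]
            for _ in range(50):
                pos = int(rng.integers(0, len(seq) - len(site)))
                window = (pos, pos + len(site))
                if all(window[1] <= a or window[0] >= b
                       for (a, b) in used_windows.get(gid, [])):
                    break
            else:
                continue
            utrs[gid] = seq[:pos] + site + seq[pos + len(site):]
            used_windows.setdefault(gid, []).append(window)
            truth.true_targets.setdefault(mid, set()).add(gid)
    # mutant reporter fragment, emitted as a synthetic control UTR entry
    utrs[AKT3_MUT_ID] = AKT3_UTR_MUT

    # -- gene sets ----------------------------------------------------------
    gene_sets: dict[str, set[str]] = {}
    pool = [g for g in gene_ids if g != AKT3_GENE_ID]
    pi3k = set(np.array(pool)[rng.choice(len(pool), size=min(14, len(pool)),
                                         replace=False)])
    pi3k.add(AKT3_GENE_ID)
    gene_sets["PI3K_AKT_SIGNALING"] = pi3k
    shuffled = list(np.array(gene_ids)[rng.permutation(len(gene_ids))])
    for k, lo in enumerate(range(0, len(shuffled), 25)):
        chunk = set(shuffled[lo:lo + 25])
        if len(chunk) >= 5:
            gene_sets[f"PATHWAY_{k:02d}"] = chunk

    # -- planted expression structure ---------------------------------------
    n_specific = round(config.frac_specific * len(mature_ids))
    spec_idx = rng.choice(len(mature_ids), size=n_specific, replace=False)
    tissue_cycle = list(config.tissues)
    for j, idx in enumerate(sorted(spec_idx)):
        truth.true_specific[mature_ids[idx]] = tissue_cycle[j % len(tissue_cycle)]
    for m in mature_ids:
        truth.true_specific.setdefault(m, "none")

    lo, hi = np.log2(config.fc_range[0]), np.log2(config.fc_range[1])
    n_de = round(config.frac_de * len(mature_ids))
    for tissue in config.tissues:
        de_idx = rng.choice(len(mature_ids), size=n_de, replace=False)
        for idx in sorted(de_idx):
            mag = float(rng.uniform(lo, hi))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            truth.true_de[(mature_ids[idx], tissue)] = sign * mag
    if has_mir22 and n_de > 0 and "liver" in config.tissues:
        # the liver miR-22-3p axis: upregulated after birth
        truth.true_de[(MIR_22_3P_ID, "liver")] = float(rng.uniform(lo, hi))

    ref = SyntheticReference(
        matures=matures,
        precursors=precursors,
        genes=genes,
        utrs=utrs,
        gene_sets=gene_sets,
        same_species_ref=same_species,
        other_species_ref=other_species,
        truth=truth,
        mature_positions=mature_positions,
    )
    truth.validate_against(matures, precursors, set(utrs))
    return ref
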
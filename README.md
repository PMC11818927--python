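# neomir

Small-RNA expression analysis for the perinatal transition, at desk scale.

Newborn mammals must switch, within hours of birth, from placental supply to
autonomous physiology — gluconeogenesis in the liver, air breathing in the
lung, independent thermogenesis and feeding. miRNAs (~22-nt regulators that
repress mRNAs through 3′UTR seed sites) are central to this switch. `neomir`
implements the complete analysis used to study this process in piglet
tissues: six tissues (heart, liver, spleen, lung, muscle, duodenum) sampled
just before and just after birth, three replicates per cell with one
postnatal spleen replicate lost (35 samples).

The package is aimed at analysts who want the whole chain — from raw
small-RNA reads to miRNA census tables, tissue-specificity calls,
pre/postnatal differential expression, seed-based target networks and
wet-lab assay statistics — as tested, composable Python, with a synthetic
study generator providing ground truth so every stage can be validated
without any external download.

## What it computes

**Quantification.** Reads are 3′-adapter trimmed (longest adapter-prefix
suffix match, minimum overlap 5 nt), quality/length filtered (Q20,
18–26 nt), collapsed, and assigned by direct matching to mature miRNA
sequences with optional templated 3′-end tolerance. Detection filter:
count ≥ 3 in ≥ 1 sample; expression is RPM (count / library size × 10⁶).

**Annotation.** A mature is *known* if byte-identical to a same-species
reference entry, *conserved* if its seed (nt 2–8) matches an other-mammal
mature, else *novel*. Precursors are intronic / intergenic / exonic /
exon–intron-straddling relative to gene models (0-based half-open
in memory, 1-based inclusive GFF-style on disk).

**Tissue specificity.** Over per-tissue mean expression x₁…x_N:

    TSI = Σᵢ (1 − xᵢ / x_max) / (N − 1)

(0 = uniform, 1 = single-tissue; < 0.15 housekeeping, > 0.85
tissue-specific, boundaries nonspecific), and an entropy-based score

    TSS_t = 1 − √(JSD(p, e_t))

with the Jensen–Shannon divergence in bits between the expression
distribution p and the one-tissue indicator e_t; a specific miRNA is
assigned argmax_t TSS_t. TSI is computed three ways: prenatal samples,
postnatal samples, and all samples.

**Differential expression.** Within each tissue, postnatal vs prenatal:
TMM normalization (doubly trimmed weighted mean of M-values, 30 %/5 %
trims), quantile-adjusted library-size equalization, conditional
maximum-likelihood common NB dispersion with empirical-Bayes shrinkage per
miRNA, an exact conditional NB test on group sums (two-sided by summing
outcomes no more probable than observed), Benjamini–Hochberg correction,
and the decision rule fold change > 1.5 (strict) and FDR < 0.05 (strict).

**Cross-tissue structure and targets.** DE-overlap distribution across
tissues, direction-conservation calls (DE in ≥ 2 tissues, same sign
everywhere), a 2×2 chi-square (1 df, no continuity correction) for
specificity–DE association, canonical seed-site scanning (8mer >
7mer-m8 > 7mer-A1), hypergeometric gene-set over-representation against
user-supplied GMT collections, and a miRNA–mRNA repression network (edge ⇔
predicted site + opposite directions in the same tissue).

**Assay statistics.** 2^−ΔΔCt relative qPCR quantification against a
calibrator group, firefly/Renilla dual-luciferase normalization relative
to the mimic control, protein-normalized glucose production, and
two-group t-tests / one-way ANOVA with `*`/`**` flags.

## Worked example

```python
from neomir.simulate import SyntheticConfig
from neomir.pipeline import run_pipeline

result = run_pipeline(
    SyntheticConfig(seed=5, n_mirnas=120, libsize_range=(8000, 12000))
)
r = result.report
print(r["annotation"]["matures_by_class"])
print(r["genomic_context"]["counts"])
print(r["specificity"]["counts"])
print(r["differential_expression"]["per_tissue"])
print(r["assays"]["luciferase_relative_activity"])
```

prints

```
{'conserved': 50, 'known': 42, 'novel': 28}
{'intron_exon': 11, 'intronic': 41, 'intergenic': 25, 'exonic': 0}
{'tissue_specific': 66, 'nonspecific': 54, 'housekeeping': 0}
{'duodenum': 2, 'heart': 8, 'liver': 3, 'lung': 3, 'muscle': 5, 'spleen': 3}
{'Mut': 1.1216143219234096, 'Wt': 0.6881424522449321}
```

Reading this: of 120 simulated matures, 42 matched the same-species
reference exactly (known), 50 shared a seed with another mammal
(conserved) and 28 were novel; 41 of 77 precursors (53.25 %) fell in
introns; 66 miRNAs (55 %) were called tissue-specific and none
housekeeping; 24 DE events were found across the six tissues (the
duodenum-to-heart spread reflects sampling at this depth); and in the
simulated dual-luciferase assay the miR-22-3p mimic halved the wild-type
AKT3 3′UTR reporter activity (0.69) while leaving the mutant reporter
unchanged (1.12) — the repression signature the network stage encodes.

The same run is available from the shell:

```bash
neomir --seed 5 --outdir out all
```

which writes `counts.tsv`, `specificity.tsv`, `de.tsv`, `network.tsv`,
the reference FASTA/GFF/GMT files, and `report.json`.

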
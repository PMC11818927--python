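# Methods

This note records the models, parameter choices and numerical conventions
behind `neomir`, and what the synthetic study does and does not emulate.

## The synthetic study

The generator reproduces the structure of a perinatal six-tissue design:
heart, liver, spleen, lung, muscle and duodenum, each sampled prenatally
and postnatally with three replicates, minus one postnatal spleen
replicate whose RNA failed quality control — 35 samples. Everything is
configurable (`SyntheticConfig`), but the defaults *are* the study
conditions and are not meant to be tuned per analysis.

**Reference world.** Precursor hairpins are random 60–120-nt sequences
assembled as 5′ flank + 5p arm + loop + 3p arm + 3′ flank; mature arms
(20–24 nt) are exact substrings, and single-arm precursors carry an
unprocessed random arm. Class structure is planted at the precursor
level: *known* matures are copied verbatim into a same-species reference,
*conserved* matures get an other-mammal homolog sharing nucleotides 2–8
(the seed) but differing elsewhere, and *novel* matures are
rejection-sampled so their seed collides with neither reference. Default
class proportions (0.294 / 0.461 / 0.245) and genomic-context proportions
(0.5314 / 0.3285 / 0.0010 / 0.1391 for intronic / intergenic / exonic /
exon–intron) follow the published census of the piglet study this design
emulates; apportionment uses largest remainders, so realized counts match
the proportions within one unit. Gene models (3–5 exons of 200–500 nt,
introns 400–1500 nt, ≥ 2-kb intergenic gaps) are laid end to end on one
synthetic chromosome and hairpins are placed to realize their assigned
context exactly; coordinates are 0-based half-open in memory and 1-based
inclusive in the GFF-like TSV on disk.

The real mature ssc-miR-22-3p sequence is wired in, together with an AKT3
gene whose 3′UTR embeds the wild-type dual-luciferase reporter fragment
(which carries the miR-22-3p 8mer site); the matching mutant fragment, in
which the seed match is destroyed, is emitted as a synthetic control UTR
entry. Planted target sites for other miRNAs are 8mer seed complements
overwritten into host UTRs at recorded positions.

**Counts.** Counts are negative binomial, `var = μ + φμ²` with φ = 0.1 by
default (typical for small-RNA replicates). The mean for miRNA *m* in
sample *s* of tissue *t* is

    μ_{m,s} = L_s · w_{m,t,g} / Σ_m w_{m,t,g}

with library size L_s uniform in 20 000–40 000 reads (desk scale),
baseline abundance lognormal (median 50, σ = 1.0 → ~3 decades of dynamic
range), a per-(miRNA, tissue) lognormal wobble of σ = 0.4 (matching the
roughly two-fold inter-tissue spread of ubiquitously expressed miRNAs in
tissue atlases), a dominance factor for the true specific tissue drawn
log-uniformly from 16–256× (tissue-restricted miRNAs are enriched one to
two-plus orders of magnitude in their home tissue), and a stage factor
2^log2FC applied postnatally to planted DE miRNAs (|FC| between 2 and 6,
signed at random; the miR-22-3p / liver axis is always planted as
upregulated). Per-tissue DE fraction defaults to 10 % and the specific
fraction to 55 %.

**Reads.** Each clean read is the mature sequence + the TruSeq small-RNA
3′ adapter, padded with random bases to 50 nt; 2 % junk reads (adapter
dimers and < 18-nt inserts) are appended and tallied. There is no
base-call error model by default (`base_error = 0`), because the
quantifier uses exact matching; a per-base substitution rate is available
for stress tests. The read *multiset* per sample equals the count column
exactly, which is what makes the noise-free round trip an identity.

**Assays.** Ct tables are built by inverting the 2^−ΔΔCt method
(Ct_target = Ct_ref + offset − log₂ expression + 𝒩(0, σ), σ = 0.1 cycles),
so zero-noise tables recover programmed fold changes exactly. Luciferase
wells carry programmed firefly/Renilla treatment ratios (wild-type mimic
0.55, everything else 1.0); glucose wells carry per-well protein content;
the neonatal blood-glucose series is a monotone (PCHIP) interpolation
through 6.03 mmol/L at birth, a 1.23 mmol/L nadir at 3 h and 2.23 mmol/L
at 6 h, plus measurement noise.

**What it does not emulate** — and hence what passing tests do not show
about real data: sequencing-error and quality profiles, isomiR complexity
beyond 3′ trimming, multi-mapping against a real genome, hairpin
discovery, correlated biological replicates, batch effects, and real
pathway structure in the GMT sets. Recovery rates measured here are upper
bounds for field data.

## Analysis conventions

**Quantification.** Adapter trimming takes the first full adapter
occurrence, else the longest ≥ 5-nt adapter prefix at the read 3′ end;
untrimmed reads are dropped by default. Quality filter Q20 mean
(Phred+33), length window 18–26 nt (clean small-RNA reads concentrate at
21–24 nt; the window brackets that peak). Reads matching more than one
mature (after optional ≤ *t*-nt 3′ trimming, or extension templated on the
hairpin) are discarded as ambiguous, never fractionally assigned —
deterministic and conservative; the tally is reported. Library size for
RPM is the per-sample total of *assigned* reads, so RPM columns sum to
10⁶ exactly.

**Specificity.** TSI uses per-tissue means of RPM without log or
pseudocount; the TSS profile is the same means normalized to sum 1. Both
metrics are scale-free in the relevant sense; a log2(RPM+1) basis is
available as an option. The TSI form Σ(1 − xᵢ/x_max)/(N−1) and the
Jensen–Shannon-based TSS (base-2 logs, so JSD ≤ 1 and the score stays in
[0, 1]) are the standard forms these names denote; both are isolated in
one module so alternates can be swapped. Thresholds: < 0.15 housekeeping,
> 0.85 specific, boundary values nonspecific (strict inequalities).
Tissue assignment is argmax TSS with lexicographic tie-breaking. miRNAs
failing the detection filter are never scored.

**Differential expression.** TMM: the reference sample is the one whose
75th count percentile (library-scaled) is closest to the mean; M/A values
use miRNAs positive in both samples; 30 % two-sided trim on M and 5 % on
A; weights are the usual inverse delta-method variances; factors are
rescaled to geometric mean 1. Dispersion: counts are mapped to a common
library size (geometric mean of effective sizes) by a normal/gamma
quantile average, and the common φ maximizes the summed conditional NB
log-likelihood (scalar bounded search on log₁₀ φ ∈ [−8, 1], two rounds of
pseudo-count refinement). Tagwise φ maximizes the per-miRNA conditional
likelihood plus 10× the mean likelihood over all miRNAs (fixed shrinkage
weight), on a 33-point grid spanning ±8 doublings around the common
value. The exact test conditions on the (rounded) total of the two group
pseudo-sums; group sums of n replicates are NB with dispersion φ/n, and
the two-sided p sums all splits at most as probable as the observed one
(a 1 + 10⁻¹² relative guard absorbs floating-point ties); φ < 10⁻⁸ falls
back to the conditional binomial. All-zero miRNAs get p = 1. These
internals follow the classic quantile-adjusted conditional approach but
are re-implementations validated by calibration (null type-I rate) and
recovery (power/FDR), not by numerical identity with any package.

log2FC is postnatal vs prenatal on group means of counts scaled to the
common effective library size, with a 0.5 pseudo-count on both means. The
DE rule is strict: fold change > 1.5 *and* BH-FDR < 0.05, with BH applied
within each tissue across miRNAs (not across tissues jointly). The n = 2
postnatal spleen group runs through the same machinery with a logged
warning.

**Cross-tissue and targets.** Direction conservation requires DE in ≥ 2
tissues with one sign everywhere DE; single-tissue DE is nonconserved by
definition. The specificity–DE chi-square uses 1 df and no continuity
correction. Seed scanning is canonical-site matching only: 7mer-m8 =
reverse complement of miRNA nt 2–8, 7mer-A1 = reverse complement of nt
2–7 followed by A, 8mer = both; overlapping classes at one seed locus
report the strongest; given strand only, no G:U wobble, no
3′-supplementary pairing, no context scoring. Enrichment is a one-sided
hypergeometric over caller-supplied GMT sets (external annotation
databases are out of scope, so published enrichment p-values are not
reproduction targets). Network edges require a predicted site and
opposite miRNA/mRNA directions in the same tissue; in the synthetic
pipeline the mRNA direction table is derived from the planted truth
(targets of truly responsive miRNAs move opposite), standing in for a
matched mRNA experiment.

**Assays.** ΔΔCt calibrates against the calibrator-group *mean* ΔCt per
target (so the calibrator's geometric mean expression is exactly 1);
amplification efficiency is fixed at 2. The two-group test is the pooled
(equal-variance) t-test, the conventional reading when unspecified, with
Welch available; > 2 groups use one-way ANOVA; flags are `*` p < 0.05 and
`**` p < 0.01.

**Reporting.** Every percentage is 100·num/den rounded half-up to two
decimals, rendered with trailing zeros trimmed (53.14 but 13.9, 0.1);
`validate_report` re-derives each percentage from the counts in the same
report and rejects any inconsistency.

## Reproducibility and problem sizes

All randomness flows from one integer seed. Each pipeline stage draws
from `default_rng([seed, stream])` with a fixed per-stage stream index —
the SeedSequence-based equivalent of a single master generator that also
keeps every artifact byte-reproducible when a stage is run on its own.

Simulation-based checks run at sizes chosen for laptop-scale iteration:
the null calibration uses 2000 miRNAs at μ = 200, φ = 0.1, 3 vs 3
(empirical p < 0.05 rate within [0.03, 0.07]); fold-change recovery uses
10 simulations of 300 miRNAs with 30 planted |FC| = 4 effects (mean
recall ≥ 80 %, mean empirical FDR ≤ 10 %); specific-tissue recovery uses
the full default 35-sample study (300 miRNAs); the round trip uses a
50-miRNA study at 2000–4000 reads per sample.

## Known limitations

Exact matching makes quantification blind to sequencing errors; the
dispersion shrinkage weight is fixed rather than estimated from data; the
exact test rounds pseudo-sums to integers (negligible at these depths,
crude below ~10 counts); TMM is undefined for samples sharing no
expressed miRNA with the reference (an error, not a fallback);
context assignment ignores strand, and a precursor hanging off a gene
edge is classified by the features it overlaps; hierarchical-clustering
leaf order inherits SciPy's deterministic lowest-index tie-breaking and
is not an optimal-leaf-ordering.
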
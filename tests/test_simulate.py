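"""Synthetic generator: determinism, planted structure, generative moments."""

import numpy as np
import pandas as pd
import pytest

from neomir import io as nio
from neomir.assays import ddct, luciferase_relative_activity
from neomir.simulate import (
    SyntheticConfig,
    generate_reference,
    make_manifest,
    simulate_assays,
    simulate_counts,
    synthesize_reads,
)
from neomir.simulate.config import STAGES
from neomir.simulate.reads import synthesize_sample_reads
from neomir.simulate.reference import apportion


# ---------------------------------------------------------------------------
# configuration validation

@pytest.mark.parametrize(
    "field,value",
    [
        ("frac_specific", 1.5),
        ("frac_de", -0.1),
        ("fc_range", (1.0, 4.0)),
        ("class_props", (0.5, 0.5, 0.5)),
        ("context_props", (1.0, 0.0, 0.0)),
        ("n_reps", 1),
        ("adapter", ""),
        ("dispersion", -0.5),
    ],
)
def test_invalid_config_rejected(field, value):
    with pytest.raises(ValueError):
        SyntheticConfig(**{field: value})


def test_manifest_is_35_samples_by_default():
    manifest = make_manifest(SyntheticConfig())
    assert len(manifest) == 35
    assert "spleen_postnatal_3" not in set(manifest["sample_id"])
    cells = manifest.groupby(["tissue", "stage"]).size()
    assert cells.loc[("spleen", "postnatal")] == 2
    assert set(manifest["stage"]) == set(STAGES)


# ---------------------------------------------------------------------------
# reference generation

def test_reference_deterministic_byte_identical(tmp_path):
    cfg = SyntheticConfig(seed=42, n_mirnas=40)
    for name in ("a", "b"):
        generate_reference(cfg).write(tmp_path / name)
    for fname in ("mature.fa", "hairpin.fa", "utr.fa", "genes.tsv",
                  "gene_sets.gmt", "same_species_mature.fa"):
        assert (tmp_path / "a" / fname).read_bytes() == \
            (tmp_path / "b" / fname).read_bytes()


def test_degenerate_class_props_all_known():
    cfg = SyntheticConfig(seed=3, n_mirnas=30, class_props=(1.0, 0.0, 0.0))
    ref = generate_reference(cfg)
    same = set(ref.same_species_ref.values())
    assert all(m.sequence in same for m in ref.matures)
    assert set(ref.truth.true_class.values()) == {"known"}


def _brute_force_context(start: int, end: int, genes) -> str:
    """Base-by-base membership oracle over the emitted gene models."""
    exon = intron = False
    for g in genes:
        g_exon = any(any(s <= b < e for (s, e) in g.exons)
                     for b in range(start, end))
        g_intron = any(any(s <= b < e for (s, e) in g.introns)
                       for b in range(start, end))
        exon |= g_exon
        intron |= g_intron
        if g_exon and g_intron:
            return "intron_exon"
    if exon:
        return "exonic"
    if intron:
        return "intronic"
    return "intergenic"


def test_degenerate_context_props_all_intronic_vs_overlap_oracle(tmp_path):
    cfg = SyntheticConfig(seed=9, n_mirnas=40,
                          context_props=(1.0, 0.0, 0.0, 0.0))
    ref = generate_reference(cfg)
    nio.write_gene_annotation(tmp_path / "genes.tsv", ref.genes)
    genes = nio.read_gene_annotation(tmp_path / "genes.tsv")
    assert set(ref.truth.true_context.values()) == {"intronic"}
    for p in ref.precursors:
        oracle = _brute_force_context(p.interval.start, p.interval.end, genes)
        assert oracle == "intronic"


def test_truth_contexts_match_overlap_oracle(small_reference):
    for p in small_reference.precursors:
        oracle = _brute_force_context(p.interval.start, p.interval.end,
                                      small_reference.genes)
        assert oracle == small_reference.truth.true_context[p.id]


def test_class_and_context_proportions_within_one_count(small_config,
                                                        small_reference):
    n_pre = len(small_reference.precursors)
    ctx_counts = pd.Series(small_reference.truth.true_context).value_counts()
    for label, prop in zip(("intronic", "intergenic", "exonic", "intron_exon"),
                           small_config.context_props):
        assert abs(ctx_counts.get(label, 0) - prop * n_pre) <= 1
    cls_by_pre = {
        m.precursor_id: small_reference.truth.true_class[m.id]
        for m in small_reference.matures
    }
    cls_counts = pd.Series(cls_by_pre).value_counts()
    for label, prop in zip(("known", "conserved", "novel"),
                           small_config.class_props):
        assert abs(cls_counts.get(label, 0) - prop * n_pre) <= 1


def test_hairpins_contain_matures_and_have_valid_length(small_reference):
    hp = small_reference.hairpin_seqs
    for m in small_reference.matures:
        assert m.sequence in hp[m.precursor_id]
        pre_id, off = small_reference.mature_positions[m.id]
        assert hp[pre_id][off: off + len(m.sequence)] == m.sequence
    assert all(60 <= len(s) <= 120 for s in hp.values())


def test_apportion_sums_and_bounds():
    counts = apportion(97, (0.5314, 0.3285, 0.0010, 0.1391))
    assert sum(counts) == 97
    assert all(abs(c - p * 97) <= 1 for c, p in
               zip(counts, (0.5314, 0.3285, 0.0010, 0.1391)))


# ---------------------------------------------------------------------------
# count simulation

def test_counts_deterministic(small_config, small_reference, small_manifest):
    ids = [m.id for m in small_reference.matures]
    a = simulate_counts(small_config, small_reference.truth, small_manifest, ids)
    b = simulate_counts(small_config, small_reference.truth, small_manifest, ids)
    assert a.counts.equals(b.counts)


def test_frac_de_zero_means_no_planted_stage_effect():
    cfg = SyntheticConfig(seed=4, n_mirnas=30, frac_de=0.0)
    ref = generate_reference(cfg)
    assert ref.truth.true_de == {}


def test_nb_moments_match_formulas():
    # mu=100, phi=0.1 -> var = 100 + 0.1*100^2 = 1100
    from neomir.simulate.counts import nb_draw

    rng = np.random.default_rng(0)
    draws = nb_draw(rng, np.full(10_000, 100.0), 0.1)
    se = np.sqrt(1100 / 10_000)
    assert abs(draws.mean() - 100) < 3 * se
    assert abs(draws.var() - 1100) < 0.1 * 1100


def test_poisson_limit_variance_to_mean_ratio():
    from neomir.simulate.counts import nb_draw

    rng = np.random.default_rng(1)
    draws = nb_draw(rng, np.full(20_000, 50.0), 1e-9)
    assert abs(draws.var() / draws.mean() - 1.0) < 0.05


def test_empty_design_rejected(small_config, small_reference):
    with pytest.raises(ValueError, match="empty design"):
        simulate_counts(small_config, small_reference.truth,
                        pd.DataFrame(columns=["sample_id", "tissue", "stage"]))


# ---------------------------------------------------------------------------
# read synthesis

def test_read_construction_and_exact_multiset():
    cfg = SyntheticConfig(seed=7, junk_frac=0.0)
    rng = cfg.rng(99)
    rs = synthesize_sample_reads("s1", {"m1": 5}, {"m1": "A" * 10 + "C" * 12},
                                 cfg, rng)
    assert len(rs.records) == 5 and rs.n_junk == 0
    insert = "A" * 10 + "C" * 12
    for _title, seq, qual in rs.records:
        assert seq.startswith(insert)
        # adapter starts right after the 22-nt insert
        assert seq[22:].startswith(cfg.adapter[: cfg.read_length - 22])
        assert len(seq) == cfg.read_length == len(qual)


def test_missing_mature_sequence_is_named():
    cfg = SyntheticConfig(seed=7)
    with pytest.raises(ValueError, match="m-absent"):
        synthesize_sample_reads("s1", {"m-absent": 3}, {}, cfg, cfg.rng(0))


def test_junk_reads_recorded(small_config):
    cfg = SyntheticConfig(seed=8, junk_frac=0.5)
    rs = synthesize_sample_reads("s1", {"m1": 100},
                                 {"m1": "ACGT" * 5 + "AC"}, cfg, cfg.rng(1))
    assert rs.n_junk == 50
    assert len(rs.records) == 150


def test_fastq_round_trip_on_disk(tmp_path, small_config, small_reference,
                                  small_counts):
    sub = small_counts.subset_samples(small_counts.samples[:2])
    synthesize_reads(sub, small_reference.mature_seqs, small_config,
                     outdir=tmp_path)
    records = list(nio.read_fastq(tmp_path / f"{sub.samples[0]}.fastq"))
    expected = int(sub.counts[sub.samples[0]].sum())
    n_junk = round(small_config.junk_frac * expected)
    assert len(records) == expected + n_junk


# ---------------------------------------------------------------------------
# assay simulation

def test_noise_free_assays_recover_programmed_values():
    cfg = SyntheticConfig(seed=5, ct_noise_sd=0.0, glucose_noise_sd=0.0)
    data = simulate_assays(None, cfg, fold_changes={"X": 4.0})
    rel = ddct(data.ct, calibrator="prenatal")
    post = rel.loc[rel["group"] == "postnatal", "relative_expression"]
    assert np.allclose(post, 4.0)
    # blood glucose hits the programmed anchors exactly without noise
    curve = data.blood_glucose.mean(axis=1)
    assert curve.loc[0.0] == pytest.approx(6.03)
    assert curve.min() == pytest.approx(1.23)
    assert curve.idxmin() == pytest.approx(3.0)
    assert curve.loc[6.0] == pytest.approx(2.23)


def test_luciferase_control_ratio_one_normalizes_to_one():
    cfg = SyntheticConfig(seed=6, ct_noise_sd=0.0)
    data = simulate_assays(None, cfg)
    rel = luciferase_relative_activity(data.luciferase)
    controls = rel[rel["treatment"] == "mimic_control"]
    for _construct, sub in controls.groupby("construct"):
        assert sub["relative_activity"].mean() == pytest.approx(1.0)


def test_ddct_fold_recovery_with_noise_monte_carlo():
    recovered = []
    for seed in range(50):
        cfg = SyntheticConfig(seed=seed, ct_noise_sd=0.05)
        data = simulate_assays(None, cfg, fold_changes={"X": 2.5})
        rel = ddct(data.ct, calibrator="prenatal")
        post = rel.loc[rel["group"] == "postnatal", "relative_expression"]
        recovered.append(post.mean())
    assert abs(np.mean(recovered) - 2.5) / 2.5 < 0.05


def test_non_positive_fold_change_rejected():
    cfg = SyntheticConfig(seed=1)
    with pytest.raises(ValueError, match="non-positive"):
        simulate_assays(None, cfg, fold_changes={"X": 0.0})
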
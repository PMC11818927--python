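"""DE overlap, direction conservation, chi-square, seed scan, network,
hypergeometric enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neomir.containers import revcomp
from neomir.simulate.reference import (
    AKT3_UTR_MUT,
    AKT3_UTR_WT,
    MIR_22_3P_SEQUENCE,
)
from neomir.targets import (
    build_network,
    direction_conservation,
    geneset_enrichment,
    overlap_distribution,
    predict_all_targets,
    predict_targets,
    seed_match_patterns,
    specificity_enrichment,
)


# ---------------------------------------------------------------------------
# overlap distribution

def test_overlap_simple_case():
    dist = overlap_distribution({"A": {"m1", "m2"}, "B": {"m1"}})
    assert dist.counts[1] == 1 and dist.counts[2] == 1
    assert dist.total_unique == 2


def test_overlap_reported_study_shape():
    # the printed overlap counts (119, 33, 10, 2, 0, 0) reconstruct a unique
    # total of 164 with a 72.56% single-tissue share
    sets: dict[str, set] = {t: set() for t in "ABCDEF"}
    mid = 0
    for k, n in zip(range(1, 7), (119, 33, 10, 2, 0, 0)):
        for _ in range(n):
            for t in list(sets)[:k]:
                sets[t].add(f"m{mid}")
            mid += 1
    dist = overlap_distribution(sets)
    assert dist.total_unique == 164
    assert dist.counts == {1: 119, 2: 33, 3: 10, 4: 2, 5: 0, 6: 0}
    assert dist.percentage(1) == pytest.approx(72.56, abs=0.005)
    assert dist.percentage(2) == pytest.approx(20.12, abs=0.005)


def test_overlap_disjoint_sets_all_k1():
    dist = overlap_distribution({"A": {"x"}, "B": {"y"}, "C": {"z"}})
    assert dist.counts[1] == 3 and dist.total_unique == 3


def test_overlap_weighted_sum_identity():
    rng = np.random.default_rng(0)
    sets = {
        f"t{j}": {f"m{i}" for i in rng.choice(50, size=20, replace=False)}
        for j in range(4)
    }
    dist = overlap_distribution(sets)
    assert sum(k * c for k, c in dist.counts.items()) == \
        sum(len(s) for s in sets.values())


# ---------------------------------------------------------------------------
# direction conservation

def _de_table(rows):
    return pd.DataFrame(
        rows, columns=["mirna_id", "tissue", "log2fc", "direction", "is_de"]
    )


def test_same_direction_in_two_tissues_is_conserved():
    table = _de_table([
        ("m1", "liver", 1.2, "up", True),
        ("m1", "lung", 0.9, "up", True),
    ])
    conserved, heat = direction_conservation(table)
    assert conserved["m1"]
    assert heat.loc["m1", "liver"] == pytest.approx(1.2)


def test_opposite_directions_not_conserved():
    table = _de_table([
        ("m1", "liver", 1.2, "up", True),
        ("m1", "lung", -0.9, "down", True),
    ])
    conserved, _ = direction_conservation(table)
    assert not conserved["m1"]


def test_single_tissue_de_not_conserved():
    table = _de_table([
        ("m1", "liver", 1.2, "up", True),
        ("m1", "lung", 0.9, "up", False),
    ])
    conserved, heat = direction_conservation(table)
    assert not conserved["m1"]
    assert np.isnan(heat.loc["m1", "lung"]) if "lung" in heat.columns else True


# ---------------------------------------------------------------------------
# chi-square

def _flags(tp, fp, fn, tn):
    de = [True] * (tp + fp) + [False] * (fn + tn)
    sp = [True] * tp + [False] * fp + [True] * fn + [False] * tn
    idx = range(len(de))
    return pd.Series(de, index=idx), pd.Series(sp, index=idx)


def test_chi_square_independent_table_is_zero():
    _t, stat, p = specificity_enrichment(*_flags(10, 10, 10, 10))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_hand_value():
    _t, stat, _p = specificity_enrichment(*_flags(30, 10, 10, 30))
    assert stat == pytest.approx(20.0)


def test_chi_square_symmetric_under_transpose():
    _t, stat1, _ = specificity_enrichment(*_flags(25, 5, 12, 18))
    de, sp = _flags(25, 5, 12, 18)
    _t, stat2, _ = specificity_enrichment(sp, de)  # swap rows/columns
    assert stat1 == pytest.approx(stat2)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(cells=st.tuples(*[st.integers(min_value=1, max_value=60)] * 4))
def test_chi_square_matches_brute_force_oracle(cells):
    a, b, c, d = cells
    _t, stat, _p = specificity_enrichment(*_flags(a, b, c, d))
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = 0.0
    for i in range(2):
        for j in range(2):
            e = table[i].sum() * table[:, j].sum() / n
            expected += (table[i, j] - e) ** 2 / e
    assert stat == pytest.approx(expected, abs=1e-9)


def test_chi_square_degenerate_margin_flagged():
    _t, stat, p = specificity_enrichment(*_flags(0, 0, 10, 10))
    assert np.isnan(stat) and np.isnan(p)


# ---------------------------------------------------------------------------
# seed scanning

def test_akt3_wildtype_fragment_has_exactly_one_8mer_site():
    sites = predict_targets("miR-22-3p", MIR_22_3P_SEQUENCE,
                            {"AKT3": AKT3_UTR_WT})
    assert len(sites) == 1
    assert sites[0].site_type == "8mer"
    core = revcomp(MIR_22_3P_SEQUENCE[1:8]) + "A"
    assert AKT3_UTR_WT[sites[0].start: sites[0].start + 8] == core


def test_akt3_mutant_fragment_has_no_sites():
    assert predict_targets("miR-22-3p", MIR_22_3P_SEQUENCE,
                           {"AKT3mut": AKT3_UTR_MUT}) == []


def test_constructed_8mer_at_position_zero():
    mirna = "TACGTACGTACGTACGTACGTA"
    utr = revcomp(mirna[1:8]) + "A"
    sites = predict_targets("m", mirna, {"g": utr})
    assert len(sites) == 1
    assert sites[0].site_type == "8mer" and sites[0].start == 0


def test_short_utr_yields_nothing():
    assert predict_targets("m", "TACGTACGTACGTACGTACGTA", {"g": "ACGTACG"}) == []


def _naive_site_scan(mirna: str, utr: str):
    """Independent motif oracle: character-by-character substring search of
    the three patterns, strongest type kept per seed-match locus.

    A locus is keyed by where the 7-nt seed-complement core starts
    (one base before the motif for 7mer-A1 sites)."""
    pats = seed_match_patterns(mirna)
    found: dict[int, str] = {}
    for t in ("8mer", "7mer-m8", "7mer-A1"):  # strongest first
        motif = pats[t]
        for i in range(len(utr) - len(motif) + 1):
            if all(utr[i + k] == motif[k] for k in range(len(motif))):
                core = i - 1 if t == "7mer-A1" else i
                found.setdefault(core, t)
    return sorted(found.items())


@settings(deadline=None, derandomize=True, max_examples=50)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_seed_scan_matches_naive_oracle_on_random_utrs(seed):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    mirna = "".join(bases[rng.integers(0, 4, 22)])
    utr = "".join(bases[rng.integers(0, 4, 400)])
    # plant one site of each class so non-trivial loci always exist
    pats = seed_match_patterns(mirna)
    utr = pats["8mer"] + utr[8:200] + pats["7mer-m8"] + "C" + utr[208:]
    got = sorted(
        (s.start - 1 if s.site_type == "7mer-A1" else s.start, s.site_type)
        for s in predict_targets("m", mirna, {"g": utr})
    )
    assert got == _naive_site_scan(mirna, utr)


def test_planted_target_pairs_all_recovered(small_reference):
    ref = small_reference
    preds = predict_all_targets(ref.mature_seqs, ref.utrs)
    predicted = set(zip(preds["mirna_id"], preds["gene_id"]))
    for mid, genes in ref.truth.true_targets.items():
        for gid in genes:
            assert (mid, gid) in predicted


# ---------------------------------------------------------------------------
# network

def _one_de_row(mid, tissue, direction, is_de=True):
    return pd.DataFrame(
        [(mid, tissue, 1.0 if direction == "up" else -1.0, direction, is_de)],
        columns=["mirna_id", "tissue", "log2fc", "direction", "is_de"],
    )


def test_network_edge_requires_site_and_opposite_directions():
    pairs = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"]})
    gdir = pd.DataFrame({"gene_id": ["g1"], "tissue": ["liver"],
                         "direction": ["down"]})
    edges = build_network(_one_de_row("m1", "liver", "up"), gdir, pairs)
    assert len(edges) == 1
    assert edges[0].mirna_direction == "up" and edges[0].gene_direction == "down"


def test_network_no_edge_when_directions_agree():
    pairs = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"]})
    gdir = pd.DataFrame({"gene_id": ["g1"], "tissue": ["liver"],
                         "direction": ["up"]})
    assert build_network(_one_de_row("m1", "liver", "up"), gdir, pairs) == []


def test_network_no_edge_without_predicted_site():
    pairs = pd.DataFrame({"mirna_id": [], "gene_id": []})
    gdir = pd.DataFrame({"gene_id": ["g1"], "tissue": ["liver"],
                         "direction": ["down"]})
    assert build_network(_one_de_row("m1", "liver", "up"), gdir, pairs) == []


# ---------------------------------------------------------------------------
# hypergeometric enrichment

def test_hypergeometric_hand_value():
    universe = {f"g{i}" for i in range(20)}
    gene_set = {f"g{i}" for i in range(5)}
    result = geneset_enrichment(gene_set, {"s": gene_set}, universe)
    assert result["pvalue"][0] == pytest.approx(1 / comb(20, 5), rel=1e-9)


def test_gene_list_equal_to_universe_gives_p_one():
    universe = {f"g{i}" for i in range(10)}
    result = geneset_enrichment(universe, {"s": {"g0", "g1", "g2"}}, universe)
    assert result["pvalue"][0] == pytest.approx(1.0)


def test_hypergeometric_matches_exhaustive_enumeration_small_universe():
    universe = [f"g{i}" for i in range(12)]
    gene_set = set(universe[:4])
    picked = set(universe[2:7])  # list of size 5, overlap 2
    result = geneset_enrichment(picked, {"s": gene_set}, set(universe))
    observed = len(picked & gene_set)
    hits = total = 0
    for combo in itertools.combinations(universe, len(picked)):
        total += 1
        if len(set(combo) & gene_set) >= observed:
            hits += 1
    assert result["pvalue"][0] == pytest.approx(hits / total, rel=1e-9)


def test_zero_overlap_with_small_set_near_one():
    universe = [f"g{i}" for i in range(15)]
    gene_set = set(universe[:2])
    picked = set(universe[5:8])
    result = geneset_enrichment(picked, {"s": gene_set}, set(universe))
    # exact-fraction enumeration over all C(15,3) draws
    hits = sum(
        1 for combo in itertools.combinations(universe, 3)
        if len(set(combo) & gene_set) >= 0
    )
    assert result["pvalue"][0] == pytest.approx(1.0)
    assert hits == comb(15, 3)


def test_empty_universe_rejected():
    with pytest.raises(ValueError):
        geneset_enrichment(set(), {"s": {"a"}}, set())
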
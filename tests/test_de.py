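"""TMM factors, NB dispersion, exact conditional test, BH, DE calls."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from neomir.de import (
    bh_fdr,
    call_de,
    estimate_dispersion,
    exact_test_table,
    _exact_pvalue,
    nb_exact_test,
    tmm_factors,
)
from neomir.simulate.counts import simulate_two_group_counts


# ---------------------------------------------------------------------------
# TMM

def test_tmm_identical_columns_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.poisson(50, size=400)
    counts = pd.DataFrame({"a": col, "b": col, "c": col})
    nf = tmm_factors(counts)
    assert np.allclose(nf.factors, 1.0)


def test_tmm_factors_have_unit_geometric_mean():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.poisson(30, size=(300, 5)))
    nf = tmm_factors(counts)
    assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-9)
    assert (nf.factors > 0).all()


def test_tmm_recovers_pure_depth_doubling_within_one_percent():
    # B sequenced twice as deep with no composition change: after dividing
    # by effective library size (lib * factor) expression equalizes.
    rng = np.random.default_rng(2)
    base = rng.lognormal(3.0, 1.0, size=1000)
    a = rng.poisson(base * 20)
    b = rng.poisson(base * 40)
    counts = pd.DataFrame({"a": a, "b": b})
    nf = tmm_factors(counts)
    eff = counts.sum(axis=0) * nf.factors
    ratio = (counts["b"] / eff["b"]).mean() / (counts["a"] / eff["a"]).mean()
    assert abs(ratio - 1.0) < 0.01


def test_tmm_invariant_to_gene_order():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.poisson(40, size=(200, 4)))
    shuffled = counts.sample(frac=1.0, random_state=7)
    assert np.allclose(tmm_factors(counts).factors,
                       tmm_factors(shuffled).factors)


def test_tmm_no_shared_positive_genes_rejected():
    counts = pd.DataFrame({"a": [5, 0, 9, 3], "b": [0, 7, 0, 0]})
    with pytest.raises(ValueError, match="shares no expressed"):
        tmm_factors(counts)


# ---------------------------------------------------------------------------
# dispersion estimation

def test_poisson_data_yields_near_zero_common_dispersion():
    rng = np.random.default_rng(4)
    counts, groups = simulate_two_group_counts(rng, 200, 100.0, 0.0)
    est = estimate_dispersion(counts, groups)
    assert est.common <= 0.05


def test_dispersion_recovery_within_thirty_percent():
    estimates = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        counts, groups = simulate_two_group_counts(rng, 200, 100.0, 0.2)
        estimates.append(estimate_dispersion(counts, groups).common)
    assert abs(np.mean(estimates) - 0.2) / 0.2 < 0.3
    assert all(abs(e - 0.2) / 0.2 < 0.5 for e in estimates)


def test_infinite_prior_weight_pulls_tagwise_to_common():
    rng = np.random.default_rng(5)
    counts, groups = simulate_two_group_counts(rng, 100, 80.0, 0.15)
    est = estimate_dispersion(counts, groups, prior_weight=1e9)
    assert np.allclose(est.tagwise, est.common, rtol=1e-6)


def test_singleton_groups_fall_back_with_warning(caplog):
    counts = pd.DataFrame({"a": [10, 20], "b": [12, 18]})
    with caplog.at_level("WARNING"):
        est = estimate_dispersion(counts, np.array(["x", "y"]))
    assert est.common == pytest.approx(0.1)
    assert "singleton" in caplog.text


# ---------------------------------------------------------------------------
# exact test

def test_equal_group_sums_give_p_one():
    assert _exact_pvalue(25, 25, 3, 3, 0.1) == pytest.approx(1.0)


def _binomial_oracle(s1: int, s2: int, n1: int, n2: int) -> float:
    """Exact-fraction conditional binomial two-sided p by enumeration."""
    t = s1 + s2
    probs = [
        Fraction(comb(t, a)) * Fraction(n1, n1 + n2) ** a
        * Fraction(n2, n1 + n2) ** (t - a)
        for a in range(t + 1)
    ]
    obs = probs[s1]
    return float(sum(p for p in probs if p <= obs))


@pytest.mark.parametrize("s1,s2,n1,n2", [
    (3, 10, 3, 3), (0, 12, 3, 3), (20, 30, 3, 3), (7, 7, 2, 3),
    (1, 40, 4, 2), (25, 25, 3, 3),
])
def test_zero_dispersion_reduces_to_binomial_enumeration(s1, s2, n1, n2):
    assert _exact_pvalue(s1, s2, n1, n2, 0.0) == \
        pytest.approx(_binomial_oracle(s1, s2, n1, n2), abs=1e-9)


def test_exact_test_symmetric_under_group_swap():
    rng = np.random.default_rng(6)
    pseudo = rng.poisson(60, size=(50, 6)).astype(float)
    groups = np.array([0, 0, 0, 1, 1, 1])
    p1 = nb_exact_test(pseudo, groups, 0.1)
    p2 = nb_exact_test(pseudo[:, ::-1], groups, 0.1)
    assert np.allclose(p1, p2)


def test_all_zero_gene_has_p_one():
    pseudo = np.zeros((1, 6))
    p = nb_exact_test(pseudo, np.array([0, 0, 0, 1, 1, 1]), 0.1)
    assert p[0] == 1.0


def test_null_pipeline_type_one_error_calibrated():
    rng = np.random.default_rng(7)
    counts, groups = simulate_two_group_counts(rng, 2000, 200.0, 0.1)
    table = exact_test_table(counts, groups)
    rate = float((table["pvalue"] < 0.05).mean())
    # 99% binomial band around 0.05 at n = 2000
    band = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
    assert 0.05 - band <= rate <= 0.05 + band


# ---------------------------------------------------------------------------
# BH and the decision rule

def test_bh_hand_example():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_and_degenerate():
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)


def test_bh_dominates_p_and_is_monotone():
    rng = np.random.default_rng(8)
    p = rng.uniform(size=100)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_fdr([0.1, np.nan])


@pytest.mark.parametrize(
    "log2fc,fdr,expected_de,expected_dir",
    [
        (1.0, 0.04, True, "up"),          # FC 2.0, significant
        (np.log2(1.5), 0.01, False, "up"),  # FC exactly 1.5: strict >
        (2.0, 0.05, False, "up"),          # FDR exactly 0.05: strict <
        (-1.5, 0.001, True, "down"),
    ],
)
def test_call_de_strict_boundaries(log2fc, fdr, expected_de, expected_dir):
    is_de, direction = call_de(log2fc, fdr)
    assert is_de is expected_de
    assert direction == expected_dir


# ---------------------------------------------------------------------------
# recovery and sign convention

def test_planted_fold_changes_recovered_with_controlled_fdr():
    recalls, efdrs = [], []
    for seed in range(10):
        rng = np.random.default_rng(5000 + seed)
        n = 300
        lfc = np.zeros(n)
        de_idx = rng.choice(n, 30, replace=False)
        lfc[de_idx] = rng.choice([-2.0, 2.0], size=30)
        counts, groups = simulate_two_group_counts(rng, n, 200.0, 0.1,
                                                   log2fc=lfc)
        table = exact_test_table(counts, groups)
        called = set(np.nonzero(table["is_de"].to_numpy())[0])
        true = set(de_idx.tolist())
        recalls.append(len(called & true) / len(true))
        efdrs.append(len(called - true) / max(len(called), 1))
    assert np.mean(recalls) >= 0.80
    assert np.mean(efdrs) <= 0.10


def test_log2fc_sign_round_trips_with_generator_truth():
    rng = np.random.default_rng(9)
    lfc = np.array([2.0, -2.0] + [0.0] * 48)
    counts, groups = simulate_two_group_counts(rng, 50, 300.0, 0.05,
                                               log2fc=lfc)
    table = exact_test_table(counts, groups)
    assert table["log2fc"].iloc[0] > 0 and table["direction"].iloc[0] == "up"
    assert table["log2fc"].iloc[1] < 0 and table["direction"].iloc[1] == "down"
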
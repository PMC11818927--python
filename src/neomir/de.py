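"""Pre- vs postnatal differential expression within one tissue.

The workflow mirrors the classic count-based small-sample pipeline:
between-sample normalization by the trimmed mean of M-values (TMM),
quantile-adjusted equalization of library sizes, conditional
maximum-likelihood estimation of a common negative-binomial dispersion with
empirical-Bayes shrinkage toward it per miRNA, an exact conditional NB test
on the group sums, and Benjamini-Hochberg correction. A miRNA is called DE
when its fold change exceeds 1.5 (either direction, strict) and its FDR is
below 0.05 (strict).

The dispersion and exact-test internals are re-implementations with
documented simplifications (grid/scalar maximization, fixed shrinkage
weight); they are validated by calibration and recovery properties rather
than numerical identity with any particular implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.05
#: shrinkage weight of the common conditional likelihood in tagwise fits
DEFAULT_PRIOR_WEIGHT = 10.0
#: dispersion used when no group has replicates
FALLBACK_DISPERSION = 0.1


# ---------------------------------------------------------------------------
# TMM normalization

@dataclass
class NormalizationFactors:
    factors: pd.Series  # per-sample TMM factor, geometric mean 1
    reference: str


def tmm_factors(
    counts: pd.DataFrame | CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference is the sample whose 75th expression percentile is closest
    to the mean 75th percentile; M and A values are computed on miRNAs
    positive in both samples, doubly trimmed (30% on M, 5% on A), and
    averaged with inverse approximate-variance weights. Factors are
    rescaled to geometric mean 1.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref_j], lib[ref_j]
    for j in range(y.shape[1]):
        if j == ref_j:
            continue
        yj, nj = y[:, j], lib[j]
        keep = (yj > 0) & (yr > 0)
        if not keep.any():
            raise ValueError(
                f"sample {counts.columns[j]!r} shares no expressed miRNA with "
                f"reference {counts.columns[ref_j]!r}"
            )
        pj, pr = yj[keep] / nj, yr[keep] / nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (nj - yj[keep]) / (nj * yj[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        n = len(M)
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        sel = (
            (rank_m >= lo_m) & (rank_m <= n + 1 - lo_m)
            & (rank_a >= lo_a) & (rank_a <= n + 1 - lo_a)
        )
        if sel.any() and w[sel].sum() > 0:
            factors[j] = 2.0 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.columns), reference=counts.columns[ref_j]
    )


# ---------------------------------------------------------------------------
# quantile adjustment to a common library size

def q2qnbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, phi: float
) -> np.ndarray:
    """Quantile-map NB counts between mean regimes (normal/gamma average)."""
    x = np.asarray(x, dtype=float)
    input_mean = np.maximum(np.asarray(input_mean, dtype=float), 1e-8)
    output_mean = np.maximum(np.asarray(output_mean, dtype=float), 1e-8)
    ri = 1.0 + phi * input_mean
    ro = 1.0 + phi * output_mean
    vi = input_mean * ri
    vo = output_mean * ro
    q_normal = output_mean + np.sqrt(vo / vi) * (x - input_mean)
    with np.errstate(invalid="ignore"):
        p = stats.gamma.cdf(x, a=input_mean / ri, scale=ri)
        q_gamma = stats.gamma.ppf(p, a=output_mean / ro, scale=ro)
    q_gamma = np.where(np.isfinite(q_gamma), q_gamma, q_normal)
    return np.maximum(0.5 * (q_normal + q_gamma), 0.0)


def equalize_library_sizes(
    y: np.ndarray, groups: np.ndarray, lib: np.ndarray, phi: float
) -> tuple[np.ndarray, float]:
    """Pseudo-counts on a common library size (geometric mean of libs)."""
    common = float(np.exp(np.mean(np.log(lib))))
    pseudo = np.empty_like(y, dtype=float)
    for g in np.unique(groups):
        cols = np.nonzero(groups == g)[0]
        abundance = y[:, cols].sum(axis=1) / lib[cols].sum()
        for j in cols:
            pseudo[:, j] = q2qnbinom(
                y[:, j], abundance * lib[j], abundance * common, phi
            )
    return pseudo, common


# ---------------------------------------------------------------------------
# conditional log-likelihood and dispersion estimation

def _group_cll(y: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene conditional NB log-likelihood for one group (genes x reps).

    Conditional on the gene's group total, assuming equal means; for
    phi -> 0 this tends to the multinomial (Poisson) limit.
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    if n < 2:
        return np.zeros(y.shape[0])
    if phi < 1e-10:
        # Poisson limit: conditional is multinomial with equal cell probs
        return (
            gammaln(z + 1) - gammaln(y + 1).sum(axis=1) - z * np.log(n)
        )
    r = 1.0 / phi
    return (
        gammaln(y + r).sum(axis=1)
        - y.shape[1] * gammaln(r)
        - gammaln(y + 1).sum(axis=1)
        - (gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1))
    )


def _total_cll(pseudo: np.ndarray, groups: np.ndarray, phi: float) -> np.ndarray:
    out = np.zeros(pseudo.shape[0])
    for g in np.unique(groups):
        cols = np.nonzero(groups == g)[0]
        if len(cols) >= 2:
            out += _group_cll(pseudo[:, cols], phi)
    return out


@dataclass
class DispersionEstimate:
    common: float
    tagwise: np.ndarray
    pseudo: np.ndarray
    common_lib: float


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    factors: pd.Series | None = None,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
) -> DispersionEstimate:
    """Common and shrunken per-miRNA NB dispersion.

    The common dispersion maximizes the summed conditional log-likelihood
    of quantile-adjusted pseudo-counts; tagwise values maximize the
    per-gene conditional likelihood plus ``prior_weight`` times the average
    likelihood (shrinkage toward the common value). When every group is a
    singleton the estimator cannot run and a documented fixed dispersion is
    returned with a warning.
    """
    y = counts.to_numpy(dtype=float)
    groups = np.asarray(groups)
    lib = y.sum(axis=0)
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    sizes = [np.sum(groups == g) for g in np.unique(groups)]
    if max(sizes) < 2:
        logger.warning(
            "all groups are singletons; falling back to fixed dispersion %.3g",
            FALLBACK_DISPERSION,
        )
        pseudo, common = equalize_library_sizes(y, groups, lib, FALLBACK_DISPERSION)
        return DispersionEstimate(
            FALLBACK_DISPERSION,
            np.full(y.shape[0], FALLBACK_DISPERSION),
            pseudo,
            common,
        )

    phi = 0.1  # starting value; two rounds of pseudo-count refinement
    pseudo, common_lib = equalize_library_sizes(y, groups, lib, phi)
    for _ in range(2):
        def neg_total(log_phi: float) -> float:
            return -float(np.sum(_total_cll(pseudo, groups, 10.0 ** log_phi)))

        res = optimize.minimize_scalar(
            neg_total, bounds=(-8.0, 1.0), method="bounded",
            options={"xatol": 1e-4},
        )
        phi = float(10.0 ** res.x)
        pseudo, common_lib = equalize_library_sizes(y, groups, lib, phi)

    # tagwise: grid around the common value, shrunken by the average CLL
    grid = phi * 2.0 ** np.linspace(-8.0, 8.0, 33)
    cll = np.stack([_total_cll(pseudo, groups, g) for g in grid], axis=1)
    score = cll + prior_weight * cll.mean(axis=0)[None, :]
    tagwise = grid[np.argmax(score, axis=1)]
    return DispersionEstimate(phi, tagwise, pseudo, common_lib)


# ---------------------------------------------------------------------------
# exact conditional NB test

def _exact_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional p for group sums (equal library sizes).

    Sums the probability of all splits of the conditional total that are at
    most as probable as the observed one.
    """
    t = s1 + s2
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    frac1 = n1 / (n1 + n2)
    if phi < 1e-8:
        logp = stats.binom.logpmf(a, t, frac1)
    else:
        m1, m2 = t * frac1, t * (1.0 - frac1)
        r1, r2 = n1 / phi, n2 / phi
        lp1 = stats.nbinom.logpmf(a, r1, r1 / (r1 + m1))
        lp2 = stats.nbinom.logpmf(t - a, r2, r2 / (r2 + m2))
        logp = lp1 + lp2
        logp = logp - logp.max()
    p_all = np.exp(logp)
    obs = p_all[s1]
    return float(min(1.0, p_all[p_all <= obs * (1.0 + 1e-12)].sum() / p_all.sum()))


def nb_exact_test(
    pseudo: np.ndarray,
    groups: np.ndarray,
    dispersion: np.ndarray | float,
) -> np.ndarray:
    """Per-gene exact conditional NB p-values on equalized pseudo-counts."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exact test needs exactly 2 groups, got {len(labels)}")
    cols1 = np.nonzero(groups == labels[0])[0]
    cols2 = np.nonzero(groups == labels[1])[0]
    s1 = np.rint(pseudo[:, cols1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(pseudo[:, cols2].sum(axis=1)).astype(np.int64)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (pseudo.shape[0],))
    return np.array(
        [
            _exact_pvalue(int(a), int(b), len(cols1), len(cols2), float(f))
            for a, b, f in zip(s1, s2, phi)
        ]
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: float,
    fdr: float,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> tuple[bool, str]:
    """(is_de, direction) under the strict FC > 1.5 and FDR < 0.05 rule."""
    if not (np.isfinite(log2fc) and np.isfinite(fdr)):
        raise ValueError("log2FC and FDR must be finite")
    is_de = bool((2.0 ** abs(log2fc) > fc_threshold) and (fdr < fdr_threshold))
    direction = "up" if log2fc > 0 else "down"
    return is_de, direction


# ---------------------------------------------------------------------------
# drivers

def exact_test_table(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
) -> pd.DataFrame:
    """TMM -> dispersion -> exact test -> BH for one two-group comparison.

    ``groups`` must contain exactly the labels "prenatal" and "postnatal";
    log2FC is postnatal vs prenatal on TMM-normalized group means with a
    0.5 pseudo-count.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    labels = set(groups)
    if labels != {"prenatal", "postnatal"}:
        raise ValueError(f"expected prenatal/postnatal groups, got {sorted(labels)}")
    sizes = groups.value_counts()
    if sizes.min() < 2:
        logger.warning("unbalanced comparison with a singleton group: %s",
                       dict(sizes))
    if sizes.min() != sizes.max():
        logger.warning("unbalanced group sizes %s", dict(sizes))

    norm = tmm_factors(counts)
    disp = estimate_dispersion(counts, groups, norm.factors, prior_weight)
    order = np.where(np.asarray(groups) == "prenatal", 0, 1)
    pvals = nb_exact_test(disp.pseudo, order, disp.tagwise)
    fdr = bh_fdr(pvals)

    lib = counts.sum(axis=0) * norm.factors
    ncounts = counts / lib * disp.common_lib
    m_pre = ncounts.loc[:, groups == "prenatal"].mean(axis=1)
    m_post = ncounts.loc[:, groups == "postnatal"].mean(axis=1)
    log2fc = np.log2((m_post + 0.5) / (m_pre + 0.5))

    calls = [call_de(l, q) for l, q in zip(log2fc, fdr)]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": [d for _, d in calls],
            "is_de": [f for f, _ in calls],
            "dispersion": disp.tagwise,
        },
        index=counts.index,
    )


def de_per_tissue(
    cm: CountMatrix,
    manifest: pd.DataFrame,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
) -> pd.DataFrame:
    """Run the pre/postnatal comparison within every tissue.

    Multiple-testing correction is applied within each tissue across
    miRNAs. Returns a long table with one row per (miRNA, tissue).
    """
    frames = []
    for tissue, sub in manifest.groupby("tissue", sort=False):
        cols = [s for s in sub["sample_id"] if s in cm.counts.columns]
        groups = sub.set_index("sample_id").loc[cols, "stage"]
        table = exact_test_table(cm.counts[cols], groups, prior_weight)
        table.insert(0, "tissue", tissue)
        frames.append(table.rename_axis("mirna_id").reset_index())
    return pd.concat(frames, ignore_index=True)
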
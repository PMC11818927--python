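"""Sample-level expression structure: correlation, PCA, clustering order.

Expression is taken as log2(RPM + 1) with per-miRNA z-scoring before PCA,
matching the standardization used for the clustering heatmaps; Pearson
correlation between samples is computed on the log scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA


def log_transform(rpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(rpm + pseudocount)


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize; constant rows are dropped (their z-score is undefined)."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    keep = sd > 0
    return expr.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of an expression table.

    Zero-variance samples get NaN against every other sample (undefined
    correlation) and 1 on the diagonal.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 miRNAs to correlate samples")
    corr = expr.corr(method="pearson")  # pandas: NaN for zero-variance pairs
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pca(
    expr_z: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with samples as observations (SVD of the centered matrix).

    ``expr_z`` is miRNA x sample; returns (sample coordinates, variance
    fractions over all computable components).
    """
    if expr_z.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if expr_z.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    X = expr_z.to_numpy().T  # samples x features
    max_comp = min(X.shape[0], X.shape[1])
    model = PCA(n_components=max_comp, svd_solver="full")
    coords = model.fit_transform(X)
    fractions = model.explained_variance_ratio_
    if n_components is not None:
        coords = coords[:, :n_components]
    coord_df = pd.DataFrame(
        coords, index=expr_z.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coord_df, fractions


def hcluster_order(
    distance: pd.DataFrame, linkage: str = "average"
) -> tuple[list[str], np.ndarray]:
    """Leaf ordering and linkage matrix for a precomputed distance table.

    The distance table must be symmetric with a zero diagonal (typically
    1 - Pearson). SciPy's ordering is deterministic with lowest-index-first
    tie handling.
    """
    d = distance.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance table contains NaN")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance table must be symmetric with zero diagonal")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return [distance.index[i] for i in leaves], Z


def correlation_distance(corr: pd.DataFrame) -> pd.DataFrame:
    d = 1.0 - corr
    np.fill_diagonal(d.values, 0.0)
    return d
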
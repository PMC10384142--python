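"""Agronomic-trait statistics: summaries, contrasts, correlations, PCA
and Ward clustering.

The table layout is accessions x traits (plant height in cm, seed weight in
g, flower-head number, seed weight per flower head in g, spine length in mm,
and plant color at harvest coded 1=green, 2=brown, 3=green-brown; the color
code is treated as numeric throughout, as the source tables do).

PCA is performed on the trait correlation matrix, since the traits carry
incommensurable units; loadings are reported as component-trait
correlations (eigenvector times the square root of its eigenvalue), each
component sign-flipped so its largest-magnitude loading is positive.
Subset-vs-population contrasts use Welch's two-sample t-test. Hierarchical
clustering is Ward linkage on Euclidean distances of z-scored traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_core import round_half_up


def summarize_traits(table: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Per-trait mean and sample SD (n-1), rounded half-up for reporting."""
    if len(table) < 2:
        raise ValueError("need at least two accessions to summarize")
    out = []
    for trait in table.columns:
        values = table[trait].dropna().to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError(f"trait {trait!r} has no observations")
        out.append(
            {
                "trait": trait,
                "mean": round_half_up(float(np.mean(values)), ndigits),
                "sd": round_half_up(float(np.std(values, ddof=1)), ndigits),
                "n": int(values.size),
            }
        )
    return pd.DataFrame(out).set_index("trait")


def subset_contrast(
    subset: pd.DataFrame, population: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch's t-test per trait between a subset and the full population.

    Returns the two group means, the two-sided p-value, and a flag column
    ('*' if p < alpha, 'NS' otherwise).
    """
    traits = [t for t in subset.columns if t in population.columns]
    if not traits:
        raise ValueError("subset and population share no traits")
    if len(subset) < 2:
        raise ValueError("subset must contain at least two accessions")
    rows = []
    for trait in traits:
        a = subset[trait].dropna().to_numpy(dtype=float)
        b = population[trait].dropna().to_numpy(dtype=float)
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                t_stat, p = 0.0, 1.0
            else:
                raise ValueError(f"trait {trait!r}: zero variance in both groups")
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "trait": trait,
                "subset_mean": float(np.mean(a)),
                "population_mean": float(np.mean(b)),
                "t": float(t_stat),
                "p": float(p),
                "flag": "*" if p < alpha else "NS",
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def pearson_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise product-moment correlations with two-sided p-values.

    p-values come from the t distribution with n-2 degrees of freedom.
    Zero-variance traits yield NaN entries (flagged by a warning in the
    returned matrix rather than an exception, so one degenerate trait does
    not void the rest of the table).
    """
    n = len(table)
    if n < 3:
        raise ValueError("need at least three accessions for correlation tests")
    traits = list(table.columns)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, ti in enumerate(traits):
        for j in range(i + 1, len(traits)):
            tj = traits[j]
            x = table[ti].to_numpy(dtype=float)
            y = table[tj].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[ti, tj] = r.loc[tj, ti] = rij
            p.loc[ti, tj] = p.loc[tj, ti] = pij
    return r, p


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame  # traits x components, as correlations
    scores: pd.DataFrame  # accessions x components


def pca(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Correlation-matrix PCA with component-trait correlation loadings.

    Eigenvalues of the trait correlation matrix are returned in decreasing
    order; explained variance is eigenvalue / n_traits x 100. Components
    whose eigenvalue is numerically zero (rank deficiency) are dropped.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more accessions than traits for a stable PCA")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [t for t, s in zip(table.columns, sds) if s == 0]
        raise ValueError(f"zero-variance traits {bad} cannot be standardized")
    Z = (X - X.mean(axis=0)) / sds
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    keep = eigvals > 1e-10
    if n_components is not None:
        keep &= np.arange(p) < n_components
    eigvals_k = eigvals[keep]
    eigvecs_k = eigvecs[:, keep]
    loadings = eigvecs_k * np.sqrt(eigvals_k)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, c]))
        if loadings[pivot, c] < 0:
            loadings[:, c] *= -1
            eigvecs_k[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    variance_pct = eigvals_k / p * 100
    return PCAResult(
        eigenvalues=eigvals_k,
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comp_names),
        scores=pd.DataFrame(Z @ eigvecs_k, index=table.index, columns=comp_names),
    )


@dataclass(frozen=True)
class WardClustering:
    labels: pd.Series  # accession -> cluster id (1..k)
    linkage: np.ndarray  # scipy linkage matrix on z-scored traits


def ward_clustering(table: pd.DataFrame, k: int) -> WardClustering:
    """Ward (minimum-variance) clustering of z-scored traits, cut at k."""
    n = len(table)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    X = table.to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sds
    linkage = hierarchy.linkage(Z, method="ward")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return WardClustering(
        labels=pd.Series(labels, index=table.index, name="cluster"),
        linkage=linkage,
    )
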
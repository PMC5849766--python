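"""Pairwise correlation, Ward clustering and the composite expression score.

Validated genes are pairwise Pearson-correlated across the TNBC tumors
(insignificant pairs flagged at alpha = 0.05), the correlation matrix is
hierarchically clustered with Ward linkage on ``d = 1 - r``, and a
multi-gene *composite score* — the per-sample mean of per-gene
standardized expression over a gene set — splits the cohort into high and
low expressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

from .stats import rowwise_pearson_p

__all__ = [
    "CorrelationResult",
    "ClusterResult",
    "CompositeScore",
    "pairwise_correlation",
    "ward_cluster",
    "composite_score",
]


@dataclass
class CorrelationResult:
    """Symmetric gene-by-gene Pearson r / p matrices with significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    undefined_genes: list
    n_samples: int


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series
    leaf_order: list


@dataclass
class CompositeScore:
    scores: pd.Series
    high: pd.Series
    fraction_high: float
    rule: str


def pairwise_correlation(
    gex: pd.DataFrame,
    genes=None,
    samples=None,
    alpha: float = 0.05,
) -> CorrelationResult:
    """All-pairs Pearson correlation of gene expression vectors.

    ``gex`` is genes-by-samples; optional ``genes``/``samples`` restrict
    the matrix (typically to validated genes and TNBC samples).  Two-sided
    p-values use the t approximation; pairs involving a constant gene are
    undefined (``NaN``) and flagged insignificant.
    """
    sub = gex
    if genes is not None:
        sub = sub.loc[list(genes)]
    if samples is not None:
        sub = sub[list(samples)]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if sub.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    x = sub.to_numpy(float)
    n = x.shape[1]
    sd = x.std(axis=1)
    undefined = [g for g, s in zip(sub.index, sd) if s == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(x)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    p = rowwise_pearson_p(r, n)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(r)] = np.nan
    sig = (p <= alpha) & ~np.isnan(p)
    idx = sub.index
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        significant=pd.DataFrame(sig, index=idx, columns=idx),
        undefined_genes=undefined,
        n_samples=n,
    )


def ward_cluster(
    corr: CorrelationResult | pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
) -> ClusterResult:
    """Ward-linkage hierarchical clustering of a correlation matrix.

    Distance is ``1 - r``; undefined correlations are imputed to r = 0
    with a warning.  Flat clusters are cut either to ``n_clusters`` or at
    ``height`` (default: 2 clusters).  Leaf order is deterministic.
    """
    r = corr.r if isinstance(corr, CorrelationResult) else corr
    genes = list(r.index)
    mat = r.to_numpy(float).copy()
    if np.isnan(mat).any():
        warnings.warn("undefined correlations imputed to r = 0 for clustering")
        mat = np.where(np.isnan(mat), 0.0, mat)
    d = 1.0 - mat
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    if height is not None:
        flat = hierarchy.fcluster(z, t=height, criterion="distance")
    else:
        flat = hierarchy.fcluster(z, t=n_clusters or 2, criterion="maxclust")
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        linkage=z,
        labels=pd.Series(flat, index=genes, name="cluster"),
        leaf_order=[genes[i] for i in order],
    )


def composite_score(
    gex: pd.DataFrame,
    genes,
    samples=None,
    rule: str = "mixture",
    quantile: float | None = None,
    random_state: int = 0,
) -> CompositeScore:
    """Mean per-gene z-score over a gene set, split into high/low groups.

    Expression is standardized per gene across the chosen samples (a
    constant gene standardizes to 0 with a warning) and averaged over the
    set.  The high/low split is config-exposed: a two-component Gaussian
    mixture on the scores (default, ``high`` = component with the larger
    mean), the cohort median, or a fixed quantile.
    """
    genes = [g for g in genes if g in gex.index]
    if not genes:
        raise ValueError("gene set empty or absent from matrix")
    sub = gex.loc[genes]
    if samples is not None:
        sub = sub[list(samples)]
    x = sub.to_numpy(float)
    mu = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        warnings.warn("constant gene(s) in composite set standardized to 0")
    z = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    scores = pd.Series(np.nanmean(z, axis=0), index=sub.columns, name="composite")

    s = scores.dropna()
    if rule == "mixture":
        gm = GaussianMixture(
            n_components=2, n_init=5, random_state=random_state
        ).fit(s.to_numpy()[:, None])
        hi_comp = int(np.argmax(gm.means_.ravel()))
        labels = gm.predict(s.to_numpy()[:, None]) == hi_comp
        high = pd.Series(labels, index=s.index)
    elif rule == "median":
        high = s > s.median()
    elif rule == "quantile":
        if quantile is None:
            raise ValueError("quantile rule requires a quantile")
        high = s > s.quantile(quantile)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    high = high.reindex(scores.index, fill_value=False)
    return CompositeScore(
        scores=scores,
        high=high,
        fraction_high=float(high[s.index].mean()),
        rule=rule,
    )
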
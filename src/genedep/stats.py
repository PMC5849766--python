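"""Shared statistical helpers: BH adjustment and row-wise rank correlation."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "rowwise_spearman", "rowwise_pearson_p"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``NaN`` entries are passed through unadjusted and do not count toward
    the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, x)


def rowwise_spearman(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and large-sample p for each row pair of two matrices.

    Rows with zero variance in either matrix yield ``NaN`` rho and p.
    The p-value uses the standard t approximation with ``n - 2`` degrees of
    freedom, matching :func:`scipy.stats.spearmanr`.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    n = a.shape[1]
    ra, rb = _rank_rows(a), _rank_rows(b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (ra * rb).sum(axis=1) / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    p = _t_two_sided(rho, n)
    return rho, p


def _t_two_sided(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation r at sample size n via the t transform."""
    if n <= 2:
        return np.full(np.shape(r), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    # perfectly monotone vectors: p -> 0
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))


def rowwise_pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson correlations via the t approximation."""
    return _t_two_sided(np.asarray(r, float), n)
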
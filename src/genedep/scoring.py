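"""Candidate-addiction identification: filters, feature blocks and scoring.

The scoring engine ranks genes for evidence of being a tumor addiction by
combining five feature *blocks*:

A. expression (fold change and significance of TNBC vs normal differential
   expression, fraction of TNBC samples over twice the normal level),
B. copy number (gain frequency, mean copy number, optional focality),
C. copy-number/expression association (cis Spearman correlation and a
   multi Mann–Whitney U test of expression across copy-number states),
D. clinical annotation (differential expression between recurrent and
   non-recurrent TNBC),
E. gene annotation (druggability, kinome, membranome, COSMIC, secretome,
   CAN-gene flags).

Each feature value is *binned* against two thresholds into a 0 / 1 / 2
score multiplied by the feature's weight; per-block sums are capped at the
block limit and divided by it, giving normalized block scores in [0, 1]
whose sum (range [0, 5]) ranks the genes.

Two upstream filters restrict the copy-number-driven arm: a gain filter
(copy number >= 2.38 in at least 10% of TNBC samples) and a cis-correlation
filter (Spearman rho >= 0.3 at p <= 0.01).  A complementary
expression-centered arm selects genes whose mean TNBC expression is more
than 2-fold the normal-epithelium mean.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profile import GeneCentricProfile
from .stats import bh_adjust, rowwise_spearman

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "BlockSpec",
    "BLOCKS",
    "cn_gain_filter",
    "cis_correlation_filter",
    "cn_state_expression_test",
    "differential_expression",
    "expression_centered_candidates",
    "bin_feature_score",
    "score_blocks",
    "build_platform",
    "default_feature_specs",
    "default_block_specs",
    "assemble_candidates",
]

BLOCKS = ("A_gex", "B_cn", "C_cn_gex", "D_clinical", "E_annotation")


@dataclass(frozen=True)
class FeatureSpec:
    """Binned-scoring configuration for one feature.

    A value below ``threshold1`` scores 0; in ``[threshold1, threshold2]``
    it scores ``weight``; above ``threshold2`` it scores ``2 * weight``
    (reversed when ``direction == "smaller"``).
    """

    name: str
    block: str
    threshold1: float
    threshold2: float
    weight: float = 1.0
    direction: str = "larger"

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.threshold1 > self.threshold2:
            raise ValueError("threshold1 must be <= threshold2")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.direction not in ("larger", "smaller"):
            raise ValueError("direction must be 'larger' or 'smaller'")


@dataclass(frozen=True)
class BlockSpec:
    """Block identifier and its cap (the 'block limit')."""

    block: str
    cap: float

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")
        if self.cap <= 0:
            raise ValueError("cap must be positive")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def cn_gain_filter(
    profile: GeneCentricProfile,
    cn_threshold: float = 2.38,
    freq_threshold: float = 0.10,
) -> pd.DataFrame:
    """Genes gained (CN >= ``cn_threshold``) in >= ``freq_threshold`` of TNBC.

    Both comparisons are inclusive.  Returns a per-gene frame with columns
    ``gain_freq`` and boolean ``passed``.
    """
    tnbc = profile.tnbc_samples
    if not tnbc:
        raise ValueError("no TNBC samples in profile")
    cn = profile.cn[tnbc]
    n = cn.notna().sum(axis=1)
    gains = (cn >= cn_threshold).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = gains / n.replace(0, np.nan)
    return pd.DataFrame(
        {"gain_freq": freq, "passed": freq >= freq_threshold},
        index=profile.genes,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho at tiny n."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def cis_correlation_filter(
    profile: GeneCentricProfile,
    genes: Sequence[str] | None = None,
    rho_min: float = 0.30,
    p_max: float = 0.01,
    method: str = "auto",
) -> pd.DataFrame:
    """Spearman correlation of CN vs expression across TNBC samples.

    ``passed`` is true iff rho >= ``rho_min`` and p <= ``p_max``.  P-values
    use the large-sample t approximation; with ``method='auto'`` and eight
    or fewer samples (or ``method='exact'``) an exact permutation p is
    computed instead.  Genes with a constant CN or expression vector are
    flagged ``undefined`` and never pass.
    """
    if genes is None:
        genes = list(profile.genes)
    tnbc = profile.tnbc_samples
    cn = profile.cn.loc[genes, tnbc]
    gex = profile.gex.loc[genes, tnbc]
    # restrict to samples with both measurements for every gene (column-wise
    # completeness keeps the row-wise fast path valid)
    ok = cn.notna().all(axis=0) & gex.notna().all(axis=0)
    cn, gex = cn.loc[:, ok], gex.loc[:, ok]
    n = cn.shape[1]
    if n < 3:
        raise ValueError("need >= 3 TNBC samples with CN and expression")

    rho, p = rowwise_spearman(cn.to_numpy(), gex.to_numpy())
    if method == "exact" or (method == "auto" and n <= 8):
        for i, g in enumerate(genes):
            if not np.isnan(rho[i]):
                p[i] = _spearman_exact_p(
                    cn.to_numpy()[i], gex.to_numpy()[i], rho[i]
                )
    undefined = np.isnan(rho)
    passed = (~undefined) & (rho >= rho_min) & (p <= p_max)
    return pd.DataFrame(
        {"rho": rho, "p": p, "passed": passed, "undefined": undefined},
        index=pd.Index(genes, name="gene"),
    )


# ---------------------------------------------------------------------------
# Copy-number-state expression test
# ---------------------------------------------------------------------------

#: CN-state boundaries: loss < 1.5 <= neutral < 2.38 <= gain < 4 <= amplification
DEFAULT_STATE_BOUNDS = (1.5, 2.38, 4.0)


def cn_state_expression_test(
    profile: GeneCentricProfile,
    genes: Sequence[str] | None = None,
    bounds: tuple[float, float, float] = DEFAULT_STATE_BOUNDS,
    min_per_state: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multi Mann–Whitney U of expression across copy-number states.

    CN over TNBC samples is discretized to {loss, neutral, gain,
    amplification}; each populated non-neutral state is compared with the
    neutral state by a two-sided Mann–Whitney U on expression.  The
    per-gene p is the minimum across comparisons, Bonferroni-scaled by the
    number of comparisons, then BH-adjusted across genes; ``significant``
    iff adjusted p < ``alpha``.  Genes without two populated states return
    ``NaN``.
    """
    if genes is None:
        genes = list(profile.genes)
    tnbc = profile.tnbc_samples
    lo, mid, hi = bounds
    cn = profile.cn.loc[genes, tnbc].to_numpy()
    gex = profile.gex.loc[genes, tnbc].to_numpy()

    p_raw = np.full(len(genes), np.nan)
    n_states = np.zeros(len(genes), dtype=int)
    for i in range(len(genes)):
        c, e = cn[i], gex[i]
        ok = ~np.isnan(c) & ~np.isnan(e)
        c, e = c[ok], e[ok]
        state = np.digitize(c, [lo, mid, hi])  # 0 loss, 1 neutral, 2 gain, 3 amp
        groups = {
            s: e[state == s]
            for s in range(4)
            if (state == s).sum() >= min_per_state
        }
        n_states[i] = len(groups)
        if 1 not in groups or len(groups) < 2:
            continue
        neutral = groups[1]
        ps = []
        for s, vals in groups.items():
            if s == 1:
                continue
            if np.ptp(np.concatenate([vals, neutral])) == 0:
                ps.append(1.0)
                continue
            ps.append(
                sps.mannwhitneyu(vals, neutral, alternative="two-sided").pvalue
            )
        if ps:
            p_raw[i] = min(1.0, min(ps) * len(ps))

    p_adj = bh_adjust(p_raw)
    return pd.DataFrame(
        {
            "p_raw": p_raw,
            "p_adj": p_adj,
            "n_states": n_states,
            "significant": (p_adj < alpha) & ~np.isnan(p_adj),
        },
        index=pd.Index(genes, name="gene"),
    )


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    profile: GeneCentricProfile,
    groups_a: str | Sequence[str] = "TNBC",
    groups_b: str | Sequence[str] = "normal",
) -> pd.DataFrame:
    """Per-gene fold change and Welch-t significance between two groups.

    Fold change is the ratio of geometric group means (``2**delta`` of the
    log2 means).  P-values come from Welch's t on log2 values with BH
    adjustment across genes; degenerate zero-variance genes report ``NaN``.
    """
    if isinstance(groups_a, str):
        groups_a = (groups_a,)
    if isinstance(groups_b, str):
        groups_b = (groups_b,)
    a = profile.gex[profile.group_samples(*groups_a)]
    b = profile.gex[profile.group_samples(*groups_b)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = sps.ttest_ind(
            a.to_numpy(), b.to_numpy(), axis=1, equal_var=False
        )
    p = t.pvalue
    degenerate = (a.var(axis=1).to_numpy() == 0) & (b.var(axis=1).to_numpy() == 0)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": 2.0**log2fc,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=profile.genes,
    )


def expression_centered_candidates(
    profile: GeneCentricProfile, fold_min: float = 2.0
) -> pd.DataFrame:
    """Genes whose linear-scale TNBC mean strictly exceeds ``fold_min`` x normal.

    Means are taken on the linear (un-logged) scale.  Returns a per-gene
    frame with ``linear_fold`` and boolean ``passed`` (strict ``>``).
    """
    normals = profile.normal_samples
    if not normals:
        raise ValueError("no normal samples in profile")
    tnbc = profile.tnbc_samples
    lin = 2.0**profile.gex
    mean_t = lin[tnbc].mean(axis=1)
    mean_n = lin[normals].mean(axis=1)
    fold = mean_t / mean_n
    return pd.DataFrame(
        {"linear_fold": fold, "passed": fold > fold_min}, index=profile.genes
    )


# ---------------------------------------------------------------------------
# Binned weighted scoring
# ---------------------------------------------------------------------------


def bin_feature_score(value: float, spec: FeatureSpec) -> float:
    """Three-bin weighted score of a single feature value.

    Missing values contribute 0 (logged at debug level).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        logger.debug("missing value for feature %s scored 0", spec.name)
        return 0.0
    v = float(value) if spec.direction == "larger" else -float(value)
    t1, t2 = (
        (spec.threshold1, spec.threshold2)
        if spec.direction == "larger"
        else (-spec.threshold2, -spec.threshold1)
    )
    if v < t1:
        return 0.0
    if v <= t2:
        return spec.weight
    return 2.0 * spec.weight


def score_blocks(
    features: pd.DataFrame,
    feature_specs: Sequence[FeatureSpec],
    block_specs: Sequence[BlockSpec],
) -> pd.DataFrame:
    """Score and rank genes from a per-gene feature table.

    ``features`` holds one row per gene and one column per feature named in
    ``feature_specs`` (missing columns/values contribute 0).  Per block the
    binned feature scores are summed, capped at the block's cap and divided
    by it; the total is the sum of normalized block scores.  Ranking is by
    total descending with deterministic ties broken by the C, A and B block
    scores and finally by gene identifier.
    """
    caps = {b.block: b.cap for b in block_specs}
    for spec in feature_specs:
        if spec.block not in caps:
            raise ValueError(
                f"feature {spec.name!r} references block {spec.block!r} "
                "with no BlockSpec"
            )

    out = pd.DataFrame(index=features.index.copy())
    block_raw = {b: np.zeros(len(features)) for b in caps}
    for spec in feature_specs:
        col = features[spec.name] if spec.name in features else pd.Series(
            np.nan, index=features.index
        )
        scores = np.array([bin_feature_score(v, spec) for v in col])
        out[f"score::{spec.name}"] = scores
        block_raw[spec.block] += scores

    total = np.zeros(len(features))
    for block, cap in caps.items():
        raw = block_raw[block]
        norm = np.minimum(raw, cap) / cap
        out[f"block_raw::{block}"] = raw
        out[f"block_norm::{block}"] = norm
        total += norm
    out["total"] = total

    def _norm(block: str) -> pd.Series:
        col = f"block_norm::{block}"
        return out[col] if col in out else pd.Series(0.0, index=out.index)

    order = pd.DataFrame(
        {
            "total": -out["total"].to_numpy(),
            "c": -_norm("C_cn_gex").to_numpy(),
            "a": -_norm("A_gex").to_numpy(),
            "b": -_norm("B_cn").to_numpy(),
            "gene_id": out.index.astype(str),
        },
        index=out.index,
    ).sort_values(["total", "c", "a", "b", "gene_id"], kind="mergesort")
    out = out.loc[order.index]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Default platform
# ---------------------------------------------------------------------------

ANNOTATION_FLAGS = (
    "druggable",
    "kinome",
    "membranome",
    "cosmic",
    "secretome",
    "can_gene",
)


def build_platform(
    profile: GeneCentricProfile,
    annotations: pd.DataFrame | None = None,
    focality: pd.Series | None = None,
    cn_threshold: float = 2.38,
) -> pd.DataFrame:
    """Compute the per-gene feature table backing the five scoring blocks.

    ``annotations`` is an optional per-gene 0/1 flag table with columns
    from :data:`ANNOTATION_FLAGS`; ``focality`` an optional precomputed
    per-gene focality column.  Absent features contribute 0 at scoring.
    """
    de_tn = differential_expression(profile, "TNBC", "normal")
    de_tumor = differential_expression(profile, ("TNBC", "HER2", "ER"), "normal")
    gains = cn_gain_filter(profile, cn_threshold=cn_threshold)
    cis = cis_correlation_filter(profile)
    states = cn_state_expression_test(profile)

    tnbc = profile.tnbc_samples
    normals = profile.normal_samples
    lin_norm_mean = (2.0**profile.gex[normals]).mean(axis=1)
    over2x = (
        (2.0**profile.gex[tnbc]).gt(2.0 * lin_norm_mean, axis=0).mean(axis=1)
    )

    feats = pd.DataFrame(index=profile.genes)
    feats["tnbc_normal_log2fc"] = de_tn["log2fc"]
    feats["tnbc_normal_neglog10_padj"] = -np.log10(
        np.clip(de_tn["p_adj"], 1e-300, None)
    )
    feats["tumor_normal_log2fc"] = de_tumor["log2fc"]
    feats["frac_tnbc_over_2x_normal"] = over2x
    feats["tnbc_gain_freq"] = gains["gain_freq"]
    feats["tnbc_mean_cn"] = profile.cn[tnbc].mean(axis=1)
    feats["cn_focality"] = (
        focality.reindex(profile.genes) if focality is not None else np.nan
    )
    feats["cis_spearman_rho"] = cis["rho"]
    feats["cn_state_neglog10_padj"] = -np.log10(
        np.clip(states["p_adj"], 1e-300, None)
    )

    if len(tnbc) >= 4 and "recurrence" in profile.samples.columns:
        rec_flag = profile.samples.loc[tnbc, "recurrence"].astype(bool)
        rec = [s for s in tnbc if rec_flag[s]]
        non = [s for s in tnbc if not rec_flag[s]]
        if len(rec) >= 2 and len(non) >= 2:
            d = profile.gex[rec].mean(axis=1) - profile.gex[non].mean(axis=1)
            t = sps.ttest_ind(
                profile.gex[rec].to_numpy(),
                profile.gex[non].to_numpy(),
                axis=1,
                equal_var=False,
            )
            feats["recurrence_abs_log2fc"] = d.abs()
            feats["recurrence_neglog10_p"] = -np.log10(
                np.clip(t.pvalue, 1e-300, None)
            )

    if annotations is not None:
        for flag in ANNOTATION_FLAGS:
            if flag in annotations.columns:
                feats[flag] = (
                    annotations[flag].reindex(profile.genes).fillna(0).astype(float)
                )
    return feats


def default_feature_specs() -> list[FeatureSpec]:
    """Shipped feature table mirroring the five-block structure.

    Thresholds and weights are package defaults (the published per-feature
    weights live in supplementary material not reproduced here); users can
    load their own via :func:`genedep.io.load_specs`.
    """
    F = FeatureSpec
    return [
        F("tnbc_normal_log2fc", "A_gex", 1.0, 2.0, weight=2.0),
        F("tnbc_normal_neglog10_padj", "A_gex", 1.3, 3.0),
        F("tumor_normal_log2fc", "A_gex", 1.0, 2.0),
        F("frac_tnbc_over_2x_normal", "A_gex", 0.25, 0.50),
        F("tnbc_gain_freq", "B_cn", 0.10, 0.30, weight=2.0),
        F("tnbc_mean_cn", "B_cn", 2.38, 3.0),
        F("cn_focality", "B_cn", 0.5, 1.5),
        F("cis_spearman_rho", "C_cn_gex", 0.30, 0.60, weight=2.0),
        F("cn_state_neglog10_padj", "C_cn_gex", 1.3, 3.0, weight=2.0),
        F("recurrence_abs_log2fc", "D_clinical", 0.5, 1.0),
        F("recurrence_neglog10_p", "D_clinical", 1.3, 2.0),
        F("druggable", "E_annotation", 0.5, 1.5),
        F("kinome", "E_annotation", 0.5, 1.5),
        F("membranome", "E_annotation", 0.5, 1.5),
        F("cosmic", "E_annotation", 0.5, 1.5),
        F("secretome", "E_annotation", 0.5, 1.5),
        F("can_gene", "E_annotation", 0.5, 1.5),
    ]


def default_block_specs() -> list[BlockSpec]:
    return [
        BlockSpec("A_gex", 6.0),
        BlockSpec("B_cn", 4.0),
        BlockSpec("C_cn_gex", 6.0),
        BlockSpec("D_clinical", 2.0),
        BlockSpec("E_annotation", 3.0),
    ]


# ---------------------------------------------------------------------------
# Candidate assembly
# ---------------------------------------------------------------------------


def assemble_candidates(
    scorecard: pd.DataFrame,
    expression_centered: Iterable[str],
    curated: Iterable[str] | None = None,
    manual: Iterable[str] = (),
    k_top: int = 85,
) -> pd.DataFrame:
    """Union of the two identification arms with per-gene provenance.

    Arm 1 takes the top ``k_top`` genes of the scorecard ranking; arm 2
    intersects the expression-centered set with an annotation-curated list
    (all of it when no curation is supplied) and adds manual picks.
    Genes found by both arms are labelled ``both``.
    """
    arm1 = list(scorecard.index[:k_top])
    expr = set(expression_centered)
    arm2 = expr & set(curated) if curated is not None else set(expr)
    arm2 |= set(manual)
    rows = []
    for gene in sorted(set(arm1) | arm2):
        in1, in2 = gene in set(arm1), gene in arm2
        rows.append(
            (gene, "both" if (in1 and in2) else ("score" if in1 else "expression"))
        )
    return pd.DataFrame(rows, columns=["gene", "source"]).set_index("gene")
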
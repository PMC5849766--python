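"""RNAi screen analytics: normalization, NPI, plate QC and hit calling.

Viability effects are expressed as normalized percent inhibition,

    NPI(x) = (x - mu_neg) / (mu_pos - mu_neg) * 100,

where mu_pos / mu_neg are the within-plate means of the positive
(cell-killing) and negative (scrambled) controls after plate-median
normalization.  Plate quality is summarized by the Z'-factor,

    Z' = 1 - (3*SD_pos + 3*SD_neg) / (mean_pos - mean_neg),

computed in NPI space (positive controls near 100, negative near 0) and
considered valid at Z' >= 0.3.  Replicates whose well-matched Pearson r^2
against the other replicates falls below 0.5 (or that anti-correlate) are
excluded.

Three rule sets turn per-gene NPI summaries into verdicts:

* primary: a gene is a hit if it spares HMEC (NPI below threshold) while
  inhibiting at least two malignant lines, or — when it does affect
  HMEC — shows a heterogeneous effect with at least two malignant lines
  below and at least two at/above the threshold;
* top-10: validated when at least two single oligos each combine
  knockdown >= 70%, no HMEC effect and an effect in >= 2 malignant lines;
* secondary (pool deconvolution): *fail* when two or more oligos knock the
  transcript down >= 70% yet show no viability effect; otherwise
  *validated* when >= 2 oligos with knockdown >= 40% show an effect; else
  inconclusive.  The fail clause takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ControlStats",
    "ZPrimeResult",
    "HitCall",
    "OligoResult",
    "DEFAULT_NPI_THRESHOLD",
    "plate_median_normalize",
    "control_stats",
    "compute_npi",
    "annotate_npi",
    "zprime",
    "replicate_qc",
    "summarize_gene_line",
    "hit_threshold",
    "primary_hit",
    "top10_hit",
    "secondary_verdict",
    "call_primary_hits",
    "call_top10_hits",
    "call_secondary",
]

#: Fallback NPI effect threshold (%) when no control summary is supplied,
#: i.e. mean + 3 SD of the published negative-control NPI distribution.
DEFAULT_NPI_THRESHOLD = 18.01


@dataclass(frozen=True)
class ControlStats:
    """Per-plate control summaries on the normalized scale."""

    mu_pos: float
    mu_neg: float
    sd_pos: float
    sd_neg: float


@dataclass(frozen=True)
class ZPrimeResult:
    zprime: float
    valid: bool


@dataclass(frozen=True)
class HitCall:
    """Rule-engine verdict with the evidence that produced it."""

    gene: str
    rule_set: str
    verdict: str
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OligoResult:
    """Deconvoluted single-oligo result used by the top-10 rule."""

    oligo: str
    kd_pct: float
    hmec_npi: float
    line_npis: Mapping[str, float]


# ---------------------------------------------------------------------------
# Normalization and NPI
# ---------------------------------------------------------------------------


def plate_median_normalize(plates: pd.DataFrame) -> pd.DataFrame:
    """Divide each plate's wells by the median of its interior sample wells.

    Controls are scaled by the same factor.  Plates with a zero (or
    undefined) sample median are rejected.
    """
    out = plates.copy()
    out["normalized_value"] = np.nan
    for plate_id, grp in plates.groupby("plate_id"):
        samples = grp.loc[grp["reagent_type"] == "sample", "raw_value"].dropna()
        if samples.empty:
            raise ValueError(f"plate {plate_id}: no sample wells to normalize by")
        med = float(samples.median())
        if med == 0 or np.isnan(med):
            raise ValueError(f"plate {plate_id}: zero/undefined sample median")
        out.loc[grp.index, "normalized_value"] = grp["raw_value"] / med
    return out


def control_stats(
    plate: pd.DataFrame, value_col: str = "normalized_value"
) -> ControlStats:
    pos = plate.loc[plate["reagent_type"] == "pos_ctrl", value_col].dropna()
    neg = plate.loc[plate["reagent_type"] == "neg_ctrl", value_col].dropna()
    if pos.empty or neg.empty:
        raise ValueError("plate lacks positive or negative control wells")
    return ControlStats(
        mu_pos=float(pos.mean()),
        mu_neg=float(neg.mean()),
        sd_pos=float(pos.std(ddof=1)) if len(pos) > 1 else 0.0,
        sd_neg=float(neg.std(ddof=1)) if len(neg) > 1 else 0.0,
    )


def compute_npi(x, stats: ControlStats):
    """Normalized percent inhibition of ``x`` given plate control means.

    May fall below 0 or exceed 100; no clamping is applied.
    """
    if stats.mu_pos == stats.mu_neg:
        raise ValueError("NPI undefined: equal control means")
    return (np.asarray(x, float) - stats.mu_neg) / (
        stats.mu_pos - stats.mu_neg
    ) * 100.0


def annotate_npi(plates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize plates, add an ``npi`` column and per-plate QC summary.

    Returns ``(wells, plate_qc)`` where ``plate_qc`` holds one row per
    plate with control statistics, the Z'-factor in NPI space and its
    validity flag.
    """
    wells = plate_median_normalize(plates)
    wells["npi"] = np.nan
    qc_rows = []
    for plate_id, grp in wells.groupby("plate_id"):
        stats = control_stats(grp)
        npi = compute_npi(grp["normalized_value"], stats)
        wells.loc[grp.index, "npi"] = npi
        pos_npi = compute_npi(
            grp.loc[grp["reagent_type"] == "pos_ctrl", "normalized_value"], stats
        )
        neg_npi = compute_npi(
            grp.loc[grp["reagent_type"] == "neg_ctrl", "normalized_value"], stats
        )
        z = zprime(pos_npi, neg_npi)
        qc_rows.append(
            {
                "plate_id": plate_id,
                "mu_pos": stats.mu_pos,
                "mu_neg": stats.mu_neg,
                "sd_pos": stats.sd_pos,
                "sd_neg": stats.sd_neg,
                "zprime": z.zprime,
                "valid": z.valid,
            }
        )
    return wells, pd.DataFrame(qc_rows).set_index("plate_id")


def zprime(pos, neg, valid_min: float = 0.3) -> ZPrimeResult:
    """Z'-factor of a plate's control populations (no absolute value).

    Computed on control values in a space where the positive-control mean
    exceeds the negative (NPI).  Equal control means make Z' undefined and
    the plate invalid.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 values per control class")
    sep = pos.mean() - neg.mean()
    if sep == 0:
        return ZPrimeResult(np.nan, False)
    z = 1.0 - (3.0 * pos.std(ddof=1) + 3.0 * neg.std(ddof=1)) / sep
    return ZPrimeResult(float(z), bool(z >= valid_min))


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------


@dataclass
class ReplicateQC:
    kept: list
    excluded: list
    r2_matrix: pd.DataFrame
    mean_r2: float
    failed: bool


def replicate_qc(
    replicates: pd.DataFrame, r2_min: float = 0.5, mode: str = "mean"
) -> ReplicateQC:
    """Concordance filter on well-matched replicate vectors.

    ``replicates`` is a wells-by-replicates frame.  Pairwise Pearson r is
    computed on matched wells; a replicate fails when its mean r^2 against
    the *retained* replicates falls below ``r2_min`` (``mode='any'``: when
    any retained pair does), or when it anti-correlates on average — a
    negative r is treated as failing regardless of its square.  Exclusion
    is greedy: the least concordant offender is dropped and concordance
    re-evaluated, so one rogue replicate cannot drag the others below the
    cut.  A lone survivor of exclusions has no concordance support and is
    excluded too; with every replicate excluded the experiment is flagged
    failed.
    """
    if replicates.shape[1] < 2:
        raise ValueError("need >= 2 replicates")
    if mode not in ("mean", "any"):
        raise ValueError("mode must be 'mean' or 'any'")
    reps = list(replicates.columns)
    r = replicates.corr(method="pearson")
    r2 = r**2
    active = list(reps)
    excluded: list = []
    while len(active) >= 2:
        mean_r, crit = {}, {}
        for rep in active:
            others = [o for o in active if o != rep]
            mean_r[rep] = float(r.loc[rep, others].mean())
            if mode == "mean":
                crit[rep] = float(r2.loc[rep, others].mean())
            else:
                crit[rep] = float(r2.loc[rep, others].min())
        offenders = [
            rep for rep in active if mean_r[rep] < 0 or crit[rep] < r2_min
        ]
        if not offenders:
            break
        worst = min(offenders, key=lambda rep: (mean_r[rep] >= 0, crit[rep]))
        active.remove(worst)
        excluded.append(worst)
    if excluded and len(active) == 1:
        excluded.append(active.pop())
    kept = [rep for rep in reps if rep in active]
    pairs = [(a, b) for i, a in enumerate(reps) for b in reps[i + 1 :]]
    mean_r2 = float(np.mean([r2.loc[a, b] for a, b in pairs]))
    return ReplicateQC(
        kept=kept,
        excluded=excluded,
        r2_matrix=r2,
        mean_r2=mean_r2,
        failed=len(kept) == 0,
    )


def summarize_gene_line(
    wells: pd.DataFrame, r2_min: float = 0.5
) -> tuple[pd.DataFrame, dict]:
    """Per gene-by-line NPI summaries across QC-passing replicates.

    ``wells`` must carry an ``npi`` column (see :func:`annotate_npi`) plus
    ``lot`` and ``replicate`` labels.  Replicate concordance is assessed
    per (lot, line) on the well-matched gene vectors.  Returns the summary
    frame (``gene, cell_line, mean_npi, sem_npi, n_reps``) and a QC report
    listing exclusions and mean r^2 per (lot, line).
    """
    samples = wells[wells["reagent_type"] == "sample"]
    rows = []
    qc_report: dict = {"experiments": {}, "failed": []}
    for (lot, line), grp in samples.groupby(["lot", "cell_line"]):
        mat = grp.pivot_table(
            index="gene", columns="replicate", values="npi", aggfunc="mean"
        )
        qc = replicate_qc(mat, r2_min=r2_min)
        key = f"lot{lot}:{line}"
        qc_report["experiments"][key] = {
            "kept": list(map(int, qc.kept)),
            "excluded": list(map(int, qc.excluded)),
            "mean_r2": qc.mean_r2,
        }
        if qc.failed:
            qc_report["failed"].append(key)
            continue
        kept = mat[qc.kept]
        for gene, vals in kept.iterrows():
            v = vals.dropna().to_numpy()
            rows.append(
                {
                    "gene": gene,
                    "cell_line": line,
                    "mean_npi": float(v.mean()),
                    "sem_npi": float(v.std(ddof=1) / np.sqrt(len(v)))
                    if len(v) > 1
                    else np.nan,
                    "n_reps": int(len(v)),
                }
            )
    return pd.DataFrame(rows), qc_report


# ---------------------------------------------------------------------------
# Threshold and rule engine
# ---------------------------------------------------------------------------


def hit_threshold(
    values=None, mean: float | None = None, sd: float | None = None
) -> float:
    """Effect threshold: mean + 3 SD of negative-control NPI values."""
    if values is not None:
        values = np.asarray(values, float)
        if values.size < 2:
            raise ValueError("need >= 2 negative-control values")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
    if mean is None or sd is None:
        raise ValueError("provide raw values or summary mean and sd")
    return mean + 3.0 * sd


def primary_hit(
    hmec_npi: float,
    line_npis: Mapping[str, float],
    threshold: float = DEFAULT_NPI_THRESHOLD,
    gene: str = "",
) -> HitCall:
    """Primary screen rule on per-line mean NPI.

    Clause A: HMEC spared (NPI < thr) and >= 2 malignant lines at/above
    thr.  Clause B: HMEC affected but the effect heterogeneous — >= 2
    malignant lines below thr *and* >= 2 at/above thr.
    """
    if hmec_npi is None or (isinstance(hmec_npi, float) and np.isnan(hmec_npi)):
        return HitCall(gene, "primary", "fail", {"reason": "missing HMEC"})
    if len(line_npis) < 2:
        return HitCall(gene, "primary", "fail", {"reason": "<2 malignant lines"})
    above = sorted(l for l, v in line_npis.items() if v >= threshold)
    below = sorted(l for l, v in line_npis.items() if v < threshold)
    hmec_spared = hmec_npi < threshold
    if hmec_spared:
        is_hit = len(above) >= 2
        clause = "A" if is_hit else None
    else:
        is_hit = len(above) >= 2 and len(below) >= 2
        clause = "B" if is_hit else None
    return HitCall(
        gene,
        "primary",
        "hit" if is_hit else "no_hit",
        {
            "clause": clause,
            "hmec_npi": float(hmec_npi),
            "lines_above": above,
            "lines_below": below,
        },
    )


def top10_hit(
    oligos: Sequence[OligoResult],
    threshold: float = DEFAULT_NPI_THRESHOLD,
    kd_min: float = 70.0,
    gene: str = "",
) -> HitCall:
    """Top-10 gene rule on deconvoluted single oligos.

    Validated when >= 2 oligos each satisfy: knockdown >= ``kd_min``, HMEC
    NPI below threshold, and NPI at/above threshold in >= 2 malignant
    lines.
    """
    if len(oligos) < 3:
        return HitCall(gene, "top10", "fail", {"reason": "<3 oligos measured"})
    if all(o.kd_pct is None or np.isnan(o.kd_pct) for o in oligos):
        return HitCall(gene, "top10", "fail", {"reason": "no knockdown data"})
    qualifying = [
        o.oligo
        for o in oligos
        if not np.isnan(o.kd_pct)
        and o.kd_pct >= kd_min
        and o.hmec_npi < threshold
        and sum(v >= threshold for v in o.line_npis.values()) >= 2
    ]
    return HitCall(
        gene,
        "top10",
        "validated" if len(qualifying) >= 2 else "no_hit",
        {"qualifying_oligos": qualifying},
    )


def secondary_verdict(
    oligos: Sequence[tuple[float, float]],
    threshold: float = DEFAULT_NPI_THRESHOLD,
    kd_fail: float = 70.0,
    kd_validate: float = 40.0,
    gene: str = "",
) -> HitCall:
    """Secondary (pool-deconvolution) rule on per-oligo ``(kd%, NPI)`` pairs.

    Fail: more than one oligo with knockdown >= 70% yet NPI below
    threshold (effective silencing without phenotype points to the pool
    phenotype being off-target).  Otherwise validated when >= 2 oligos
    with knockdown >= 40% show NPI at/above threshold; else inconclusive.
    The fail clause takes precedence.
    """
    discordant = [
        i
        for i, (kd, npi) in enumerate(oligos)
        if kd >= kd_fail and npi < threshold
    ]
    concordant = [
        i
        for i, (kd, npi) in enumerate(oligos)
        if kd >= kd_validate and npi >= threshold
    ]
    if len(discordant) >= 2:
        verdict = "fail"
    elif len(concordant) >= 2:
        verdict = "validated"
    else:
        verdict = "inconclusive"
    return HitCall(
        gene,
        "secondary",
        verdict,
        {"discordant": discordant, "concordant": concordant},
    )


# ---------------------------------------------------------------------------
# Table-level wrappers
# ---------------------------------------------------------------------------


def call_primary_hits(
    gene_line: pd.DataFrame,
    threshold: float = DEFAULT_NPI_THRESHOLD,
    hmec_line: str = "HMEC",
) -> pd.DataFrame:
    """Apply the primary rule to a ``gene, cell_line, mean_npi`` frame."""
    rows = []
    for gene, grp in gene_line.groupby("gene"):
        npis = dict(zip(grp["cell_line"], grp["mean_npi"]))
        hmec = npis.pop(hmec_line, np.nan)
        call = primary_hit(hmec, npis, threshold, gene=gene)
        rows.append(
            {
                "gene": gene,
                "verdict": call.verdict,
                "clause": call.evidence.get("clause"),
                "hmec_npi": call.evidence.get("hmec_npi", np.nan),
                "lines_above": ";".join(call.evidence.get("lines_above", [])),
                "lines_below": ";".join(call.evidence.get("lines_below", [])),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def call_top10_hits(
    oligo_table: pd.DataFrame,
    threshold: float = DEFAULT_NPI_THRESHOLD,
    kd_min: float = 70.0,
    hmec_line: str = "HMEC",
) -> pd.DataFrame:
    """Apply the top-10 rule to a long frame of per-oligo, per-line NPIs.

    Expected columns: ``gene, oligo, kd_pct, cell_line, npi``.
    """
    rows = []
    for gene, grp in oligo_table.groupby("gene"):
        oligos = []
        for oligo, og in grp.groupby("oligo"):
            npis = dict(zip(og["cell_line"], og["npi"]))
            hmec = npis.pop(hmec_line, np.nan)
            oligos.append(
                OligoResult(
                    oligo=oligo,
                    kd_pct=float(og["kd_pct"].iloc[0]),
                    hmec_npi=hmec,
                    line_npis=npis,
                )
            )
        call = top10_hit(oligos, threshold, kd_min, gene=gene)
        rows.append(
            {
                "gene": gene,
                "verdict": call.verdict,
                "qualifying_oligos": ";".join(
                    call.evidence.get("qualifying_oligos", [])
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def call_secondary(
    oligo_table: pd.DataFrame, threshold: float = DEFAULT_NPI_THRESHOLD
) -> pd.DataFrame:
    """Apply the secondary rule to a ``gene, oligo, kd_pct, npi`` frame."""
    rows = []
    for gene, grp in oligo_table.groupby("gene"):
        pairs = list(zip(grp["kd_pct"], grp["npi"]))
        call = secondary_verdict(pairs, threshold, gene=gene)
        rows.append({"gene": gene, "verdict": call.verdict})
    return pd.DataFrame(rows).set_index("gene")
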
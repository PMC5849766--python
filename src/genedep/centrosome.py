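"""Centrosome-amplification (CA) and pericentrin-abnormality (PCAB) scoring.

CA is scored from per-cell counts: a cell is centrosome-amplified when it
carries more than two centrosomes and/or any centrosome bears more than
two centriole markers; the CA score is the percentage of amplified cells.

PCAB is scored from stained-body object tables: a pericentrin body is
abnormal when its area strictly exceeds 7 µm² (the largest body seen in
normal breast epithelium); the PCAB score of a case is the percentage of
abnormal bodies among all bodies, valid only when at least 20 bodies were
scored.  Cases are dichotomized at a 20% PCAB cutoff (strictly above =
high) for association with RNAi sensitivity (ordinary least squares) and
recurrence-free survival (Kaplan–Meier curves with a log-rank test).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ca_score",
    "pcab_score",
    "pcab_associations",
    "DEFAULT_SIZE_CUTOFF",
    "DEFAULT_MIN_BODIES",
    "DEFAULT_PCAB_CUTOFF",
]

DEFAULT_SIZE_CUTOFF = 7.0  # µm², largest normal-epithelium body
DEFAULT_MIN_BODIES = 20
DEFAULT_PCAB_CUTOFF = 20.0  # %


def _centriole_counts(value) -> list[int]:
    if isinstance(value, str):
        return [int(v) for v in value.split(";") if v != ""]
    if isinstance(value, Iterable):
        return [int(v) for v in value]
    raise ValueError(f"cannot parse centriole counts: {value!r}")


def ca_score(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-case centrosome-amplification score from a cell table.

    ``cells`` needs columns ``case, n_centrosomes, centriole_counts``
    (semicolon-joined string or sequence per cell).  A cell is amplified
    iff ``n_centrosomes > 2`` or any per-centrosome centriole count
    exceeds 2.  Returns ``n_cells, n_amplified, ca_pct`` per case.
    """
    if cells.empty:
        raise ValueError("empty cell table")
    amplified = []
    for _, row in cells.iterrows():
        counts = _centriole_counts(row["centriole_counts"])
        if len(counts) != int(row["n_centrosomes"]):
            raise ValueError(
                f"centriole list length {len(counts)} != centrosome count "
                f"{row['n_centrosomes']} for cell {row.get('cell_id', '?')}"
            )
        amplified.append(
            int(row["n_centrosomes"]) > 2 or any(c > 2 for c in counts)
        )
    df = cells.assign(_amp=amplified)
    out = df.groupby("case").agg(
        n_cells=("_amp", "size"), n_amplified=("_amp", "sum")
    )
    out["ca_pct"] = 100.0 * out["n_amplified"] / out["n_cells"]
    return out


def pcab_score(
    bodies: pd.DataFrame,
    size_cutoff: float = DEFAULT_SIZE_CUTOFF,
    min_bodies: int = DEFAULT_MIN_BODIES,
) -> pd.DataFrame:
    """Per-case PCAB score from a stained-body table.

    ``bodies`` needs columns ``case`` and ``area_um2`` (µm²).  Rows with
    non-positive area are dropped with a log message.  Abnormal iff area
    strictly greater than ``size_cutoff``.  Cases with fewer than
    ``min_bodies`` bodies are flagged invalid and carry no score.
    """
    bad = bodies["area_um2"] <= 0
    if bad.any():
        logger.warning("dropping %d bodies with non-positive area", int(bad.sum()))
        bodies = bodies[~bad]
    if bodies.empty:
        raise ValueError("no bodies with positive area")
    df = bodies.assign(_abn=bodies["area_um2"] > size_cutoff)
    out = df.groupby("case").agg(
        n_bodies=("_abn", "size"), n_abnormal=("_abn", "sum")
    )
    out["valid"] = out["n_bodies"] >= min_bodies
    out["pcab_pct"] = np.where(
        out["valid"], 100.0 * out["n_abnormal"] / out["n_bodies"], np.nan
    )
    return out


def pcab_associations(
    case_scores: pd.DataFrame,
    cutoff: float = DEFAULT_PCAB_CUTOFF,
    include_cox: bool = False,
) -> dict:
    """Associations of valid per-case PCAB scores with dependency and outcome.

    ``case_scores`` carries ``pcab_pct`` plus optionally ``npi`` (RNAi
    sensitivity) and ``recurrence_time`` / ``recurrence_event``.  Reports:

    * ordinary least squares of NPI on PCAB (slope, intercept, r², p) when
      both variables are present for >= 3 cases;
    * dichotomization at ``cutoff`` (high iff PCAB strictly above) with
      the fraction of cases above;
    * Kaplan–Meier survival curves per group and a log-rank test when
      outcome columns are present and both groups are populated;
    * optionally an off-the-shelf Cox proportional-hazards fit
      (``include_cox=True``) for a hazard ratio, clearly not bespoke code.
    """
    df = case_scores.dropna(subset=["pcab_pct"]).copy()
    if "valid" in df.columns:
        df = df[df["valid"]]
    report: dict = {"n_cases": int(len(df)), "cutoff": float(cutoff)}

    df["high_pcab"] = df["pcab_pct"] > cutoff
    report["fraction_above_cutoff"] = float(df["high_pcab"].mean())

    if "npi" in df.columns and df["npi"].notna().sum() >= 3:
        sub = df.dropna(subset=["npi"])
        if float(np.ptp(sub["pcab_pct"])) == 0.0:
            raise ValueError("regression undefined: zero-variance PCAB")
        fit = sps.linregress(sub["pcab_pct"], sub["npi"])
        report["regression"] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r2": float(fit.rvalue**2),
            "p": float(fit.pvalue),
            "n": int(len(sub)),
        }

    has_outcome = {"recurrence_time", "recurrence_event"} <= set(df.columns)
    if has_outcome:
        surv = df.dropna(subset=["recurrence_time", "recurrence_event"])
        hi = surv[surv["high_pcab"]]
        lo = surv[~surv["high_pcab"]]
        if len(hi) and len(lo):
            from lifelines import KaplanMeierFitter
            from lifelines.statistics import logrank_test

            km = {}
            for name, grp in (("high", hi), ("low", lo)):
                fitter = KaplanMeierFitter()
                fitter.fit(
                    grp["recurrence_time"],
                    grp["recurrence_event"],
                    label=name,
                )
                km[name] = fitter.survival_function_
            lr = logrank_test(
                hi["recurrence_time"],
                lo["recurrence_time"],
                event_observed_A=hi["recurrence_event"],
                event_observed_B=lo["recurrence_event"],
            )
            report["survival"] = {
                "km": km,
                "logrank_stat": float(lr.test_statistic),
                "logrank_p": float(lr.p_value),
                "n_high": int(len(hi)),
                "n_low": int(len(lo)),
            }
            if include_cox:
                from lifelines import CoxPHFitter

                cph = CoxPHFitter()
                cph.fit(
                    surv[["recurrence_time", "recurrence_event", "high_pcab"]]
                    .astype(float),
                    duration_col="recurrence_time",
                    event_col="recurrence_event",
                )
                report["survival"]["hazard_ratio"] = float(
                    np.exp(cph.params_["high_pcab"])
                )
    return report
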
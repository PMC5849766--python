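"""Synthetic cohorts, screen plates and centrosome object tables.

Every downstream stage of the pipeline is exercised on generated data with
known planted structure:

* :func:`simulate_cohort` emits paired copy-number / expression matrices
  emulating a TNBC-enriched breast cancer cohort (140 TNBC, 21 HER2+/ER-,
  21 HER2-/ER+, 9 normal epithelium samples by default) with a configurable
  number of planted *cis-regulated driver* genes — genes gained in a
  fraction of TNBC samples whose expression tracks copy number at a target
  Spearman correlation — and a planted co-upregulated gene cluster.
* :func:`simulate_screen` emits triplicate 96-well viability plates per
  (gene lot, cell line) with interior-well layout, positive/negative
  control wells, and planted gene-by-line dependencies expressed on the
  normalized-percent-inhibition (NPI) scale, plus a per-oligo knockdown
  table.
* :func:`simulate_centrosome_objects` emits per-case stained-body tables
  (areas in µm² straddling the 7 µm² normal/abnormal cutoff) and per-cell
  centriole/centrosome count tables.

All generators are deterministic under a fixed seed; each draws from its
own RNG stream derived from the master seed so that outputs are stable when
unrelated configuration changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profile import GeneCentricProfile

__all__ = [
    "CohortSimConfig",
    "ScreenSimConfig",
    "CentrosomeSimConfig",
    "ScreenData",
    "simulate_cohort",
    "simulate_screen",
    "simulate_centrosome_objects",
]

_COHORT_STREAM, _SCREEN_STREAM, _CENTROSOME_STREAM = 11, 23, 37


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic tumor cohort.

    Defaults mirror the study conditions the pipeline is designed for: a
    140/21/21/9 TNBC-enriched cohort with 20 planted cis-driver genes among
    2000, gained (copy number 3.5) in 30% of TNBC samples with a target
    CN–expression Spearman correlation of 0.6, and a 13-gene co-upregulated
    cluster.
    """

    n_genes: int = 2000
    n_tnbc: int = 140
    n_her2: int = 21
    n_er: int = 21
    n_normal: int = 9
    n_cis_driver_genes: int = 20
    cis_rho: float = 0.6
    gain_freq: float = 0.30
    cn_gain_level: float = 3.5
    noise_sd: float = 0.5
    n_coexpr_genes: int = 13
    #: log2 expression upshift of planted driver genes in TNBC samples
    driver_upshift: float = 1.5
    #: fraction of TNBC samples with a recurrence event
    recurrence_rate: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tnbc", "n_her2", "n_er", "n_normal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cis_driver_genes < 0 or self.n_coexpr_genes < 0:
            raise ValueError("planted gene counts must be >= 0")
        if self.n_cis_driver_genes + self.n_coexpr_genes > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if not 0.0 <= self.gain_freq <= 1.0:
            raise ValueError("gain_freq must lie in [0, 1]")
        if not 0.0 <= self.cis_rho <= 1.0:
            raise ValueError("cis_rho must lie in [0, 1]")
        if self.cis_rho == 1.0 and self.noise_sd > 0:
            raise ValueError(
                "cis_rho = 1 is unattainable with noise_sd > 0; "
                "set noise_sd = 0 for a deterministic cis relation"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _calibrate_slope(
    cn: np.ndarray, eps: np.ndarray, rho_target: float
) -> float:
    """Slope b such that spearman(cn, b*cn + eps) hits ``rho_target``.

    The realized rank correlation is a (noisy) non-decreasing function of
    the slope, so a bisection on b against the sample Spearman correlation
    of the already-drawn noise vector lands within the rank-step resolution
    of the target.
    """
    if rho_target <= 0:
        return 0.0
    if np.ptp(cn) == 0:
        return 0.0

    def realized(b: float) -> float:
        return sps.spearmanr(cn, b * cn + eps).statistic

    lo, hi = 0.0, 1.0
    for _ in range(40):
        if realized(hi) >= rho_target:
            break
        hi *= 2.0
    else:  # saturated below target (e.g. heavy rank ties); use the cap
        return hi
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if realized(mid) < rho_target:
            lo = mid
        else:
            hi = mid
    return hi


def simulate_cohort(config: CohortSimConfig) -> GeneCentricProfile:
    """Generate a paired CN/expression cohort with planted structure.

    The first ``n_cis_driver_genes`` genes are cis drivers: a ``gain_freq``
    fraction of TNBC samples carries copy number ``cn_gain_level`` and the
    gene's expression follows ``gex = baseline + b·CN + ε`` with the slope
    calibrated per gene so the realized TNBC Spearman correlation matches
    ``cis_rho``.  The next ``n_coexpr_genes`` genes share a per-sample
    latent factor giving pairwise expression correlation around 0.7.  All
    remaining genes are null: diploid CN jitter and independent expression.

    Returns a :class:`~genedep.profile.GeneCentricProfile` whose ``truth``
    maps ``cis_genes`` and ``coexpr_genes`` to the planted identifiers and
    records per-gene planted gain counts.
    """
    config.validate()
    rng = _rng(config.seed, _COHORT_STREAM)

    n_samples = config.n_tnbc + config.n_her2 + config.n_er + config.n_normal
    sample_ids = (
        [f"TNBC_{i:03d}" for i in range(config.n_tnbc)]
        + [f"HER2_{i:03d}" for i in range(config.n_her2)]
        + [f"ER_{i:03d}" for i in range(config.n_er)]
        + [f"NORM_{i:03d}" for i in range(config.n_normal)]
    )
    groups = (
        ["TNBC"] * config.n_tnbc
        + ["HER2"] * config.n_her2
        + ["ER"] * config.n_er
        + ["normal"] * config.n_normal
    )
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    is_tumor = np.array([g != "normal" for g in groups])
    tnbc_cols = np.arange(config.n_tnbc)

    # background: diploid CN jitter, expression = per-gene baseline + noise
    cn = 2.0 + rng.normal(0.0, 0.15, size=(config.n_genes, n_samples))
    baseline = rng.uniform(4.0, 10.0, size=config.n_genes)
    gex = baseline[:, None] + rng.normal(
        0.0, max(config.noise_sd, 1e-12), size=(config.n_genes, n_samples)
    )

    n_cis = config.n_cis_driver_genes
    n_gain = int(round(config.gain_freq * config.n_tnbc))
    truth_gain_counts: dict[str, int] = {}
    for gi in range(n_cis):
        gained = rng.choice(tnbc_cols, size=n_gain, replace=False)
        cn[gi, gained] = config.cn_gain_level + rng.normal(0.0, 0.1, n_gain)
        truth_gain_counts[genes[gi]] = n_gain
        # TNBC upshift makes drivers over-expressed vs normals as well
        gex[gi, tnbc_cols] += config.driver_upshift
        cn_tnbc = cn[gi, tnbc_cols]
        eps = gex[gi, tnbc_cols] - gex[gi, tnbc_cols].mean()
        b = _calibrate_slope(cn_tnbc, eps, config.cis_rho)
        gex[gi, tnbc_cols] += b * (cn_tnbc - cn_tnbc.mean())

    # planted co-upregulated cluster: shared latent factor across samples
    if config.n_coexpr_genes:
        factor = rng.normal(0.0, 1.0, n_samples)
        # loading for ~0.7 pairwise correlation at the configured noise level
        lam = max(config.noise_sd, 1e-12) * np.sqrt(0.7 / 0.3)
        lo = n_cis
        hi = n_cis + config.n_coexpr_genes
        gex[lo:hi, :] += lam * factor[None, :]

    # normals carry no CN calls (allowed and flagged by the profile)
    cn[:, ~is_tumor] = np.nan

    recur = np.zeros(n_samples, dtype=int)
    times = np.full(n_samples, np.nan)
    tumor_idx = np.where(is_tumor)[0]
    recur[tumor_idx] = rng.binomial(1, config.recurrence_rate, tumor_idx.size)
    raw_t = rng.exponential(60.0, tumor_idx.size)
    times[tumor_idx] = np.minimum(raw_t, 120.0)

    samples = pd.DataFrame(
        {"group": groups, "recurrence": recur, "recurrence_time": times},
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = {
        "cis_genes": genes[:n_cis],
        "coexpr_genes": genes[n_cis : n_cis + config.n_coexpr_genes],
        "gain_counts": truth_gain_counts,
    }
    gidx = pd.Index(genes, name="gene")
    return GeneCentricProfile(
        cn=pd.DataFrame(cn, index=gidx, columns=sample_ids),
        gex=pd.DataFrame(gex, index=gidx, columns=sample_ids),
        samples=samples,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Parameters of the synthetic RNAi viability screen.

    Wells on the outermost plate ring are left empty (edge-effect
    avoidance); controls and gene wells occupy interior positions only.
    ``planted_hits`` entries are ``(gene, line, npi_mean, npi_sd)``: sample
    wells for that pair are drawn so their NPI given the plate's controls
    is centered on ``npi_mean``.  Null gene wells are drawn from the
    negative-control distribution.  The default negative-control spread
    (``neg_sd = 0.0475`` at a 0.8 control separation) puts the null NPI
    standard deviation near the 5.94% observed for scrambled controls.
    """

    n_genes: int = 40
    n_lines: int = 5
    plate_rows: int = 8
    plate_cols: int = 12
    n_pos_ctrl: int = 6
    n_neg_ctrl: int = 6
    neg_mean: float = 1.0
    neg_sd: float = 0.0475
    pos_mean: float = 0.2
    pos_sd: float = 0.024
    planted_hits: Sequence[tuple[str, str, float, float]] = field(
        default_factory=list
    )
    n_replicates: int = 3
    oligos_per_gene: int = 4
    kd_true: Mapping[str, Sequence[float]] | None = None
    #: multiplicative plate-to-plate scale jitter (lognormal sigma)
    plate_scale_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_lines <= 0:
            raise ValueError("n_genes and n_lines must be positive")
        if self.pos_mean >= self.neg_mean:
            raise ValueError(
                "pos_mean must be below neg_mean: the positive control "
                "kills cells on the raw viability scale"
            )
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3 (triplicate plates)")
        if not 3 <= self.oligos_per_gene <= 4:
            raise ValueError("oligos_per_gene must be 3 or 4")
        interior = (self.plate_rows - 2) * (self.plate_cols - 2)
        if interior < self.n_pos_ctrl + self.n_neg_ctrl + 1:
            raise ValueError("plate layout too small for requested wells")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def line_names(self) -> list[str]:
        """HMEC (non-malignant comparator) followed by malignant lines."""
        return ["HMEC"] + [f"BCCL{i:02d}" for i in range(1, self.n_lines)]


@dataclass
class ScreenData:
    """Generated screen: long-format plate wells plus knockdown table."""

    plates: pd.DataFrame
    knockdown: pd.DataFrame
    truth: dict


def simulate_screen(config: ScreenSimConfig) -> ScreenData:
    """Generate triplicate screen plates with planted dependencies.

    Genes are partitioned into lots that fit the interior wells left after
    controls; each (lot, line) combination yields ``n_replicates`` plates.
    Raw well values are on an arbitrary viability scale with a lognormal
    per-plate scale factor, so plate-median normalization is required
    before control statistics are meaningful.
    """
    config.validate()
    rng = _rng(config.seed, _SCREEN_STREAM)

    genes = config.gene_names
    lines = config.line_names
    planted = {
        (g, l): (mu, sd) for g, l, mu, sd in config.planted_hits
    }
    for g, l in planted:
        if g not in genes or l not in lines:
            raise ValueError(f"planted hit references unknown gene/line: {(g, l)}")

    rows, cols = config.plate_rows, config.plate_cols
    interior = [
        (r, c)
        for r in range(1, rows - 1)
        for c in range(1, cols - 1)
    ]
    exterior = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if (r, c) not in set(interior)
    ]
    capacity = len(interior) - config.n_pos_ctrl - config.n_neg_ctrl
    lots = [genes[i : i + capacity] for i in range(0, len(genes), capacity)]

    sep = config.pos_mean - config.neg_mean  # negative number
    records: list[tuple] = []
    for li, lot in enumerate(lots):
        for line in lines:
            for rep in range(1, config.n_replicates + 1):
                plate_id = f"LOT{li + 1}_{line}_R{rep}"
                scale = float(
                    np.exp(rng.normal(0.0, config.plate_scale_sd))
                )
                layout = list(interior)
                rng.shuffle(layout)
                it = iter(layout)
                for _ in range(config.n_pos_ctrl):
                    r, c = next(it)
                    raw = scale * rng.normal(config.pos_mean, config.pos_sd)
                    records.append(
                        (plate_id, li + 1, rep, r, c, "pos_ctrl", "", "", line, raw)
                    )
                for _ in range(config.n_neg_ctrl):
                    r, c = next(it)
                    raw = scale * rng.normal(config.neg_mean, config.neg_sd)
                    records.append(
                        (plate_id, li + 1, rep, r, c, "neg_ctrl", "", "", line, raw)
                    )
                for gene in lot:
                    r, c = next(it)
                    if (gene, line) in planted:
                        mu, sd = planted[(gene, line)]
                        npi = rng.normal(mu, sd)
                        raw = scale * (config.neg_mean + npi / 100.0 * sep)
                    else:
                        raw = scale * rng.normal(config.neg_mean, config.neg_sd)
                    records.append(
                        (plate_id, li + 1, rep, r, c, "sample", gene, "pool", line, raw)
                    )
                for r, c in itertools.chain(it, exterior):
                    records.append(
                        (plate_id, li + 1, rep, r, c, "empty", "", "", line, np.nan)
                    )

    plates = pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "lot",
            "replicate",
            "row",
            "col",
            "reagent_type",
            "gene",
            "oligo",
            "cell_line",
            "raw_value",
        ],
    )

    kd_records = []
    for gene in genes:
        if config.kd_true is not None and gene in config.kd_true:
            fractions = list(config.kd_true[gene])
        else:
            fractions = rng.uniform(0.55, 0.95, config.oligos_per_gene).tolist()
        for oi, frac in enumerate(fractions, start=1):
            kd_records.append((gene, f"oligo{oi}", 100.0 * frac))
    knockdown = pd.DataFrame(kd_records, columns=["gene", "oligo", "kd_pct"])

    truth = {
        "planted": dict(planted),
        "lots": {i + 1: lot for i, lot in enumerate(lots)},
    }
    return ScreenData(plates=plates, knockdown=knockdown, truth=truth)


# ---------------------------------------------------------------------------
# Centrosome objects
# ---------------------------------------------------------------------------


@dataclass
class CentrosomeSimConfig:
    """Parameters for stained-body and per-cell centrosome tables.

    Areas are in µm².  The normal-body distribution (lognormal with median
    1.44 µm², the average normal-tissue body size) is resampled to lie at
    or below the 7 µm² normal maximum; abnormal bodies are drawn strictly
    above 7 µm², so planted abnormal labels coincide exactly with the
    size rule and recounts are exact.
    """

    n_cases: int = 30
    bodies_per_case: int = 200
    abnormal_fraction: float | Sequence[float] = 0.2
    #: scipy frozen distribution of normal body areas (resampled to <= 7 µm²)
    normal_area_dist: object | None = None
    #: scipy frozen distribution of the abnormal-body area excess over 7 µm²
    abnormal_area_dist: object | None = None
    cells_per_case: int = 100
    amplified_cell_fraction: float | Sequence[float] = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.bodies_per_case <= 0:
            raise ValueError("n_cases and bodies_per_case must be positive")
        if self.cells_per_case <= 0:
            raise ValueError("cells_per_case must be positive")
        for frac in np.atleast_1d(np.asarray(self.abnormal_fraction, float)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("abnormal_fraction must lie in [0, 1]")
        for frac in np.atleast_1d(np.asarray(self.amplified_cell_fraction, float)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("amplified_cell_fraction must lie in [0, 1]")


def _per_case(value, n_cases: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, float))
    if arr.size == 1:
        return np.repeat(arr, n_cases)
    if arr.size != n_cases:
        raise ValueError("per-case parameter length must equal n_cases")
    return arr


def simulate_centrosome_objects(
    config: CentrosomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-case body and cell tables with planted abnormality.

    Returns ``(bodies, cells)``.  ``bodies`` has columns ``case, body_id,
    area_um2, mean_intensity, planted_abnormal``; ``cells`` has ``case,
    cell_id, n_centrosomes, centriole_counts`` (semicolon-joined per-
    centrosome centriole counts) and ``planted_amplified``.
    """
    config.validate()
    rng = _rng(config.seed, _CENTROSOME_STREAM)
    n = config.n_cases
    abn_frac = _per_case(config.abnormal_fraction, n)
    amp_frac = _per_case(config.amplified_cell_fraction, n)

    normal_dist = config.normal_area_dist or sps.lognorm(
        s=0.6, scale=1.44
    )
    abnormal_excess = config.abnormal_area_dist or sps.gamma(a=2.0, scale=3.0)

    def draw_normal(k: int) -> np.ndarray:
        out = np.empty(k)
        filled = 0
        while filled < k:
            cand = normal_dist.rvs(size=2 * (k - filled), random_state=rng)
            cand = cand[(cand > 0) & (cand <= 7.0)]
            take = min(cand.size, k - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
        return out

    def draw_abnormal(k: int) -> np.ndarray:
        out = np.empty(k)
        filled = 0
        while filled < k:
            cand = 7.0 + abnormal_excess.rvs(
                size=2 * (k - filled), random_state=rng
            )
            cand = cand[cand > 7.0]
            take = min(cand.size, k - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
        return out

    body_rows = []
    cell_rows = []
    for ci in range(n):
        case = f"CASE{ci + 1:03d}"
        nb = config.bodies_per_case
        abnormal = rng.random(nb) < abn_frac[ci]
        areas = np.empty(nb)
        areas[~abnormal] = draw_normal(int((~abnormal).sum()))
        areas[abnormal] = draw_abnormal(int(abnormal.sum()))
        intensity = np.where(
            abnormal,
            rng.normal(160.0, 25.0, nb),
            rng.normal(120.0, 20.0, nb),
        )
        for bi in range(nb):
            body_rows.append(
                (
                    case,
                    f"{case}_B{bi + 1:05d}",
                    areas[bi],
                    max(intensity[bi], 1.0),
                    bool(abnormal[bi]),
                )
            )

        amplified = rng.random(config.cells_per_case) < amp_frac[ci]
        for cj in range(config.cells_per_case):
            if amplified[cj]:
                if rng.random() < 0.5:  # supernumerary centrosomes
                    n_cs = int(rng.integers(3, 6))
                    centrioles = rng.integers(1, 3, n_cs).tolist()
                else:  # over-duplicated centrioles within a centrosome
                    n_cs = int(rng.integers(1, 3))
                    centrioles = rng.integers(1, 3, n_cs).tolist()
                    centrioles[int(rng.integers(0, n_cs))] = int(
                        rng.integers(3, 5)
                    )
            else:
                n_cs = int(rng.integers(1, 3))
                centrioles = [2] * n_cs
            cell_rows.append(
                (
                    case,
                    f"{case}_C{cj + 1:04d}",
                    n_cs,
                    ";".join(str(int(x)) for x in centrioles),
                    bool(amplified[cj]),
                )
            )

    bodies = pd.DataFrame(
        body_rows,
        columns=["case", "body_id", "area_um2", "mean_intensity", "planted_abnormal"],
    )
    cells = pd.DataFrame(
        cell_rows,
        columns=["case", "cell_id", "n_centrosomes", "centriole_counts", "planted_amplified"],
    )
    return bodies, cells
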
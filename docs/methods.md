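# Methods

This note documents the models and procedures `genedep` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Candidate scoring

The scoring engine operates on a gene-centric view of a tumor cohort: an
absolute-copy-number-like matrix (diploid = 2) and a log2-like expression
matrix over shared genes and samples, plus per-sample group labels (TNBC,
HER2+/ER−, HER2−/ER+, normal epithelium) and recurrence fields.

**Filters.** The gain filter retains genes with CN ≥ 2.38 in at least 10%
of TNBC samples (both comparisons inclusive). The value 2.38 is treated as
a threshold on whatever gene-centric CN scale the input declares; the
default interpretation is absolute copy number. The cis filter computes
Spearman's ρ between each gene's CN and expression across TNBC samples and
passes genes with ρ ≥ 0.30 and p ≤ 0.01. The statistic is ρ itself, not
ρ²; both cuts are config-exposed. P-values use the standard large-sample t
approximation, with an exact permutation option that engages automatically
at n ≤ 8. Constant vectors make the correlation undefined; such genes are
flagged and never pass. The two filters commute: applying them
sequentially equals intersecting their independent pass sets.

**CN-state expression test.** CN is discretized to loss (< 1.5), neutral
([1.5, 2.38)), gain ([2.38, 4)) and amplification (≥ 4); the boundaries
are defaults exposed in the API since no canonical values exist for the
interior cuts. Expression in each populated non-neutral state (≥ 2
samples) is compared with the neutral state by a two-sided Mann–Whitney U;
the per-gene p is the minimum across comparisons, Bonferroni-scaled by the
number of comparisons within the gene, then Benjamini–Hochberg adjusted
across genes (significant at adjusted p < 0.05).

**Differential expression.** Fold change is the ratio of geometric group
means (2^Δ of log2 means); significance is Welch's t on log2 values with
BH adjustment. A moderated-variance (limma-style) engine is deliberately
not implemented: the contribution here is the scoring pipeline, and the DE
stand-in is documented and swappable. The expression-centered candidate
arm instead compares *linear-scale* means (strictly > 2-fold over normal
epithelium), matching how such over-expression cuts are usually stated.

**Binned scoring.** Each feature is scored 0 / w / 2w against thresholds
(t₁, t₂): below t₁ → 0, in [t₁, t₂] (inclusive on both ends) → w, above
t₂ → 2w; for "smaller is better" features the bins reverse. Missing values
contribute 0. Per-block sums are capped at the block limit and divided by
it; the total is the sum of the five normalized block scores (range
[0, 5]). The shipped default feature table mirrors the five-block
structure (expression, copy number, CN–expression association, clinical,
annotation) with package-default thresholds, weights and caps; the
originally published per-feature weights live in supplementary material
not redistributed here, and users can load their own via
`genedep.io.load_specs`. GISTIC-style focality is accepted as a
precomputed per-gene column (absent → contributes 0). Ranking ties are
broken deterministically by the C, A and B block scores and finally by
gene identifier.

**Candidate assembly.** Arm 1 takes the top-k (default 85) genes by total
score; arm 2 intersects the expression-centered set with an
annotation-curated list (the whole set when no curation is given) and adds
manual picks; the union carries per-gene provenance labels.

## Screen analytics

Raw viability plates are normalized per plate by the median of interior
*sample* wells (not all wells: median normalization targets the sample
distribution, and control wells would bias it on plates with many
controls). NPI is computed from within-plate control means with no
clamping, so values below 0 and above 100 survive. Z′ is computed in NPI
space, exactly as the formula reads — no absolute value in the
denominator — and a plate is valid at Z′ ≥ 0.3.

Replicate concordance uses pairwise Pearson r² on well-matched vectors
with exclusion at mean r² < 0.5. Exclusion is greedy and iterative: the
least concordant offender is removed and concordance re-evaluated against
the retained replicates. A one-shot rule would let a single rogue
replicate drag every pairwise mean below the cut and exclude the
concordant majority along with it. A replicate whose mean r is negative
fails regardless of r² magnitude — anti-correlated replicates are not
concordant even though squaring hides the sign. A lone survivor of
exclusions has no concordance support and is excluded too; an experiment
with no surviving replicates is flagged failed. A config switch (`mode`)
selects any-pair instead of mean-pair assessment.

The effect threshold is mean + 3 SD of negative-control NPIs (the module
constant 18.01% reproduces the published control summary of 0.18% ± 5.94).
Hit rules are decided on per-line mean NPI across kept replicates:

* **primary** — hit iff (HMEC < thr and ≥ 2 malignant lines ≥ thr) or
  (HMEC ≥ thr and ≥ 2 lines < thr and ≥ 2 lines ≥ thr);
* **top-10** — validated iff ≥ 2 single oligos each combine knockdown
  ≥ 70%, HMEC < thr and ≥ 2 malignant lines ≥ thr;
* **secondary** — fail iff ≥ 2 oligos with knockdown ≥ 70% show no effect
  (NPI < thr); otherwise validated iff ≥ 2 oligos with knockdown ≥ 40%
  show an effect; else inconclusive. The fail clause takes precedence,
  chosen because effective silencing without phenotype is direct evidence
  the pooled phenotype was off-target; the source material lists the rules
  in that order without resolving the overlap explicitly.

All threshold comparisons are ≥ thr for "effect" and < thr for "no
effect".

## Co-expression and composite score

Pairwise Pearson correlations are computed across TNBC samples with
two-sided t-approximation p-values; pairs at p > 0.05 are flagged
insignificant and constant genes propagate as undefined. Clustering is
agglomerative with Ward linkage on d = 1 − r (undefined entries imputed to
r = 0 with a warning); a switch to Euclidean distance between correlation
rows is available. Flat clusters cut by count or height.

The composite score is defined here as the per-sample mean of per-gene
z-scores over the gene set — the simplest score consistent with "use the
expression levels of these genes" — with the high/low split config-exposed:
a two-component 1-D Gaussian mixture (default; high = component with the
larger mean), the cohort median, or a fixed quantile. Neither the score
formula nor the cut has a canonical published definition, so both are
deliberate design choices. Note the mean-of-z form means duplicating a
single member gene reweights the mean (it is not invariant to duplicating
one gene, only to duplicating the whole set); it *is* invariant to
per-gene affine rescaling of expression.

## Centrosome biomarker

CA: a cell is centrosome-amplified iff it has > 2 centrosomes and/or any
centrosome with > 2 centriole markers; the score is the percentage of
amplified cells. PCAB: a stained body is abnormal iff its area strictly
exceeds 7 µm² — 7 µm² is defined as the *largest normal* body, so the
boundary itself is normal (cutoff config-exposed). The case score is
100·abnormal/total, valid only at ≥ 20 bodies; staining intensity is
carried through but does not participate in the call (the published
scatter plots show area vs intensity, but the score text uses size only).
Dichotomization is strictly above 20%. Associations: OLS of NPI on PCAB
(r², slope); Kaplan–Meier curves and a log-rank test across the
dichotomized groups, both via lifelines; a Cox proportional-hazards fit
for a hazard ratio is available behind `include_cox=True` and is an
off-the-shelf lifelines fit, not bespoke code.

## Synthetic data

The cohort generator emulates a TNBC-enriched breast cancer cohort —
140 TNBC, 21 HER2+/ER−, 21 HER2−/ER+ tumors and 9 normal epithelium
samples, 2000 genes by default. Planted cis drivers carry a CN gain
(default 3.5) in a configurable fraction of TNBC samples (default 30%)
and expression `baseline + b·CN + ε`; the slope *b* is calibrated per
gene by bisection against the realized sample Spearman correlation, so
the emitted correlation matches the target (default 0.6) up to rank-step
resolution. Requesting ρ = 1 with noise is rejected as impossible.
Planted drivers are additionally upshifted +1.5 log2 in TNBC, making them
over-expressed against normals as real CN-driven drivers are. A planted
co-upregulated cluster (13 genes) shares a per-sample latent factor tuned
for ≈ 0.7 pairwise correlation. Background genes have diploid CN jitter
(SD 0.15) and independent expression. Normal samples carry no CN calls.
Recurrence events are Bernoulli (rate 0.35) with exponential times
(scale 60, administratively censored at 120 time units).

The screen generator lays out 96-well plates with the outer ring empty
(edge-effect avoidance), positive/negative control wells and gene wells in
the interior, triplicate plates per (gene lot, cell line), and a lognormal
per-plate scale factor (σ = 0.05) so normalization is actually exercised.
Raw control magnitudes are free parameters nowhere pinned by published
values; the defaults (negative mean 1.0, positive mean 0.2, negative SD
0.0475) are chosen so null-well NPI spread reproduces the published
negative-control SD of 5.94%. Planted (gene, line) effects are expressed
directly on the NPI scale. Null gene wells are draws from the
negative-control distribution. Per-oligo knockdown fractions default to
uniform 55–95%.

The centrosome generator draws normal body areas from a lognormal with
median 1.44 µm² (the average normal-tissue body) resampled to ≤ 7 µm², and
abnormal areas as 7 µm² plus a gamma excess, so planted abnormal labels
coincide exactly with the size rule and brute-force recounts are exact.

**What passing tests show — and do not.** The generators plant clean,
separable structure: no batch effects, no segmentation noise, no probe
artifacts, no spatial plate effects beyond a scalar, no correlated
off-target RNAi signatures, no inter-observer variation in object tables.
Recovery results on this data demonstrate the *correctness of the
computations*, not the expected power of the pipeline on real cohorts,
where all of these nuisances are present. Problem sizes in the tests and
acceptance script (2000-gene cohorts over 5–10 seeds, 40-gene screens over
10–20 seeds, 440 bodies per case) were chosen as the smallest that make
the planted-recovery statements statistically meaningful.

## Numerical choices

* BH adjustment delegates to statsmodels (`fdr_bh`); NaNs pass through and
  do not count toward the number of tests. The test suite checks it
  against an independently coded step-up oracle.
* Spearman/Pearson p-values use the t transform with n − 2 degrees of
  freedom; |r| = 1 maps to p = 0.
* Z′ with equal control means is undefined (NaN, invalid) rather than an
  error at the table level; `compute_npi` with equal means raises.
* Ward clustering leaf order comes deterministically from scipy's linkage;
  permuting input genes leaves flat clusters unchanged as sets.
* Ties in candidate ranking are resolved by block C, then A, then B, then
  lexicographic gene id, for reproducibility.
* All generators draw from independent RNG streams derived from the master
  seed, so changing one module's configuration does not shift another's
  output.

## Known limitations

* The DE engine is Welch's t, not a moderated-variance model; at very
  small sample sizes the moderated approach would be more powerful.
* The composite-score split by a 2-component mixture can be unstable when
  the two populations are not separated; the median/quantile rules are the
  robust fallback.
* The secondary-validation precedence (fail over validated) is a
  documented design decision, not an externally fixed convention.
* Hazard-ratio estimation is off-the-shelf only; no bespoke survival
  modeling is included.
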
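# Methods

`phoskin` implements a label-free phosphoproteomic analysis pipeline for
tumor cohorts profiled in two enrichment channels — a global pS/T (IMAC)
channel and a pY immunoprecipitation channel — from MaxQuant-dialect output
tables to subtype discovery, differential statistics, signature enrichment,
integrative inferred kinase activity (INKA) and survival association. This
note records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Data model and ingestion

A phosphosite is keyed by (protein accession, position, multiplicity); gene
symbols are annotation only, avoiding symbol-collision bugs. Positions are
1-based; flanking windows are 15-mers padded with `X` at protein ends.
Intensities of zero and absent intensities are both treated as *not
observed* (MaxQuant writes 0 for absent values) and stored as NaN; **no
imputation is performed anywhere** — every downstream statistic operates on
observed values only. Ingestion drops reverse-database hits, contaminants
and rows with no observed intensity, then applies the class-I filter
(localization probability ≥ 0.75, boundary inclusive). Phosphopeptide
spectral counts are aggregated from the evidence table by summing MS/MS
counts per (modified peptide, sample).

## Normalization and feature filtering

* Global pS/T channel: per-sample multiplicative scaling so each sample's
  median observed site intensity equals the across-sample median of
  per-sample medians. Any fixed target changes only a global constant; the
  median-of-medians keeps the data near its original scale.
* pY channel: per-sample scaling by mean(total lysate spectral counts) /
  sample total, the standard correction for IP input differences.
* Data presence (DP): keep features observed in ≥ f of samples (f = 0.10
  for discovery matrices, 1.00 for complete-case correlation analyses);
  boundaries inclusive.
* Variance filtering: median absolute deviation per feature over observed
  **log2** intensities (intensities are log-normal, and the fold-change
  gates imply ratio scale); top ⌈f·n⌉ features, ties broken by feature key
  so selection is deterministic.

## Consensus subtyping

Monti-style resampling consensus: for each candidate k, draw
⌊0.8·n⌋-sample subsamples without replacement (default 250 draws), cluster
each, and form M_k(i,j) = (times co-clustered) / (times co-sampled).
Features entering clustering are the DP- and MAD-filtered log2 matrix;
remaining missing entries are filled, *inside this step only*, with the
feature's observed minimum (low-abundance fill) because distance
computation needs complete vectors. Final labels cut an average-linkage
tree of 1 − M at k; cluster ids are renumbered by decreasing size.

The number of clusters is chosen from the area A(k) under the empirical CDF
of off-diagonal consensus entries: k grows while the relative increase
ΔA(k) = (A(k) − A(k−1))/A(k−1) stays above a threshold. Two choices here
were settled empirically:

* **Inner clusterer: average-linkage hierarchical (default).** k-means was
  considered but splits a true cluster differently on every subsample, so
  the consensus matrix at k > k_true accrues mid-range entries and A(k)
  keeps rising sharply (measured spurious ΔA ≈ 0.26 on two well-separated
  blobs); hierarchical splits are far more reproducible. k-means remains
  available (`inner="kmeans"`).
* **ΔA threshold 0.15.** Measured on planted-structure data, a genuine
  extra cluster gains ΔA ≥ ~0.45 while spurious extra clusters gain
  0.03–0.11; 0.15 separates the regimes with about 1.4× margin below and
  3× above. The chosen k can always be overridden (`choose_k`).

The resampling stream is keyed to lexicographic sample order, so permuting
input columns permutes the result exactly.

## Differential statistics

Empirical-Bayes moderated t/F: per-feature pooled within-group variance
s²_g with d_g residual dof (observed values only; features with < 2
observed values in any group are reported untested); prior (d0, s0²)
fitted by matching the mean and excess variance of log s²_g across features
(digamma/trigamma moment equations, trigamma inverted by Newton
iteration); posterior s²_post = (d0·s0² + d_g·s²_g)/(d0 + d_g); t or F on
d0 + d_g dof. d0 = 0 recovers the classic test exactly; when the observed
log-variance spread does not exceed its sampling spread, d0 = ∞ (complete
pooling) is used. Three-group screening uses the moderated F; its
fold-change gate is the largest-magnitude pairwise difference of group
means.

Gates: BH-adjusted q ≤ 0.05 and |log2 FC| ≥ 1 (fold change 2), both
boundaries inclusive; "fold change ≥ 2 or ≤ −2" is interpreted as a
difference of log2 group means. Small extreme-group survival contrasts gate
on the *unadjusted* p ≤ 0.05 instead — deliberately laxer, matching the
exploratory 3-vs-3 setting. The pre-ranked enrichment metric is
(−log10 p) · sign(log2 FC), with p = 0 capped at the smallest positive
double.

## Enrichment (ssGSEA / PTM-SEA style)

The enrichment score of a signature in one ranked profile is the summed
difference between the weighted in-set ECDF (weights |value|^α) and the
uniform out-of-set ECDF, walked over the descending ranking (ties broken by
key). α = 0.25 for per-sample intensity profiles, α = 1 for the pre-ranked
signed −log10 p metric. A signature covering every key scores 0 by
convention; all-tied profiles score 0 with a warning. Effective set size
(after intersection with available keys) must lie in [5, 1000], else the
signature is skipped and flagged. No permutation normalization is applied
by default. Site-level signatures are keyed by the 15-mer flanking window
as printed; duplicated windows are collapsed to the entry with the largest
row-sum intensity before scoring. Per-cluster summaries are arithmetic
means of member samples' scores.

## INKA

Per kinase and analysis unit, four evidence arms from spectral counts
(intensity mode available):

* C_kin — counts on the kinase's own phosphosites, activation-loop sites
  excluded (avoids double counting),
* C_act — counts on its activation-loop sites,
* C_psp — counts over curated substrate sites,
* C_nwk — counts over predicted substrate sites with prediction score
  ≥ 2.0 (configurable) and no curated edge from the same kinase.

Kinase-centric evidence K = C_kin + C_act and substrate-centric evidence
S = C_psp + C_nwk are integrated as the geometric mean I = √(K·S) — the
declared integration formula, isolated in one function (`inka_score`) for
easy substitution. Kinases with K > 0 but S = 0 are reported in a separate
kinase-centric-only list rather than ranked; scale is equivariant
(multiplying all counts by c multiplies every score by c, ranks unchanged).
Group profiles pool (sum) evidence over member samples before scoring, so
rare-but-strong evidence is retained; each kinase is annotated with DP%,
the percentage of the group's samples in which it scores individually.
Ranks break ties alphabetically.

## Survival

Per-kinase Spearman correlation of INKA scores with overall survival months
(exact permutation p for n ≤ 9, t-approximation otherwise; kinases scored
in < 3 samples skipped; constant vectors reported not-assessable). OS is
correlated as observed, without censoring adjustment; a caveat is logged
when censored samples are included. Short/long outcome groups split at a
bimodal cutoff: Gaussian KDE (Silverman bandwidth, 512-point grid) on OS;
if two or more modes exist — a local maximum must reach ≥ 10% of the
density peak to count, so negligible bumps in a sparse tail are not
mistaken for a component — the cutoff is the lowest density minimum
between the two largest modes, else none is reported. Kaplan–Meier curves,
medians and the two-group log-rank test are computed with lifelines.

## The synthetic cohort generator

The generator (`synthetic_data`) emulates a 42-tumor resected PDAC cohort
with two enrichment channels and planted ground truth; its defaults *are*
the study conditions that the tests and the acceptance script measure.

* **Design**: 3 subtypes (balanced), 18 kinases (12 S/T, 6 Y), 600 global
  and 150 pY sites, 8 substrate edges per kinase (35% predicted, scored
  Uniform(1,5)); each kinase owns one self site and one activation-loop
  site on its own protein. Substrate sets are disjoint across kinases where
  the pool allows, so each substrate site reflects one kinase's activity.
* **Activities**: a_{k,s} = 23 (log2 intensity of an average site) +
  3·[kinase assigned to subtype(s)] + N(0,1). One designated hyperactive
  kinase receives an extra +4 in its subtype — a dominant driver whose
  substrate phosphorylation stands well above the co-activated kinases of
  the same subtype, which is what a top-ranked kinase in an activity
  profile represents. One designated prognostic kinase drives survival.
* **Site intensities**: log2 I = Σ incoming a_{k,s} + N(0, 1); undriven
  sites get a per-site baseline ~ N(23, 1.5). A cellularity term
  (±1 log2 unit across the 20–80% purity range) couples signal to tumor
  content, so identification counts correlate with cellularity as in real
  cohorts.
* **Missingness** is missing-not-at-random: observation ~
  Bernoulli(logistic(−16 + 0.75·log2 I)), i.e. ~78% presence at the
  average site and steeply less below — about 25% missing overall.
* **Spectral counts** ~ Poisson(min(50, 5·2^(0.6·(log2 I − 23)))): counts
  grow sub-linearly with intensity and saturate, as MS/MS sampling does.
* **Localization**: ~90% of sites are class I (prob Uniform(0.75, 1)),
  the rest Uniform(0.2, 0.75).
* **Clinical**: survival ~ exponential with baseline median 18 months and
  log-hazard 0.8 per SD of the prognostic kinase's activity; 25% of
  samples censored (uniform fraction of the event time); 23/42
  treatment-naive; KRAS mutant 95.2% with allele variants at their
  reported cohort frequencies, TP53 mutant 73.8%; 9/42 samples lack the pY
  channel entirely (sample-level dropout, mechanism unmodeled). Optional
  TP53-linked sites (`tp53_effect`) plant a mutation-stratified contrast.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: peptide-level missingness correlation (one
synthetic phosphopeptide per site, multiplicity always 1), batch and
run-order effects, retention-time or spectral artifacts, stromal/CAF
admixture beyond a scalar cellularity term, correlated kinase–kinase
signaling beyond shared subtype membership, non-exponential survival
shapes, and the curated breadth of real kinase–substrate resources.
Recovery results on this cohort demonstrate that the pipeline's inference
is correct under its own assumptions, not that those assumptions hold for
any particular real cohort.

## Problem sizes and reproducibility

All randomness flows through explicit seeds; the pipeline derives one seed
per stage from the global seed and a fixed stage index, so adding a stage
never perturbs earlier stages, and a rerun with the same seed is
byte-identical. The test suite and `scripts/acceptance.py` use cohorts at
the default size (n = 42) with 5 replicates for consensus recovery, 25 for
kinase-ranking recovery, 50 for survival recovery, 10 for differential
recall, and 1000 replicates for null calibration of the moderated t,
Mann–Whitney and log-rank tests — sizes chosen to make the Monte-Carlo
error small relative to the margins being checked.

## Known limitations

* The INKA integration formula is a declared stand-in for the published
  pipeline's arithmetic (geometric mean of pooled arms, no cross-arm
  normalization or skewness diagnostics) and is isolated for substitution.
* OS correlation ignores censoring by design; with heavy censoring the
  Spearman association is attenuated and a proper survival model should be
  preferred.
* Multiplicity variants are kept as separate site keys; the collapsing
  behavior of other pipelines is not reproduced.
* The bimodal cutoff is a descriptive device; on unimodal survival
  distributions it correctly reports none, and callers must choose a
  fallback (the analysis scripts use the median).
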
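# Methods

## The measurement

`methtopo` summarizes a 450K-style methylation array sample by *global
methylome scores*: the arithmetic mean β-value over all probes falling in a
genomic class. Three classes are distance windows upstream of the
transcription start site (TSS) of the annotated gene —

* **R1**: 1–250 bp,
* **R2**: >250 bp–1 kb,
* **R3**: >1 kb–2 kb,

with bounds `(lower, upper]` so the windows partition and a probe printed on
a shared boundary falls in the window closer to the TSS. Distances are
strand-aware and counted on the promoter side only; probes downstream of
every annotated TSS receive no window. The remaining classes are the
CpG-island-relative annotation of the manifest (Island, N/S shore, N/S
shelf, open sea, where N is the lower-coordinate side), the composites
N = N_Shore ∪ N_Shelf and S = S_Shore ∪ S_Shelf, and the gene-feature groups
(TSS200, TSS1500, 5'UTR, first exon, body, 3'UTR). A probe contributes once
per class regardless of how many transcripts put it there; multi-gene probes
anchor to the nearest TSS, ties broken by lexicographic gene symbol.

Scores are computed on the β scale (β = meth/(meth+unmeth+100), the
GenomeStudio convention), because mean β is directly interpretable as
average fraction methylated; differential testing can additionally be run
on M-values, M = log2((max(meth,0)+α)/(max(unmeth,0)+α)) with α = 100,
which is the statistically better-behaved scale.

## Preprocessing chain

The order is fixed: (1) probe filtering, (2) type-I color-bias adjustment,
(3) between-sample quantile normalization of methylated and unmethylated
intensities separately, (4) type-I/type-II background equalization,
(5) β/M computation, (6) intra-sample three-state quantile correction of the
type-II β compression. Every step is deterministic and idempotent.

* **Filtering** retains probes confidently detected (detection p < 0.01) in
  ≥ 95% of samples, and drops SNP-measuring probes and sex-chromosome
  probes. (The retain-confident reading is deliberate: discarding probes
  that are *well* detected in most samples would invert the filter's
  purpose.)
* **Color bias**: per sample, the pooled type-I intensities of the
  smaller-median channel are scaled by the ratio of channel medians — a
  monotone map that equalizes channel medians exactly.
* **Quantile normalization** maps each sample's order statistics onto the
  across-sample mean of order statistics; ties resolve by stable sort.
* **Background equalization** matches the 5th-percentile total intensity of
  the two probe chemistries by subtracting an additive offset from the
  higher-background type's totals, spread proportionally over the two
  channels and floored at zero. Applying the offset to the total (rather
  than per channel) makes the contract exact and re-application the
  identity.
* **Type-II correction** is a three-state empirical quantile map: within
  each sample, type-II β values in the unmethylated (<0.2), hemimethylated
  (0.2–0.8) and methylated (>0.8) states are mapped onto the type-I β
  distribution of the same state at equal rank position p = rank/(n−1),
  clipped to the state interval. This preserves within-state rank order, is
  exactly the identity when the distributions already agree, and is
  idempotent. It replaces a full beta-mixture EM fit with hard state
  thresholds; the known limitation is that a compression strong enough to
  push a β mode across a threshold (e.g. 0.85 → below 0.8) mis-assigns
  those probes to the neighboring state. States with fewer than 10 type-I
  probes pass through unadjusted with a warning.

**A property worth knowing:** between-sample quantile normalization forces
identical marginal intensity distributions across samples, so it removes any
*net* cohort-level methylation shift. If tumors are globally hypomethylated
across most of the probe panel, every class-level tumor−normal difference is
biased toward zero by roughly the probe-averaged shift. This is inherent to
quantile normalization, not an implementation artifact; the synthetic
recovery experiments quantify it (≈ +0.006 bias on the 1–2 kb delta when
only the R1/R3 effects are planted, ≈ +0.02 when the full effect profile
is). Analyses that need absolute global deltas should use the direct
β-matrix input path, which skips intensity normalization.

## Statistics

Group comparisons use Mann–Whitney U (exact enumeration when the pooled
size is ≤ 20 without ties, otherwise the normal approximation with tie and
continuity corrections) and Kruskal–Wallis H with tie correction;
correlations use Spearman's ρ on average ranks; per-class tumor/normal
differences on M-value aggregates use Welch's t (the unequal-variance form,
since group spreads differ visibly between tumor and normal tissue).
Categorical associations use the **Freeman–Halton exact test** for r×c
tables: full recursive enumeration of all tables sharing the observed
margins with log-factorial arithmetic; the two-sided p is the sum of
multivariate hypergeometric probabilities of every table as probable or less
probable than the observed one (probability ties compared with relative
tolerance 1e-7). Each call verifies the enumerated probabilities sum to 1
within 1e-9 and refuses (rather than approximates) margin structures
admitting more than 5×10⁷ tables. Multiple testing uses strict Bonferroni
thresholds p < 0.05/m with the divisor recorded per report family
(15 for the clinicopathological battery, 5 for normal-mucosa and molecular
tables, 11 for the tumor-feature table).

CIMP status is classified from panel-gene calls: the 5-gene panel (CACNA1G,
IGF2, NEUROG1, RUNX3, SOCS1) is high when >3 genes are methylated; the
8-gene panel (plus CDKN2A, CRABP1, MLH1) is high when ≥6 are (the 6/8
convention; the threshold is a parameter because the published prose also
admits a strict ">6" reading, which `ogino_high_min=7` reproduces).
Partially methylated genes count as methylated; missing calls shrink the
assessed denominator and are logged.

## Synthetic cohorts

The generator emulates the structure the analysis consumes, at desk scale
(default 2,000 genes × 10 probes = 20,000 probes; 82 tumors — 32
conventional, 40 serrated, 10 hmMSI-H — and 35 adjacent normal mucosae).

* **Geometry**: each gene gets a TSS with an overlapping island
  (half-width 680 bp), shores within 2 kb of the island edges, shelves in
  the next 2 kb, open sea beyond; probes are placed in R1/R2/R3 and in
  downstream shore/shelf/open-sea positions so every class is populated.
  The island half-width and the bimodal baseline weights (high-mode weight
  0.22 on islands, 0.717 on shores, 0.78 shelves, 0.80 open sea; modes 0.10
  and 0.85 with probe-level logit jitter SD 0.3) were calibrated
  analytically so the expected normal-mucosa scores are ≈ 0.266 / 0.423 /
  0.634 at R1/R2/R3 — the methylation topography of normal colonic mucosa.
* **Effects** are additive on the logit scale. For each (class, subtype)
  the logit shift is solved by bisection so the planted *β-scale class-mean
  difference* equals the configured target; achieved values are written to
  the truth record. Defaults plant hypermethylation nearest the TSS
  (strongest in hmMSI-H) and hypomethylation at 1–2 kb, shelves and open
  sea (strongest in conventional carcinoma, serrated intermediate), with
  composition-weighted overall R1/R2/R3 deltas of about +0.0036 / −0.0116 /
  −0.0384.
* **Between-sample variation**: each sample draws a trivariate Gaussian
  effect (proximal / mid / distal probe strata) with rank correlations
  0.542 (prox–mid), 0.883 (mid–dist) and 0.268 (prox–dist) — the
  methylation-continuum structure in which only adjacent distance windows
  correlate — converted to latent Pearson via ρ = 2·sin(πρ_s/6). Logit SDs
  are 0.02 (normal) and 0.04 (tumor), giving normal-mucosa score IQRs of a
  few thousandths and wider tumor spreads.
* **Noise and artifacts**: β values are drawn from a beta distribution with
  precision 200 (per-probe SD ≈ 0.03); intensities come from a log-normal
  total (median 6000, σ 0.3) defined *inclusive* of the β offset so the
  offset-100 β recovers the simulated value exactly. Planted artifacts the
  chain must remove: a 1.3× green-channel bias on type-I probes, a 0.9
  type-II compression toward 0.5, detection failures (0.1% sporadic entries
  plus 0.5% dead probes failing in ~30% of samples), 1% SNP probes and 2%
  sex-chromosome probes.

**What the generator does not emulate**: spatial chip artifacts, batch
structure, per-sample scanner gain differences, copy-number interference,
probe cross-hybridization, realistic per-gene CIMP co-methylation structure
(panel calls depend on subtype only), and the full 485k-probe panel. Tests
passing on these cohorts therefore demonstrate that the *machinery*
(annotation, normalization contracts, scoring, tests, classification)
behaves as specified under controlled truth — not that any biological claim
transfers to real arrays.

**Measured sample correlations undershoot planted values.** The
adjacent-window Spearman correlations are planted as population values; the
n=35 sample estimate carries the usual downward rank-estimator bias plus a
little β-noise dilution, so replicate-averaged measurements center near
0.51 and 0.84 rather than 0.542 and 0.883. This mirrors how a single real
cohort's reported correlation is itself a noisy draw.

## Numerical choices and degenerate inputs

Logit calibration runs 200 bisection steps on [−8, 8]; β means are clipped
to [1e-4, 1−1e-4] before beta sampling. Exact-test probability ties use
relative tolerance 1e-7. Contingency tables with a zero margin are
degenerate (p = 1, warning). Rank tests on fully constant pooled data
return p = 1; Spearman on constant input raises. A Welch test with two
zero-variance groups returns t = 0, p = 1 when means agree. All steps are
seed-free and deterministic; the only randomness in the package is the
synthetic generator, driven by a single integer seed through one generator
stream in documented draw order (geometry, sample sheet, baselines, sample
effects, β draws, intensities, detection).

## Problem sizes used in the shipped checks

The test suite uses cohorts of 30–2,000 genes; the parameter-recovery check
runs 20,000 probes × 70 samples through the full chain, and the null
calibration uses 500 replicate 300-probe cohorts. The acceptance script
averages score-based quantities over 48 replicate study-scale cohorts and
runs a 500-replicate null calibration; these sizes give Monte-Carlo standard
errors well below the effects being measured while keeping a laptop-scale
run under a minute.
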
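# Methods

## Scope and data model

The package analyzes a tumor/normal cohort described by six tables:
transcript annotation (GTF, 1-based inclusive externally, 0-based half-open
internally), per-event inclusion/skipping junction counts, a transcript
abundance matrix (TPM-like), a gene expression matrix, a MAF-like mutation
table, and a clinical table. All tabular I/O is UTF-8 TSV with `NA` for
missing values; floats are serialized with `%.17g` and re-read with
round-trip parsing, so write-then-read is bit-identical. Sample identifiers
are opaque, case-sensitive strings; joins are exact. Read alignment,
junction extraction and variant calling are out of scope — counts and calls
arrive as tables.

## Splice events and ψ

Events are enumerated by pairwise comparison of a gene's transcripts:
cassette exons (SE) where one transcript joins the flanking exons directly;
mutually exclusive exons (MXE) between shared flank boundaries; alternative
5′/3′ splice sites where two exons share one boundary and splice to a common
partner at the other (donor vs acceptor resolved by strand); retained
introns (RI) where one transcript's intron lies strictly inside the other's
exon. Events are deduplicated on (type, coordinates) and ordered
deterministically, so enumeration is invariant to transcript input order;
event identifiers are content hashes of (gene, type, coordinates).

ψ is the length-normalized junction ratio
ψ = (I/len_inc) / (I/len_inc + S/len_skip), with effective lengths equal to
the number of distinct diagnostic junctions (SE: 2 vs 1; MXE: 2 vs 2;
A5SS/A3SS: 1 vs 1; RI: 1 vs 1, the retention form supported by intron-body
counts supplied in the table). ψ is undefined below a coverage floor
(default 10 total supporting reads) — this distinguishes "confidently
skipped" (ψ = 0) from "not measurable". The transcript-ratio route divides
inclusion-isoform abundance by the combined abundance of the designated
inclusion and exclusion isoform sets, undefined when both are zero. The two
estimators coincide on noise-free two-isoform data, which the test suite
asserts to 1e-9.

## Differential splicing

Per event, samples with undefined ψ are dropped; events with fewer than 3
defined values or less than `min_defined_frac` (default 0.5) defined in
either group are not tested. The test is a two-sided Wilcoxon rank-sum on
per-sample ψ — exact enumeration for tie-free groups under 10 samples,
normal approximation with continuity correction otherwise — with
Benjamini–Hochberg correction across tested events. Significance requires
both |Δψ| > 0.15 (Δψ = mean ψ difference) and q < 0.05; significant events
are directional (included/skipped). A rank test was chosen deliberately: it
is distribution-free on a bounded quantity, and the |Δψ| gate (not the
p-value alone) carries the effect-size requirement. Variability is
summarized as the empirical CDF of per-event ψ standard deviations.

## Burden statistics

**Entropy.** For each multi-isoform gene, P_i = abundance_i / Σ abundance
over all annotated isoforms (zeros permitted), H = −Σ P_i ln P_i with
0·ln 0 := 0. Natural logarithm throughout — the median comparison between
groups is base-invariant, but the unit (nats) is fixed and reported. Genes
with total abundance below 1 (TPM-equivalent) per sample are skipped, the
same floor used for expression filtering in enrichment. The per-sample
burden is the median H over qualifying multi-isoform genes.

**Driver alteration fractions.** Per event, the normal reference is the
mean ψ over normal samples with defined ψ (median available by option). A
(tumor sample, gene) pair is splicing-altered iff the maximum over the
gene's events of |ψ − reference| exceeds 0.30; all events with defined ψ
are considered, with a caller-level option to restrict to significant
events. Genes without usable events, and samples without defined ψ for a
gene, contribute to neither numerator nor denominator. Mutation fractions
count genes with a qualifying call: medium/high-impact SNV/indel
(missense, frameshift, nonsense, splice-site) at VAF > 0.2 and depth > 20,
copy gain ≥ 5 copies, or homozygous deletion. Pathway status is mutant on
any qualifying call in the set, wild-type only when every set gene is
covered and entirely free of alteration records (sub-threshold SNVs and
modest copy changes block wild-type without conferring mutant), otherwise
indeterminate. Splicing and mutation fractions are compared with Welch's
two-sided t-test; across multiple cohorts the p-values are BH-corrected.

## Enrichment

Pre-ranked GSEA uses the weighted Kolmogorov–Smirnov running sum with
weight exponent 1: hits add |score|^w normalized by total hit weight,
misses subtract uniformly; ES is the signed extreme deviation (|ES| ≤ 1).
The null permutes gene labels with a seeded generator (default 1,000
permutations); NES divides ES by the mean |null ES| of matching sign, and p
uses the add-one permutation estimate. Across a collection, sets outside
[5, 500] hits are skipped and FDR is BH over permutation p-values. Ranking
scores: expression mode sign(fold change)·(−log₁₀ adjusted p); splicing
mode −log₁₀ of the gene's minimum adjusted p over its events (zero p
clamped to the smallest positive double).

ssGSEA ranks genes within one sample (descending expression, ties broken by
gene identifier) after discarding genes with mean expression < 1, weights
rank r (top gene r = N) as r^0.75, and accumulates the difference between
the weighted in-set ECDF and the uniform out-of-set ECDF. Because weights
are rank-based, scores are invariant under monotone transformations of a
sample's values for any exponent; exponent 0 gives the pure rank mode.
Scores are optionally normalized by their range across samples. The exact
normalization of hosted ssGSEA implementations varies; this one is fixed,
documented, and exposed through the exponent and normalization flags.

Correlation analyses use Pearson's r (two-sided) with pairwise deletion of
missing values, requiring ≥ 3 complete pairs, BH-corrected within the
requested family. The correlated-target proportion reports, per regulator,
the fraction of targets with q < 0.05; the "All" mode uses the regulator
with the largest across-sample variance as the composite reference.

## Protein impact

An event's variable region (cassette exon, alternative segment, or retained
intron) is intersected with the exonic CDS of a reference transcript — the
coding transcript containing the inclusion form with the longest CDS, ties
broken by identifier. Coding offsets run in transcription order, making the
mapping strand-symmetric; residue k covers offsets 3(k−1)..3k−1, intervals
are 1-based closed, and an event is frame-preserving iff the affected
coding length ≡ 0 (mod 3). Events not touching the CDS yield an empty
interval. Gene-set summaries count a gene for a feature class when any of
its events' residue intervals intersects a feature of that class
(closed-interval overlap; PTM sites are single residues), over the
denominator of set genes with ≥ 1 coding event. Direct overlap is the
criterion; downstream consequences of frameshifts are reported only through
the frame flag.

## Survival

Stratification orders samples by (value, sample_id) and cuts at the
empirical quartile ranks, so |Q1| and |Q4| differ by at most one and ties —
common for burden fractions with a 50-gene denominator — are resolved
deterministically; for tie-free values this coincides with thresholding at
interpolated percentiles. All-equal values are rejected as degenerate. The
Q4-vs-Q1 design drops Q2/Q3. Two-group tests are weighted log-rank
(uniform weights, or number-at-risk weights for Gehan–Breslow–Wilcoxon;
both exposed since early-difference sensitivity differs) with chi-square
p on 1 df; Cox proportional hazards uses the partial likelihood with Efron
tie handling, Wald intervals, a guard of ≥ 5 events per covariate, and
rejection of constant covariates. Kaplan–Meier, log-rank and Cox are
delegated to lifelines.

## Synthetic cohort generator

The generator emulates the statistical structure of a tumor/normal splicing
study at desk scale; defaults are one fixed choice of study conditions
(64 tumors, 20 normals, 120 genes, 400 events, 50-gene driver census).

* **Junction counts.** Baseline ψ₀ ~ U(0.05, 0.95) per event; 10% of events
  are planted with a ±0.30 tumor shift, scaled per tumor by a "splicing
  instability" factor u ~ U(0, 2) so tumors differ in how many events cross
  the alteration threshold — this is what spreads driver-splice burden
  across samples. Depth ~ Poisson(100) per event/sample; counts are
  beta-binomial with ρ = 0.01 (biological overdispersion on top of
  sampling noise; ρ → 0 recovers the binomial). Counts are emitted
  pre-normalized (both effective lengths 1) so the estimator's length
  correction cancels in expectation.
* **Isoform ratios.** Normal samples draw gene isoform ratios from a
  Dirichlet concentrated (α₀ = 100) around a dominant-isoform composition
  (85% of mass on one isoform); tumors draw from a Dirichlet around the
  uniform composition at low concentration (α₀ = 5). Because the expected
  entropy of a Dirichlet draw is bounded above by the entropy of its mean,
  the group difference is planted in the mean composition — promiscuous
  isoform usage in tumors versus one dominant isoform in normal tissue —
  with the concentrations acting as dispersion knobs. Abundance =
  ratio × log-normal gene expression.
* **NF1-like switch and pathway coupling.** One designated two-isoform gene
  has inclusion ratio ~ Beta around 0.30 in normals and 0.75 in tumors
  (tight, concentration 50). Pathway-set genes receive an expression boost
  exp(shift · σ(8(ψ − ψ_mid))) — a logistic link in that sample's NF1-like
  inclusion — reproducing a monotone ψ-to-activity association without
  asserting mechanism.
* **Mutations.** Per (tumor, driver gene) qualifying SNVs at rate 0.05
  (VAF ~ U(0.25, 0.6), depth 20 + Poisson(80)); pathway genes at rate 0.01;
  sub-threshold decoys (low VAF or low depth) at rate 0.05 and modest
  copy-number events to exercise the filters; gains ≥ 5 and homozygous
  deletions at low rates.
* **Survival.** Exponential event times with hazard
  (1/600 days)·exp(3.5 · driver-splice fraction) — a baseline in the range
  of aggressive glioma median survival with a hazard span of ~4–6 between
  burden extremes — and independent exponential censoring (rate 1/1500).

All randomness flows from one mandatory seed through spawned generators;
a fixed seed reproduces every table bit-for-bit, and the end-to-end
pipeline output is byte-identical across runs.

### What the generator does not emulate

Real genome coordinates and splice-site sequences; expression-level
confounding of ψ estimates; correlated mutation co-occurrence and subclonal
structure; cohort substructure (subgroups, batch effects); non-proportional
hazards. Tests passing on this cohort demonstrate correctness of the
statistics and calibration of the callers under the stated model, not
robustness to artifacts of real RNA-seq.

## Numerical choices and degenerate inputs

BH correction via statsmodels throughout; rank tests via scipy with
midranks. Identical groups short-circuit to p = 1 rather than relying on
tie-corrected variance. Adjusted p = 0 is clamped to the smallest positive
double before logs; permutation p-values use add-one estimates. Entropy
uses 0·ln 0 := 0. ψ with zero total support is undefined, not zero.
Quartile stratification refuses all-equal inputs; Cox fits refuse constant
covariates and under-evented designs rather than returning unstable
estimates.

## Problem sizes in the test and acceptance runs

The default synthetic cohort (above) drives the end-to-end checks; the
calibration suites use 500-event null cohorts at 20 vs 20 samples over 20
replicates, 100-event planted cohorts over 3 replicates, Cox recovery at
n = 500 over 20 replicates, and 200-replicate null log-rank calibration —
sizes chosen so every Monte-Carlo margin stated in the tests is meaningful
while the whole suite stays quick to run.

## Known limitations

The differential caller is a rank test on point estimates of ψ and does not
model read-count uncertainty hierarchically, so its power at low coverage
is below likelihood-based callers; the RI route depends entirely on the
supplied intron-retention counts; GSEA normalization follows the classic
sign-matched mean convention and small permutation counts floor the
attainable p; the "All" composite regulator is one of several reasonable
readings of a maximally-variant-member analysis and is documented as such.
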
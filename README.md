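# spliceburden

Alternative-splicing burden analysis for bulk tumor/normal RNA-seq cohorts,
motivated by high-grade glioma, where splicing alters cancer-driver genes far
more often than point mutation does and where that splicing burden — but not
mutation burden — tracks patient survival. The package is a library for
computational biologists who have junction counts, isoform abundances,
mutation calls and clinical follow-up on a cohort and want to quantify
splicing dysregulation, score it against a driver-gene census, and test its
clinical impact.

## What it computes

**Percent spliced in (ψ).** For a splice event with inclusion reads *I* over
`len_inc` diagnostic junctions and skipping reads *S* over `len_skip`:

    ψ = (I / len_inc) / (I / len_inc + S / len_skip)

masked below a coverage floor (default 10 reads). The same quantity is also
derived from isoform abundances as ψ = Σ(inclusion TPM) / Σ(total TPM) — the
NF1-I/NF1-II style isoform-ratio readout; on noise-free two-isoform data the
two routes agree exactly.

**Differential splicing.** Two-sided Wilcoxon rank-sum on per-sample ψ,
Benjamini–Hochberg corrected; an event is significant when |Δψ| > 0.15 and
q < 0.05, classified as preferentially included or skipped, per event type
(SE, MXE, A5SS, A3SS, RI).

**Isoform-entropy burden.** Per gene *G* with *g* isoforms and transcript
ratios *Pᵢ*, the Shannon entropy

    H(g) = − Σᵢ Pᵢ · ln Pᵢ ,    0 ≤ H ≤ ln g

and per sample the median H over multi-isoform genes — higher means more
isoform diversity.

**Driver splicing vs mutation burden.** A (sample, gene) pair is
splicing-altered when any event of the gene deviates more than 0.30 ψ from
its normal-tissue reference; mutation-altered when the gene carries a
medium/high-impact SNV/indel at VAF > 0.2 and depth > 20, a copy gain of 5+
copies, or a homozygous deletion. Per-sample fractions over a driver census
are compared by Welch's t-test. The same qualifying-call rules drive
pathway-level mutant/wild-type classification (wild-type requires every
pathway gene covered and alteration-free).

**Enrichment.** Pre-ranked GSEA (weighted Kolmogorov–Smirnov running sum,
seeded permutation null, NES) with the splicing ranking score
−log₁₀(min adjusted p per gene); single-sample ssGSEA (rank-weighted ECDF
difference, genes with mean expression < 1 discarded) as the pathway
activation score; Pearson correlations with BH control across families.

**Survival.** Empirical quartile stratification (Q4 vs Q1), Kaplan–Meier,
log-rank and Gehan–Breslow–Wilcoxon tests, and Cox proportional hazards
(Efron ties) via lifelines.

**Synthetic cohorts.** `spliceburden.synthetic` generates a seeded
tumor/normal bundle with planted Δψ effects, an entropy gradient,
decoy-laden mutation tables, a pathway program coupled to an NF1-like
isoform switch, and burden-linked survival — ground truth included, so every
stage is testable end to end without controlled-access data.

## Worked example

`examples/` holds one short script per capability. From the repository root:

```bash
python examples/03_burden_and_pathways.py
```

prints, for the default seed-7 synthetic cohort (64 tumors, 20 normals,
50 driver genes):

```
median entropy burden: tumor 0.939 vs normal 0.501 nats
driver burden per sample: splicing 0.232 vs mutation 0.063 (Welch t = 5.0, p = 5.07e-06)
NF1-like inclusion psi vs pathway ssGSEA score: r = 0.982, p = 5.1e-61
```

Tumors express more isoforms per gene (higher median entropy), splicing
alters ~23% of driver genes per sample versus ~6% for qualifying mutations,
and the NF1-like inclusion ratio tracks the pathway activation score.
Continuing with survival:

```bash
python examples/04_survival.py
```

```
Q1 n = 16, Q4 n = 16
log-rank: chi2 = 11.8, p = 5.92e-04
Cox q4_burden: HR = 6.51 [2.44, 17.38], p = 0.000187
```

i.e. tumors in the top splicing-burden quartile die faster, and the effect
survives adjustment for pathway mutation status and NF1-like expression.

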
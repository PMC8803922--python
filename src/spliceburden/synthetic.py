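"""Seeded synthetic tumor/normal cohort generator.

Produces every table the pipeline consumes — annotation, splice-event
junction counts, isoform abundances, gene expression, mutation calls,
clinical follow-up — with known ground truth emitted alongside, so the full
analysis is testable end-to-end without any external data.

Statistical structure emulated:

* event inclusion — per event a baseline psi ~ U(0.05, 0.95); a planted
  fraction of events shifts tumor psi by +/- ``delta_psi_effect`` scaled by
  a per-tumor "splicing instability" factor, so tumors differ in how many
  driver-gene events deviate from the normal reference; junction counts are
  beta-binomial (biological overdispersion on top of sampling noise);
* isoform ratios — normal samples draw near a dominant-isoform composition
  (one isoform carries most of the mass, tightly concentrated), tumors draw
  near the uniform composition at low concentration: tumors therefore
  express more isoforms and carry higher Shannon-entropy splicing burden;
* one designated two-isoform "NF1-like" gene whose inclusion-isoform ratio
  is shifted upward in tumors and coupled through a logistic link to a
  planted expression shift in a pathway gene set (the RAS-activation
  analog), giving a positive psi-to-pathway-score correlation;
* mutations — per (tumor sample, driver gene) Bernoulli qualifying calls,
  plus sub-threshold decoys and copy-number events to exercise filtering;
* survival — exponential times with hazard proportional to
  exp(log_hr_burden * driver-splice fraction), independent exponential
  censoring.

All randomness flows from a single mandatory seed through spawned
generators, so a fixed seed reproduces the bundle bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .types import (
    ClinicalRecord,
    GeneModel,
    GeneSet,
    GenomicInterval,
    MutationCall,
    SpliceEvent,
    TranscriptModel,
    event_id_for,
)
from . import io as sb_io

EVENT_TYPE_PROBS = {"SE": 0.60, "MXE": 0.20, "A5SS": 0.08, "A3SS": 0.08, "RI": 0.04}
ISOFORM_COUNT_PROBS = {1: 0.25, 2: 0.30, 3: 0.20, 4: 0.15, 5: 0.10}


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults mirror the study design
    (64 tumors vs 20 normal-tissue samples, a 50-gene driver census,
    |delta psi| = 0.30 splicing alterations, ~5% per-gene mutation rate)."""

    seed: int
    n_tumor: int = 64
    n_normal: int = 20
    n_genes: int = 120
    n_events: int = 400
    planted_fraction: float = 0.10
    delta_psi_effect: float = 0.30
    read_depth: float = 100.0
    overdispersion: float = 0.01  # beta-binomial rho; 0 = pure binomial
    dirichlet_conc_normal: float = 100.0
    dirichlet_conc_tumor: float = 5.0
    normal_dominant_fraction: float = 0.85
    n_driver_genes: int = 50
    mutation_prob: float = 0.05
    pathway_mutation_prob: float = 0.01  # per pathway gene; ~1/3 of samples mutant
    decoy_prob: float = 0.05
    cnv_gain_prob: float = 0.01
    cnv_del_prob: float = 0.005
    cnv_neutralish_prob: float = 0.01  # 3-4 copies: CN change, non-qualifying
    pathway_size: int = 40
    pathway_shift: float = 1.0  # log-scale expression shift at full activation
    nf1_normal_psi: float = 0.30
    nf1_tumor_psi: float = 0.75
    nf1_coupling_slope: float = 8.0
    gene_expression_mu: float = 20.0  # median TPM of the log-normal gene level
    gene_expression_sigma: float = 1.0
    sample_noise_sigma: float = 0.2
    baseline_hazard: float = 1.0 / 600.0  # per day
    log_hr_burden: float = 3.5  # per unit driver-splice fraction
    censor_rate: float = 1.0 / 1500.0  # per day; 0 = no censoring

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("planted_fraction", "mutation_prob", "decoy_prob",
                     "cnv_gain_prob", "cnv_del_prob", "cnv_neutralish_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dirichlet_conc_normal <= 0 or self.dirichlet_conc_tumor <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ValueError("overdispersion must be in [0, 1)")

    @staticmethod
    def from_yaml(path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return CohortConfig(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class CohortBundle:
    config: CohortConfig
    tumor_samples: list[str]
    normal_samples: list[str]
    genes: list[GeneModel]
    transcript_to_gene: dict[str, str]
    events: dict[str, SpliceEvent]
    events_by_gene: dict[str, list[str]]
    counts: pd.DataFrame  # event_id, sample_id, inc_count, skip_count
    event_truth: pd.DataFrame  # per event: gene, etype, psi_normal, psi_tumor, planted
    abundance: pd.DataFrame  # transcripts x samples
    expression: pd.DataFrame  # genes x samples
    entropy_truth: pd.DataFrame  # genes x samples true-ratio entropy (multi-isoform)
    driver_set: GeneSet
    pathway_set: GeneSet
    nf1_gene: str
    nf1_inclusion_transcript: str
    nf1_exclusion_transcript: str
    nf1_truth: pd.Series  # per-sample true inclusion ratio
    tumor_instability: pd.Series  # per-tumor planted-effect scale
    mutations: list[MutationCall]
    clinical: list[ClinicalRecord]

    @property
    def samples(self) -> list[str]:
        return self.normal_samples + self.tumor_samples


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_EXON_LEN = 100
_INTRON_LEN = 200
_N_EXONS = 6
_GENE_SPACING = 10_000
_CASSETTE_LEN = 63  # NF1-like cassette: 21 codons


def _make_gene(gene_id: str, index: int, n_isoforms: int, cassette: bool = False) -> GeneModel:
    """A toy gene: a chain of exons; alternate isoforms skip one internal
    exon each (or the designated cassette for the NF1-like gene)."""
    base = 1_000 + index * _GENE_SPACING
    strand = "+" if index % 2 == 0 else "-"
    chrom = "chr1"
    starts = [base + i * (_EXON_LEN + _INTRON_LEN) for i in range(_N_EXONS)]
    exons = [GenomicInterval(chrom, s, s + _EXON_LEN, strand) for s in starts]
    if cassette:
        exons[2] = GenomicInterval(chrom, starts[2], starts[2] + _CASSETTE_LEN, strand)
    cds = GenomicInterval(chrom, exons[0].start + 30, exons[-1].end - 31, strand)
    txs = []
    for k in range(n_isoforms):
        if k == 0:
            keep = exons
        else:
            skip_idx = 1 + ((k - 1) % (_N_EXONS - 2)) + (1 if cassette else 0)
            skip_idx = min(skip_idx, _N_EXONS - 2)
            if cassette:
                skip_idx = 2  # NF1-like: second isoform always skips the cassette
            keep = [e for i, e in enumerate(exons) if i != skip_idx]
        txs.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{k + 1}", gene_id=gene_id,
                exons=keep, cds=cds,
            )
        )
    return GeneModel(gene_id, txs)


def _make_annotation(config: CohortConfig, rng: np.random.Generator):
    counts = np.array(list(ISOFORM_COUNT_PROBS.keys()))
    probs = np.array(list(ISOFORM_COUNT_PROBS.values()))
    genes = []
    nf1_index = config.n_driver_genes + config.pathway_size
    if nf1_index >= config.n_genes:
        raise ValueError("n_genes too small for driver + pathway sets plus NF1-like gene")
    for i in range(config.n_genes):
        gid = f"G{i + 1:04d}"
        if i == nf1_index:
            genes.append(_make_gene(gid, i, 2, cassette=True))
        else:
            g = int(rng.choice(counts, p=probs))
            genes.append(_make_gene(gid, i, g))
    t2g = {tx.transcript_id: g.gene_id for g in genes for tx in g.transcripts}
    return genes, t2g, genes[nf1_index].gene_id


# ---------------------------------------------------------------------------
# splice-event counts
# ---------------------------------------------------------------------------

def _synthetic_event(gene_id: str, etype: str, serial: int) -> SpliceEvent:
    """A schematic event record for a simulated junction-count unit.

    Counts are emitted pre-normalized (per-junction averages), so both
    effective lengths are 1 and the psi estimator reduces to I / (I + S).
    """
    a = 10_000 + serial * 1_000
    coords = (a, a + 100, a + 200, a + 300)
    return SpliceEvent(
        event_id=event_id_for(gene_id, etype, coords),
        gene_id=gene_id,
        etype=etype,
        chrom="chr1",
        strand="+",
        inclusion_junctions=frozenset() if etype == "RI" else frozenset({(a, a + 100)}),
        skipping_junctions=frozenset({(a, a + 300)}),
        variable_regions=(GenomicInterval("chr1", a + 100, a + 200, "+"),),
        len_inc=1,
        len_skip=1,
        coords=coords,
    )


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    """Counts ~ BetaBinomial(n, p, rho); rho -> 0 degenerates to Binomial."""
    p = np.clip(p, 1e-9, 1 - 1e-9)
    if rho <= 0:
        return rng.binomial(n, p)
    scale = (1.0 - rho) / rho
    draw_p = rng.beta(p * scale, (1.0 - p) * scale)
    return rng.binomial(n, draw_p)


def simulate_event_counts(
    config: CohortConfig,
    rng: np.random.Generator,
    genes: list[GeneModel],
    tumor_samples: list[str],
    normal_samples: list[str],
    tumor_instability: pd.Series,
):
    """Junction counts for ``n_events`` events plus ground truth.

    Returns (counts long table, truth table, events dict, events_by_gene).
    Planted events shift tumor psi by delta_psi_effect scaled per tumor by
    its instability factor; counts are beta-binomial around the true psi.
    """
    gene_ids = [g.gene_id for g in genes]
    etypes = list(EVENT_TYPE_PROBS)
    etype_p = np.array([EVENT_TYPE_PROBS[t] for t in etypes])

    events: dict[str, SpliceEvent] = {}
    events_by_gene: dict[str, list[str]] = {}
    truth_rows = []
    count_rows = []
    n_planted = int(round(config.planted_fraction * config.n_events))
    samples = normal_samples + tumor_samples

    for serial in range(config.n_events):
        gene_id = gene_ids[serial % len(gene_ids)]
        etype = etypes[int(rng.choice(len(etypes), p=etype_p))]
        ev = _synthetic_event(gene_id, etype, serial)
        events[ev.event_id] = ev
        events_by_gene.setdefault(gene_id, []).append(ev.event_id)

        psi0 = float(rng.uniform(0.05, 0.95))
        planted = serial < n_planted
        sign = 1.0 if rng.random() < 0.5 else -1.0

        depths = rng.poisson(config.read_depth, size=len(samples))
        for sample, depth in zip(samples, depths):
            if planted and sample in tumor_instability.index:
                shift = sign * config.delta_psi_effect * float(tumor_instability[sample])
                psi_true = float(np.clip(psi0 + shift, 0.01, 0.99))
            else:
                psi_true = psi0
            inc = int(_beta_binomial(rng, np.array([depth]), np.array([psi_true]),
                                     config.overdispersion)[0])
            count_rows.append((ev.event_id, sample, inc, int(depth) - inc))

        psi_tumor_nominal = (
            float(np.clip(psi0 + sign * config.delta_psi_effect, 0.01, 0.99))
            if planted else psi0
        )
        truth_rows.append((ev.event_id, gene_id, etype, psi0, psi_tumor_nominal, planted))

    counts = pd.DataFrame(
        count_rows, columns=["event_id", "sample_id", "inc_count", "skip_count"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "gene_id", "etype", "psi_normal", "psi_tumor", "planted"],
    )
    return counts, truth, events, events_by_gene


# ---------------------------------------------------------------------------
# isoform abundances
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simulate_isoform_abundances(
    config: CohortConfig,
    rng: np.random.Generator,
    genes: list[GeneModel],
    tumor_samples: list[str],
    normal_samples: list[str],
    nf1_gene: str,
    pathway_genes: frozenset[str],
):
    """Transcript abundances with planted entropy and pathway structure.

    Normal samples draw isoform ratios around a dominant-isoform mean at
    high concentration (one isoform carries ``normal_dominant_fraction`` of
    the mass); tumors draw around the uniform mean at low concentration, so
    tumor entropy is stochastically higher. The NF1-like gene's inclusion
    ratio follows designed group means, and pathway-set genes receive an
    expression boost that is a logistic function of that sample's NF1-like
    inclusion — the planted psi-to-pathway-activity coupling.

    Returns (abundance, expression, entropy_truth, nf1_truth, inc_tx, exc_tx).
    """
    samples = normal_samples + tumor_samples
    is_tumor = {s: (s in set(tumor_samples)) for s in samples}

    nf1_model = next(g for g in genes if g.gene_id == nf1_gene)
    # inclusion isoform = the transcript containing the cassette exon (t1)
    inc_tx = f"{nf1_gene}.t1"
    exc_tx = f"{nf1_gene}.t2"
    assert {inc_tx, exc_tx} == {t.transcript_id for t in nf1_model.transcripts}

    # per-sample NF1-like inclusion ratio; concentration 50 keeps draws tight
    nf1_psi = {}
    for s in samples:
        mean = config.nf1_tumor_psi if is_tumor[s] else config.nf1_normal_psi
        nf1_psi[s] = float(rng.beta(mean * 50.0, (1.0 - mean) * 50.0))
    nf1_truth = pd.Series(nf1_psi, dtype=float).sort_index()

    psi_mid = 0.5 * (config.nf1_normal_psi + config.nf1_tumor_psi)

    abundance_rows = {}
    entropy_rows = {}
    gene_expr = {}
    for gene in genes:
        g = len(gene.transcripts)
        mu = rng.lognormal(np.log(config.gene_expression_mu),
                           config.gene_expression_sigma)
        expr_noise = rng.lognormal(0.0, config.sample_noise_sigma, size=len(samples))
        expr = mu * expr_noise
        if gene.gene_id in pathway_genes:
            activation = 1.0 / (
                1.0 + np.exp(-config.nf1_coupling_slope
                             * (nf1_truth[samples].to_numpy() - psi_mid))
            )
            expr = expr * np.exp(config.pathway_shift * activation)
        gene_expr[gene.gene_id] = dict(zip(samples, expr))

        ratios = np.empty((len(samples), g))
        if gene.gene_id == nf1_gene:
            for j, s in enumerate(samples):
                ratios[j] = [nf1_psi[s], 1.0 - nf1_psi[s]]
        elif g == 1:
            ratios[:] = 1.0
        else:
            dominant = np.full(g, (1.0 - config.normal_dominant_fraction) / (g - 1))
            dominant[0] = config.normal_dominant_fraction
            uniform = np.full(g, 1.0 / g)
            for j, s in enumerate(samples):
                if is_tumor[s]:
                    alpha = config.dirichlet_conc_tumor * uniform
                else:
                    alpha = config.dirichlet_conc_normal * dominant
                ratios[j] = rng.dirichlet(alpha)

        if g >= 2:
            entropy_rows[gene.gene_id] = {
                s: _entropy(ratios[j]) for j, s in enumerate(samples)
            }
        for k, tx in enumerate(gene.transcripts):
            abundance_rows[tx.transcript_id] = {
                s: ratios[j, k] * gene_expr[gene.gene_id][s]
                for j, s in enumerate(samples)
            }

    abundance = pd.DataFrame(abundance_rows).T.sort_index()[sorted(samples)]
    abundance.index.name = "transcript_id"
    expression = pd.DataFrame(gene_expr).T.sort_index()[sorted(samples)]
    expression.index.name = "gene_id"
    entropy_truth = pd.DataFrame(entropy_rows).T.sort_index()[sorted(samples)]
    entropy_truth.index.name = "gene_id"
    return abundance, expression, entropy_truth, nf1_truth, inc_tx, exc_tx


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

_QUAL_IMPACTS = ("missense", "frameshift", "nonsense", "splice_site")


def simulate_mutations(
    config: CohortConfig,
    rng: np.random.Generator,
    tumor_samples: list[str],
    driver_genes: GeneSet,
    pathway_genes: Optional[GeneSet] = None,
) -> list[MutationCall]:
    """Qualifying driver mutations plus decoys that must be filtered out.

    Qualifying SNVs: VAF ~ U(0.25, 0.6), depth ~ 20 + Poisson(80). Decoys
    are either low-VAF or low-depth qualifying-impact SNVs. CNVs: gains of
    5+ copies and homozygous deletions qualify; 3-4 copy events are
    copy-number changes that do not.
    """
    calls: list[MutationCall] = []
    gene_probs = {g: config.mutation_prob for g in sorted(driver_genes.genes)}
    if pathway_genes is not None:
        for g in sorted(pathway_genes.genes - driver_genes.genes):
            gene_probs[g] = config.pathway_mutation_prob
    for sample in tumor_samples:
        for gene, prob in gene_probs.items():
            if rng.random() < prob:
                calls.append(
                    MutationCall(
                        sample_id=sample, gene=gene, mclass="SNV",
                        impact=_QUAL_IMPACTS[int(rng.integers(len(_QUAL_IMPACTS)))],
                        vaf=float(rng.uniform(0.25, 0.6)),
                        depth=int(20 + rng.poisson(80.0)),
                    )
                )
            if rng.random() < config.decoy_prob:
                if rng.random() < 0.5:
                    vaf, depth = float(rng.uniform(0.02, 0.2)), int(20 + rng.poisson(80.0))
                else:
                    vaf, depth = float(rng.uniform(0.25, 0.6)), int(rng.integers(5, 21))
                calls.append(
                    MutationCall(
                        sample_id=sample, gene=gene, mclass="SNV",
                        impact=_QUAL_IMPACTS[int(rng.integers(len(_QUAL_IMPACTS)))],
                        vaf=vaf, depth=depth,
                    )
                )
            r = rng.random()
            if r < config.cnv_gain_prob:
                calls.append(MutationCall(sample_id=sample, gene=gene, mclass="CNV",
                                          copy_number=int(rng.integers(5, 9))))
            elif r < config.cnv_gain_prob + config.cnv_del_prob:
                calls.append(MutationCall(sample_id=sample, gene=gene, mclass="CNV",
                                          copy_number=0))
            elif r < (config.cnv_gain_prob + config.cnv_del_prob
                      + config.cnv_neutralish_prob):
                calls.append(MutationCall(sample_id=sample, gene=gene, mclass="CNV",
                                          copy_number=int(rng.integers(3, 5))))
    return calls


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival_times(
    config: CohortConfig,
    rng: np.random.Generator,
    burden: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> list[ClinicalRecord]:
    """Exponential survival with hazard tied to driver-splice burden.

    hazard_i = baseline_hazard * exp(log_hr_burden * burden_i); censoring
    is an independent exponential clock (none when censor_rate = 0).
    """
    records = []
    for sample in sorted(burden.index):
        b = float(burden[sample])
        if np.isnan(b):
            continue
        hazard = config.baseline_hazard * np.exp(config.log_hr_burden * b)
        t_event = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0:
            t_cens = rng.exponential(1.0 / config.censor_rate)
        else:
            t_cens = np.inf
        time = max(min(t_event, t_cens), 1e-3)
        covs = {}
        if covariates is not None and sample in covariates.index:
            covs = covariates.loc[sample].to_dict()
        records.append(
            ClinicalRecord(
                sample_id=sample,
                os_time=float(time),
                os_event=int(t_event <= t_cens),
                covariates=covs,
            )
        )
    return records


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full tumor/normal bundle for one seed."""
    root = np.random.SeedSequence(config.seed)
    rng_ann, rng_inst, rng_counts, rng_ab, rng_mut, rng_surv = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    tumor_samples = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    normal_samples = [f"N{i + 1:03d}" for i in range(config.n_normal)]

    genes, t2g, nf1_gene = _make_annotation(config, rng_ann)
    driver_set = GeneSet.of(
        "driver_census", [g.gene_id for g in genes[: config.n_driver_genes]]
    )
    pathway_set = GeneSet.of(
        "ras_pathway",
        [g.gene_id for g in
         genes[config.n_driver_genes: config.n_driver_genes + config.pathway_size]],
    )

    tumor_instability = pd.Series(
        rng_inst.uniform(0.0, 2.0, size=config.n_tumor), index=tumor_samples
    ).sort_index()

    counts, event_truth, events, events_by_gene = simulate_event_counts(
        config, rng_counts, genes, tumor_samples, normal_samples, tumor_instability
    )
    abundance, expression, entropy_truth, nf1_truth, inc_tx, exc_tx = (
        simulate_isoform_abundances(
            config, rng_ab, genes, tumor_samples, normal_samples,
            nf1_gene, pathway_set.genes,
        )
    )
    mutations = simulate_mutations(config, rng_mut, tumor_samples, driver_set,
                                   pathway_genes=pathway_set)

    # burden driving survival: fraction of driver genes whose nominal psi
    # deviation exceeds the alteration threshold in this tumor, from truth
    from .psi import psi_matrix
    from .burden import driver_splicing_burden

    psi = psi_matrix(events, counts)
    splice_burden = driver_splicing_burden(
        psi, events_by_gene, normal_samples, tumor_samples, driver_set
    ).per_sample["driver_splice_fraction"]

    ras_mutant = {}
    qualifying_by_sample: dict[str, bool] = {}
    from .types import is_qualifying

    for m in mutations:
        if m.gene in pathway_set.genes and is_qualifying(m):
            qualifying_by_sample[m.sample_id] = True
    for s in tumor_samples:
        ras_mutant[s] = int(qualifying_by_sample.get(s, False))
    covariates = pd.DataFrame(
        {
            "ras_mutant": pd.Series(ras_mutant, dtype=float),
            "nf1_expression": expression.loc[nf1_gene, tumor_samples],
            "nf1_psi": nf1_truth[tumor_samples],
        }
    )
    clinical = simulate_survival_times(config, rng_surv, splice_burden, covariates)

    return CohortBundle(
        config=config,
        tumor_samples=tumor_samples,
        normal_samples=normal_samples,
        genes=genes,
        transcript_to_gene=t2g,
        events=events,
        events_by_gene=events_by_gene,
        counts=counts,
        event_truth=event_truth,
        abundance=abundance,
        expression=expression,
        entropy_truth=entropy_truth,
        driver_set=driver_set,
        pathway_set=pathway_set,
        nf1_gene=nf1_gene,
        nf1_inclusion_transcript=inc_tx,
        nf1_exclusion_transcript=exc_tx,
        nf1_truth=nf1_truth,
        tumor_instability=tumor_instability,
        mutations=mutations,
        clinical=clinical,
    )


def write_bundle(bundle: CohortBundle, outdir) -> None:
    """Write the bundle as the pipeline's external TSV/GTF/GMT formats,
    with ground truth under ``truth/``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)

    sb_io.write_annotation(bundle.genes, outdir / "annotation.gtf")
    sb_io.write_table(bundle.counts, outdir / "event_counts.tsv")
    sb_io.write_matrix(bundle.abundance, outdir / "abundance.tsv", "transcript_id")
    sb_io.write_matrix(bundle.expression, outdir / "expression.tsv", "gene_id")
    sb_io.write_mutations(bundle.mutations, outdir / "mutations.tsv")
    sb_io.write_clinical(bundle.clinical, outdir / "clinical.tsv")
    sb_io.write_gene_sets([bundle.driver_set, bundle.pathway_set], outdir / "sets.gmt")

    events_df = pd.DataFrame(
        [
            (e.event_id, e.gene_id, e.etype, e.len_inc, e.len_skip)
            for e in bundle.events.values()
        ],
        columns=["event_id", "gene_id", "etype", "len_inc", "len_skip"],
    ).sort_values("event_id", kind="stable")
    sb_io.write_table(events_df, outdir / "events.tsv")

    groups = pd.DataFrame(
        [(s, "normal") for s in bundle.normal_samples]
        + [(s, "tumor") for s in bundle.tumor_samples],
        columns=["sample_id", "group"],
    )
    sb_io.write_table(groups, outdir / "groups.tsv")

    sb_io.write_table(bundle.event_truth, truth_dir / "event_truth.tsv")
    sb_io.write_matrix(bundle.entropy_truth, truth_dir / "entropy_truth.tsv", "gene_id")
    sb_io.write_table(
        bundle.nf1_truth.rename("nf1_psi").rename_axis("sample_id").reset_index(),
        truth_dir / "nf1_truth.tsv",
    )
    sb_io.write_table(
        bundle.tumor_instability.rename("instability").rename_axis("sample_id")
        .reset_index(),
        truth_dir / "tumor_instability.tsv",
    )
    bundle.config.to_yaml(outdir / "config.yaml")
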
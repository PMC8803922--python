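"""End-to-end cohort analysis: from a bundle of tables to burden, enrichment
and survival summaries.

The pipeline mirrors the analysis flow the package exists for: quantify psi
from junction counts, call tumor-vs-normal differential events, compute the
isoform-entropy and driver-gene burden statistics, classify pathway mutation
status, score pathway activity per sample and correlate it with the
NF1-like inclusion ratio, then stratify tumors by burden and test survival.
Every step is deterministic for a fixed bundle and seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import io as sb_io
from .burden import (
    BurdenComparison,
    BurdenTable,
    assemble_burden_table,
    classify_pathway_status,
    compare_burdens,
    driver_mutation_burden,
    driver_splicing_burden,
    entropy_burden_series,
)
from .diffsplice import count_by_type, differential_events
from .enrichment import gsea_preranked, rank_genes, ssgsea_score
from .psi import psi_matrix, transcript_ratio_psi_series
from .survival import SurvivalResult, cox_fit, quartile_stratify, survival_test
from .synthetic import CohortBundle


@dataclass
class PipelineResult:
    psi: pd.DataFrame
    diff_events: list
    diff_counts: pd.DataFrame
    entropy_burden: pd.Series
    entropy_tumor_median: float
    entropy_normal_median: float
    entropy_p: float
    burden: BurdenTable
    burden_comparison: BurdenComparison
    pathway_status: pd.Series  # tumor sample -> mutant/wild_type/indeterminate
    ras_score: pd.Series
    nf1_psi: pd.Series
    nf1_score_r: float
    nf1_score_p: float
    driver_gsea_es: float
    driver_gsea_nes: float
    strata: pd.Series  # tumor sample -> Q1..Q4 by driver splice fraction
    logrank: Optional[SurvivalResult]
    gbw: Optional[SurvivalResult]
    cox: Optional[SurvivalResult]
    notes: list[str] = field(default_factory=list)


def run_pipeline(bundle: CohortBundle, gsea_seed: int = 0,
                 n_perm: int = 1000) -> PipelineResult:
    cfg = bundle.config
    notes: list[str] = []

    report = sb_io.validate_bundle(
        abundance=bundle.abundance, mutations=bundle.mutations,
        clinical=bundle.clinical,
    )
    report.raise_on_hard()

    psi = psi_matrix(bundle.events, bundle.counts)
    etypes = {e.event_id: e.etype for e in bundle.events.values()}

    diff = differential_events(
        psi, group_a=bundle.tumor_samples, group_b=bundle.normal_samples,
        etypes=etypes,
    )
    diff_counts = count_by_type(diff)

    entropy = entropy_burden_series(bundle.abundance, bundle.transcript_to_gene)
    ent_t = entropy[bundle.tumor_samples].dropna()
    ent_n = entropy[bundle.normal_samples].dropna()
    entropy_p = float(stats.mannwhitneyu(ent_t, ent_n, alternative="two-sided").pvalue)

    splice_b = driver_splicing_burden(
        psi, bundle.events_by_gene, bundle.normal_samples, bundle.tumor_samples,
        bundle.driver_set,
    )
    mut_b = driver_mutation_burden(
        bundle.mutations, bundle.driver_set, bundle.tumor_samples
    )
    burden = assemble_burden_table(entropy, splice_b, mut_b)
    comparison = compare_burdens(burden, "per_sample")

    covered = {g.gene_id for g in bundle.genes}
    status = pd.Series(
        {
            s: classify_pathway_status(
                bundle.mutations, bundle.pathway_set, s, covered
            ).status
            for s in bundle.tumor_samples
        }
    ).sort_index()

    ras_score = ssgsea_score(bundle.expression, bundle.pathway_set)
    nf1_psi = transcript_ratio_psi_series(
        bundle.abundance, bundle.transcript_to_gene, bundle.nf1_gene,
        [bundle.nf1_inclusion_transcript], [bundle.nf1_exclusion_transcript],
    )
    joined = pd.concat(
        [nf1_psi.rename("psi"), ras_score.rename("score")], axis=1, join="inner"
    ).dropna()
    nf1_r, nf1_p = stats.pearsonr(joined["psi"], joined["score"])

    ranking = rank_genes("splicing", diff_events=diff,
                         event_genes={e: bundle.events[e].gene_id for e in etypes})
    try:
        gsea = gsea_preranked(ranking, bundle.driver_set, n_perm=n_perm,
                              seed=gsea_seed)
        gsea_es, gsea_nes = gsea.es, gsea.nes
    except ValueError as exc:
        notes.append(f"driver-set GSEA skipped: {exc}")
        gsea_es, gsea_nes = float("nan"), float("nan")

    splice_frac = burden.per_sample["driver_splice_fraction"].loc[
        lambda s: s.index.isin(bundle.tumor_samples)
    ]
    strata = pd.Series(
        {a.sample_id: a.stratum for a in quartile_stratify(splice_frac)}
    ).sort_index()
    clin = {r.sample_id: r for r in bundle.clinical}
    q1 = [clin[s] for s in strata.index[strata == "Q1"] if s in clin]
    q4 = [clin[s] for s in strata.index[strata == "Q4"] if s in clin]

    logrank = gbw = cox = None
    if q1 and q4:
        logrank = survival_test(q4, q1, weighting="logrank")
        gbw = survival_test(q4, q1, weighting="gehan_breslow_wilcoxon")
        cox_records = []
        for r in q1 + q4:
            covs = {
                "q4_burden": 1.0 if strata[r.sample_id] == "Q4" else 0.0,
                "ras_mutant": float(r.covariates.get("ras_mutant", 0.0)),
                "log_nf1_expression": float(
                    np.log(max(r.covariates.get("nf1_expression", 1.0), 1e-6))
                ),
            }
            cox_records.append(
                type(r)(r.sample_id, r.os_time, r.os_event, covs)
            )
        try:
            cox = cox_fit(
                cox_records, ["q4_burden", "ras_mutant", "log_nf1_expression"]
            )
        except (ValueError, RuntimeError) as exc:
            notes.append(f"Cox fit skipped: {exc}")

    return PipelineResult(
        psi=psi,
        diff_events=diff,
        diff_counts=diff_counts,
        entropy_burden=entropy,
        entropy_tumor_median=float(ent_t.median()),
        entropy_normal_median=float(ent_n.median()),
        entropy_p=entropy_p,
        burden=burden,
        burden_comparison=comparison,
        pathway_status=status,
        ras_score=ras_score,
        nf1_psi=nf1_psi,
        nf1_score_r=float(nf1_r),
        nf1_score_p=float(nf1_p),
        driver_gsea_es=float(gsea_es),
        driver_gsea_nes=float(gsea_nes),
        strata=strata,
        logrank=logrank,
        gbw=gbw,
        cox=cox,
        notes=notes,
    )


def write_results(result: PipelineResult, outdir) -> None:
    """Serialize the pipeline outputs as TSV/JSON; byte-stable for a fixed
    bundle and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sb_io.write_matrix(result.psi, outdir / "psi.tsv", "event_id")
    diff_df = pd.DataFrame(
        [
            (d.event_id, d.etype, d.delta_psi, d.p_value, d.q_value,
             d.direction, d.significant)
            for d in result.diff_events
        ],
        columns=["event_id", "etype", "delta_psi", "p_value", "q_value",
                 "direction", "significant"],
    )
    sb_io.write_table(diff_df, outdir / "differential_events.tsv")
    result.diff_counts.to_csv(outdir / "diff_counts.tsv", sep="\t")
    sb_io.write_matrix(result.burden.per_sample, outdir / "burden_per_sample.tsv",
                       "sample_id")
    sb_io.write_matrix(result.burden.per_gene, outdir / "burden_per_gene.tsv", "gene")
    sb_io.write_table(
        pd.DataFrame({"sample_id": result.ras_score.index,
                      "ras_score": result.ras_score.to_numpy(),
                      "nf1_psi": result.nf1_psi[result.ras_score.index].to_numpy()}),
        outdir / "pathway_scores.tsv",
    )

    summary = {
        "n_differential_significant": int(sum(d.significant for d in result.diff_events)),
        "entropy_tumor_median": result.entropy_tumor_median,
        "entropy_normal_median": result.entropy_normal_median,
        "entropy_p": result.entropy_p,
        "burden_t_statistic": result.burden_comparison.statistic,
        "burden_p": result.burden_comparison.p_value,
        "mean_driver_splice_fraction": result.burden_comparison.mean_splicing,
        "mean_driver_mutation_fraction": result.burden_comparison.mean_mutation,
        "pathway_mutant_count": int((result.pathway_status == "mutant").sum()),
        "nf1_score_r": result.nf1_score_r,
        "nf1_score_p": result.nf1_score_p,
        "driver_gsea_es": result.driver_gsea_es,
        "driver_gsea_nes": result.driver_gsea_nes,
        "logrank_p": None if result.logrank is None else result.logrank.p_value,
        "gbw_p": None if result.gbw is None else result.gbw.p_value,
        "cox_hr_q4": (
            None if result.cox is None
            else next(c.hazard_ratio for c in result.cox.covariates
                      if c.name == "q4_burden")
        ),
        "notes": result.notes,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
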
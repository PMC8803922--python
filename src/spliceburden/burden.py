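"""Splicing- and mutation-burden statistics.

Two complementary per-sample burden measures:

* **isoform-entropy burden** — the median, over multi-isoform genes, of the
  Shannon entropy H = -sum_i P_i ln P_i of the gene's transcript-ratio
  distribution (P_i = isoform i's share of gene abundance). Natural log;
  0 * ln 0 := 0, so 0 <= H <= ln(g) for g isoforms.
* **driver alteration fractions** — the fraction of cancer-census driver
  genes altered per sample, by splicing (any event of the gene deviating
  more than 30 percentage points of psi from its normal-tissue reference)
  or by mutation (a qualifying SNV/indel or copy-number alteration).

Pathway-level mutant/wild-type classification uses the same qualifying-call
criteria; wild-type additionally requires every pathway gene to be covered
and free of any alteration record.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSet, MutationCall, PathwayStatus, is_qualifying

DEFAULT_MIN_GENE_ABUNDANCE = 1.0
DEFAULT_CHANGE_THRESHOLD = 0.30


@dataclass(frozen=True)
class EntropyRecord:
    gene_id: str
    sample_id: str
    H: float  # nats
    g: int  # isoforms considered


@dataclass
class BurdenTable:
    """Per-sample and per-gene burden summaries.

    ``per_sample`` columns: median_entropy, driver_splice_fraction,
    driver_mutation_fraction (NaN where undefined). ``per_gene`` columns:
    altered_sample_fraction (splicing), mutated_sample_fraction.
    """

    per_sample: pd.DataFrame
    per_gene: pd.DataFrame


def gene_entropy(
    abundance: pd.DataFrame,
    transcript_to_gene: Mapping[str, str],
    gene: str,
    sample: str,
    min_gene_abundance: float = DEFAULT_MIN_GENE_ABUNDANCE,
) -> Optional[EntropyRecord]:
    """Shannon entropy (nats) of one gene's isoform-ratio distribution.

    Returns None when total gene abundance is below ``min_gene_abundance``
    (ratio estimates unusable at negligible expression).
    """
    tids = sorted(t for t, g in transcript_to_gene.items() if g == gene)
    if not tids:
        raise KeyError(f"unknown gene {gene!r}")
    vec = abundance.loc[tids, sample].to_numpy(dtype=float)
    return _entropy_from_abundances(vec, gene, sample, min_gene_abundance)


def _entropy_from_abundances(
    vec: np.ndarray, gene: str, sample: str, min_gene_abundance: float
) -> Optional[EntropyRecord]:
    if np.any(vec < 0):
        raise ValueError(f"negative abundance for gene {gene!r}")
    total = float(vec.sum())
    if total < min_gene_abundance:
        return None
    p = vec / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return EntropyRecord(gene, sample, h, len(vec))


def sample_splicing_burden(
    abundance: pd.DataFrame,
    transcript_to_gene: Mapping[str, str],
    sample: str,
    min_gene_abundance: float = DEFAULT_MIN_GENE_ABUNDANCE,
) -> Optional[float]:
    """Median entropy over multi-isoform genes for one sample.

    Genes with a single annotated transcript are excluded by construction;
    genes below the abundance floor contribute nothing. Returns None when
    no gene qualifies.
    """
    groups: dict[str, list[str]] = {}
    for tid, gid in transcript_to_gene.items():
        groups.setdefault(gid, []).append(tid)
    hs = []
    col = abundance[sample]
    for gid, tids in groups.items():
        if len(tids) < 2:
            continue
        vec = col.loc[sorted(tids)].to_numpy(dtype=float)
        rec = _entropy_from_abundances(vec, gid, sample, min_gene_abundance)
        if rec is not None:
            hs.append(rec.H)
    if not hs:
        return None
    return float(np.median(hs))


def entropy_burden_series(
    abundance: pd.DataFrame,
    transcript_to_gene: Mapping[str, str],
    min_gene_abundance: float = DEFAULT_MIN_GENE_ABUNDANCE,
) -> pd.Series:
    """Per-sample median multi-isoform entropy, over all samples."""
    vals = {
        s: sample_splicing_burden(abundance, transcript_to_gene, s, min_gene_abundance)
        for s in abundance.columns
    }
    return pd.Series(
        {s: (np.nan if v is None else v) for s, v in vals.items()}, dtype=float
    ).sort_index()


def driver_splicing_burden(
    psi: pd.DataFrame,
    events_by_gene: Mapping[str, Sequence[str]],
    normal_samples: Iterable[str],
    tumor_samples: Iterable[str],
    driver_genes: GeneSet,
    change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
    reference: str = "mean",
) -> BurdenTable:
    """Driver-gene splicing-alteration fractions.

    Per event, the normal-tissue reference is the mean (or median) psi over
    normal samples with defined psi. A (tumor sample, gene) pair is altered
    iff the maximum over the gene's events of |psi - reference| exceeds
    ``change_threshold``. Per-sample fraction: altered genes / driver genes
    usable in that sample; per-gene fraction: altered samples / tumor
    samples with usable psi for that gene. Driver genes without any usable
    event are excluded from denominators.
    """
    if reference not in ("mean", "median"):
        raise ValueError("reference must be 'mean' or 'median'")
    normals = sorted(set(map(str, normal_samples)))
    tumors = sorted(set(map(str, tumor_samples)))
    if set(normals) & set(tumors):
        raise ValueError("normal and tumor sample sets overlap")

    agg = np.nanmean if reference == "mean" else np.nanmedian
    norm_mat = psi.loc[:, normals]

    # per-event reference, defined only where >=1 normal sample has psi
    with np.errstate(invalid="ignore"):
        ref = pd.Series(agg(norm_mat.to_numpy(dtype=float), axis=1), index=psi.index)

    genes = sorted(driver_genes.genes)
    altered = pd.DataFrame(np.nan, index=tumors, columns=genes)
    for gene in genes:
        event_ids = [e for e in events_by_gene.get(gene, []) if e in psi.index]
        usable = [e for e in event_ids if not np.isnan(ref.loc[e])]
        if not usable:
            continue
        sub = psi.loc[usable, tumors].to_numpy(dtype=float)
        dev = np.abs(sub - ref.loc[usable].to_numpy(dtype=float)[:, None])
        any_defined = (~np.isnan(dev)).any(axis=0)
        with np.errstate(invalid="ignore"):
            max_dev = np.nanmax(np.where(np.isnan(dev), -np.inf, dev), axis=0)
        col = np.where(any_defined, (max_dev > change_threshold).astype(float), np.nan)
        altered[gene] = pd.Series(col, index=tumors)

    per_sample = altered.mean(axis=1, skipna=True).rename("driver_splice_fraction")
    per_gene = altered.mean(axis=0, skipna=True).rename("altered_sample_fraction")
    return BurdenTable(
        per_sample=per_sample.to_frame(),
        per_gene=per_gene.to_frame(),
    )


def classify_pathway_status(
    mutations: Iterable[MutationCall],
    gene_set: GeneSet,
    sample: str,
    covered_genes: Iterable[str],
) -> PathwayStatus:
    """Mutant / wild-type / indeterminate call for one sample and gene set.

    Mutant: any qualifying alteration in a set gene. Wild-type: every set
    gene is covered by the assay and carries no alteration record at all
    (sub-threshold calls and any copy-number change disqualify wild-type
    without making the sample mutant). Otherwise indeterminate.
    """
    covered = set(covered_genes)
    calls = [m for m in mutations if m.sample_id == sample and m.gene in gene_set.genes]
    if any(is_qualifying(m) for m in calls):
        return PathwayStatus(sample, gene_set.name, "mutant")
    if gene_set.genes <= covered and not calls:
        return PathwayStatus(sample, gene_set.name, "wild_type")
    return PathwayStatus(sample, gene_set.name, "indeterminate")


def driver_mutation_burden(
    mutations: Iterable[MutationCall],
    driver_genes: GeneSet,
    samples: Iterable[str],
) -> BurdenTable:
    """Fraction of driver genes with a qualifying alteration, per sample,
    and of samples altered, per gene."""
    samples = sorted(set(map(str, samples)))
    genes = sorted(driver_genes.genes)
    hit = pd.DataFrame(False, index=samples, columns=genes)
    for m in mutations:
        if m.sample_id in hit.index and m.gene in hit.columns and is_qualifying(m):
            hit.loc[m.sample_id, m.gene] = True
    per_sample = hit.mean(axis=1).rename("driver_mutation_fraction")
    per_gene = hit.mean(axis=0).rename("mutated_sample_fraction")
    return BurdenTable(per_sample=per_sample.to_frame(), per_gene=per_gene.to_frame())


def assemble_burden_table(
    entropy: Optional[pd.Series] = None,
    splicing: Optional[BurdenTable] = None,
    mutation: Optional[BurdenTable] = None,
) -> BurdenTable:
    """Join entropy, splicing and mutation fragments into one table."""
    sample_parts = []
    if entropy is not None:
        sample_parts.append(entropy.rename("median_entropy"))
    if splicing is not None:
        sample_parts.append(splicing.per_sample["driver_splice_fraction"])
    if mutation is not None:
        sample_parts.append(mutation.per_sample["driver_mutation_fraction"])
    gene_parts = []
    if splicing is not None:
        gene_parts.append(splicing.per_gene["altered_sample_fraction"])
    if mutation is not None:
        gene_parts.append(mutation.per_gene["mutated_sample_fraction"])
    per_sample = pd.concat(sample_parts, axis=1) if sample_parts else pd.DataFrame()
    per_gene = pd.concat(gene_parts, axis=1) if gene_parts else pd.DataFrame()
    return BurdenTable(per_sample=per_sample.sort_index(), per_gene=per_gene.sort_index())


@dataclass(frozen=True)
class BurdenComparison:
    view: str  # per_sample | per_gene
    statistic: float
    p_value: float
    mean_splicing: float
    mean_mutation: float
    n_splicing: int
    n_mutation: int


def compare_burdens(burden: BurdenTable, grouping: str = "per_sample") -> BurdenComparison:
    """Welch two-sided t-test of splicing vs mutation alteration fractions."""
    if grouping == "per_sample":
        frame = burden.per_sample
        a = frame["driver_splice_fraction"].dropna().to_numpy(dtype=float)
        b = frame["driver_mutation_fraction"].dropna().to_numpy(dtype=float)
    elif grouping == "per_gene":
        frame = burden.per_gene
        a = frame["altered_sample_fraction"].dropna().to_numpy(dtype=float)
        b = frame["mutated_sample_fraction"].dropna().to_numpy(dtype=float)
    else:
        raise ValueError("grouping must be 'per_sample' or 'per_gene'")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >=3 observations per arm")
    if np.array_equal(a, b):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    return BurdenComparison(
        view=grouping,
        statistic=float(stat),
        p_value=float(p),
        mean_splicing=float(a.mean()),
        mean_mutation=float(b.mean()),
        n_splicing=len(a),
        n_mutation=len(b),
    )


def compare_burdens_across(
    cohorts: Mapping[str, BurdenTable], grouping: str = "per_sample"
) -> pd.DataFrame:
    """compare_burdens over several cohorts with BH correction across them."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for name in sorted(cohorts):
        c = compare_burdens(cohorts[name], grouping)
        rows.append((name, c.statistic, c.p_value, c.mean_splicing, c.mean_mutation))
    df = pd.DataFrame(
        rows, columns=["cohort", "statistic", "p_value", "mean_splicing", "mean_mutation"]
    )
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
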
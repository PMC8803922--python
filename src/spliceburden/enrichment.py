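"""Pre-ranked GSEA, single-sample enrichment (ssGSEA), and correlation links.

The pre-ranked enrichment score is the classic weighted Kolmogorov-Smirnov
running-sum statistic: walking down the ranking, set members ("hits") add
|score|^w normalized by the total hit weight, non-members subtract a uniform
increment; ES is the signed extreme deviation. Significance comes from a
seeded gene-label permutation null; NES divides ES by the mean |null ES| of
matching sign.

ssGSEA follows the rank-weighted ECDF-difference construction: within one
sample, genes are ordered by expression and the difference between the
weighted in-set ECDF and the uniform out-of-set ECDF is accumulated over the
whole ranking.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffsplice import DifferentialEvent
from .types import GeneSet

DEFAULT_GSEA_WEIGHT = 1.0
DEFAULT_N_PERM = 1000
DEFAULT_SET_SIZE_BOUNDS = (5, 500)
DEFAULT_SSGSEA_WEIGHT = 0.75
DEFAULT_MIN_MEAN_EXPRESSION = 1.0

_TINY = np.finfo(float).tiny  # clamp for adjusted p = 0


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    fdr: float
    n_hits: int


def rank_genes(
    mode: str,
    de_table: Optional[pd.DataFrame] = None,
    diff_events: Optional[Sequence[DifferentialEvent]] = None,
    event_genes: Optional[Mapping[str, str]] = None,
) -> pd.Series:
    """Gene ranking scores for pre-ranked GSEA.

    ``mode="expression"``: score = sign(fold change) * -log10(adjusted p),
    from a DE table with columns gene, log2fc, padj.
    ``mode="splicing"``: score = -log10 of the gene's minimum adjusted p
    over its events; needs ``diff_events`` plus ``event_genes`` mapping
    event_id -> gene. Returns a Series sorted by descending score, ties
    broken by gene identifier.
    """
    if mode == "expression":
        if de_table is None:
            raise ValueError("expression mode needs a DE table")
        padj = de_table["padj"].to_numpy(dtype=float).clip(min=_TINY)
        score = np.sign(de_table["log2fc"].to_numpy(dtype=float)) * (-np.log10(padj))
        ser = pd.Series(score, index=de_table["gene"].astype(str).to_numpy())
    elif mode == "splicing":
        if diff_events is None or event_genes is None:
            raise ValueError("splicing mode needs diff_events and event_genes")
        best: dict[str, float] = {}
        for ev in diff_events:
            gene = event_genes[ev.event_id]
            q = max(ev.q_value, _TINY)
            best[gene] = min(best.get(gene, math.inf), q)
        ser = pd.Series({g: -math.log10(q) for g, q in best.items()}, dtype=float)
    else:
        raise ValueError("mode must be 'expression' or 'splicing'")
    if ser.index.duplicated().any():
        raise ValueError("duplicate genes in ranking input")
    order = sorted(ser.index, key=lambda g: (-ser[g], g))
    return ser.loc[order]


def _running_es(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """Signed extreme deviation of the weighted KS running sum."""
    n = len(scores)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the ranking")
    hit_w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, hit_w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:  # all hit scores are exactly 0: fall back to uniform hits
        hit_w = hit_mask.astype(float)
        total_hit = hit_w.sum()
    inc = hit_w / total_hit
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(inc - dec)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx])


def gsea_preranked(
    ranking: pd.Series,
    gene_set: GeneSet,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight: float = DEFAULT_GSEA_WEIGHT,
    set_size_bounds: tuple[int, int] = DEFAULT_SET_SIZE_BOUNDS,
    enforce_size_bounds: bool = False,
) -> EnrichmentResult:
    """Weighted-KS pre-ranked enrichment for one gene set.

    ``ranking`` must be a gene -> score Series already ordered by descending
    score (as from :func:`rank_genes`). The permutation null shuffles gene
    labels with a seeded generator, so results are reproducible bit-for-bit
    for a fixed seed. NES = ES / mean |null ES| of the same sign; the
    single-set FDR equals the permutation p (BH across sets is applied by
    :func:`gsea_preranked_collection`).
    """
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    hit_mask = np.isin(genes, sorted(gene_set.genes))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranking")
    if n_hits == len(genes):
        raise ValueError(f"gene set {gene_set.name!r} covers the entire ranking")
    if enforce_size_bounds and not (set_size_bounds[0] <= n_hits <= set_size_bounds[1]):
        raise ValueError(
            f"gene set {gene_set.name!r}: {n_hits} hits outside bounds {set_size_bounds}"
        )

    es = _running_es(scores, hit_mask, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    positions = np.arange(len(genes))
    for i in range(n_perm):
        perm_hits = np.zeros(len(genes), dtype=bool)
        perm_hits[rng.choice(positions, size=n_hits, replace=False)] = True
        null[i] = _running_es(scores, perm_hits, weight)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        nes = math.nan
        p = 1.0 / (n_perm + 1)
    else:
        mean_abs = np.abs(same_sign).mean()
        nes = es / mean_abs if mean_abs > 0 else math.nan
        p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
    return EnrichmentResult(
        gene_set=gene_set.name, es=es, nes=float(nes), p_value=float(p),
        fdr=float(p), n_hits=n_hits,
    )


def gsea_preranked_collection(
    ranking: pd.Series,
    gene_sets: Sequence[GeneSet],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight: float = DEFAULT_GSEA_WEIGHT,
    set_size_bounds: tuple[int, int] = DEFAULT_SET_SIZE_BOUNDS,
) -> pd.DataFrame:
    """Run :func:`gsea_preranked` per set and BH-correct across sets.

    Sets outside the size bounds (after intersection with the ranking) are
    skipped. Each set gets an independent child seed derived from ``seed``.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(gene_sets))
    lo, hi = set_size_bounds
    for gs, child in zip(gene_sets, child_seeds):
        n_hits = len(gene_set_hits(ranking, gs))
        if not (lo <= n_hits <= hi):
            continue
        res = gsea_preranked(ranking, gs, n_perm=n_perm, seed=int(child) % (2**31),
                             weight=weight)
        rows.append((res.gene_set, res.es, res.nes, res.p_value, res.n_hits))
    df = pd.DataFrame(rows, columns=["gene_set", "es", "nes", "p_value", "n_hits"])
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df


def gene_set_hits(ranking: pd.Series, gene_set: GeneSet) -> list[str]:
    return sorted(set(ranking.index) & gene_set.genes)


def ssgsea_score(
    expression: pd.DataFrame,
    gene_set: GeneSet,
    min_mean_expression: float = DEFAULT_MIN_MEAN_EXPRESSION,
    weight: float = DEFAULT_SSGSEA_WEIGHT,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample single-sample enrichment score for one gene set.

    Genes whose mean expression across samples is below
    ``min_mean_expression`` are discarded first. Within each sample, genes
    are ranked by expression (descending; ties broken by gene identifier for
    determinism) and rank-based weights r^w (r = number of genes for the top
    gene, 1 for the bottom) drive the in-set ECDF. The score is the sum of
    (weighted in-set ECDF - uniform out-of-set ECDF) over the ranking. With
    ``normalize`` the scores are divided by the score range across samples.
    """
    means = expression.mean(axis=1)
    kept = expression.loc[means >= min_mean_expression]
    genes = pd.Index(kept.index.astype(str))
    in_set = genes.isin(sorted(gene_set.genes)).astype(bool)
    n = len(genes)
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} vanished after the expression filter"
        )
    if n_hits == n:
        raise ValueError(f"gene set {gene_set.name!r} covers all retained genes")

    scores = {}
    gene_order_key = np.argsort(genes.to_numpy())  # tie-break by identifier
    for sample in kept.columns:
        vals = kept[sample].to_numpy(dtype=float)
        # stable sort on (-value, gene id): sort by id first, then by -value
        order = gene_order_key[np.argsort(-vals[gene_order_key], kind="stable")]
        hits = in_set[order]
        ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets weight n^w
        w = ranks**weight
        hit_w = np.where(hits, w, 0.0)
        ecdf_in = np.cumsum(hit_w) / hit_w.sum()
        ecdf_out = np.cumsum(np.where(hits, 0.0, 1.0)) / (n - n_hits)
        scores[str(sample)] = float(np.sum(ecdf_in - ecdf_out))
    ser = pd.Series(scores, dtype=float).sort_index()
    if normalize and len(ser) > 1:
        rng_ = ser.max() - ser.min()
        if rng_ > 0:
            ser = ser / rng_
    return ser


def correlate_with_adjustment(
    x: Mapping[str, pd.Series] | pd.DataFrame,
    y: Mapping[str, pd.Series] | pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Pearson correlation per (x, y) pair with BH across the family.

    Missing values are dropped pairwise; each pair needs >=3 complete
    observations. Returns columns pair_x, pair_y, n, r, p_value, q_value.
    """
    def get(container, key) -> pd.Series:
        if isinstance(container, pd.DataFrame):
            return container.loc[key] if key in container.index else container[key]
        return container[key]

    rows = []
    for kx, ky in pairs:
        sx, sy = get(x, kx), get(y, ky)
        joined = pd.concat([sx.rename("x"), sy.rename("y")], axis=1, join="inner").dropna()
        if len(joined) < 3:
            raise ValueError(f"pair ({kx}, {ky}): fewer than 3 complete observations")
        r, p = stats.pearsonr(joined["x"], joined["y"])
        rows.append((kx, ky, len(joined), float(r), float(p)))
    df = pd.DataFrame(rows, columns=["pair_x", "pair_y", "n", "r", "p_value"])
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def correlated_target_proportion(
    target_psi: pd.DataFrame,
    regulator_psi: pd.DataFrame,
    alpha: float = 0.05,
    include_all_mode: bool = True,
) -> pd.Series:
    """Per-regulator fraction of targets whose psi correlates (BH q < alpha).

    ``target_psi``: targets x samples; ``regulator_psi``: regulators x
    samples. BH runs within each regulator's family of targets. The "All"
    entry correlates targets against the maximally variant regulator (the
    row of ``regulator_psi`` with the largest across-sample variance).
    """
    regs = list(map(str, regulator_psi.index))
    frames = {}
    for reg in regs:
        frames[reg] = regulator_psi.loc[reg]
    if include_all_mode and len(regs) > 1:
        variances = regulator_psi.var(axis=1, ddof=1)
        frames["All"] = regulator_psi.loc[variances.idxmax()]

    out = {}
    targets = list(map(str, target_psi.index))
    for name, reg_series in frames.items():
        pvals = []
        for t in targets:
            joined = pd.concat(
                [target_psi.loc[t].rename("x"), reg_series.rename("y")],
                axis=1, join="inner",
            ).dropna()
            if len(joined) < 3 or joined["x"].nunique() < 2 or joined["y"].nunique() < 2:
                pvals.append(1.0)
                continue
            _, p = stats.pearsonr(joined["x"], joined["y"])
            pvals.append(float(p))
        q = multipletests(pvals, method="fdr_bh")[1]
        out[name] = float(np.mean(q < alpha))
    return pd.Series(out, dtype=float)
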
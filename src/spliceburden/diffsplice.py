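"""Differential splicing between two sample groups, and psi variability.

An event is called significant when |delta psi| exceeds the inclusion-change
threshold (default 0.15) AND its Benjamini-Hochberg q-value is below the FDR
threshold (default 0.05). The per-event test is a two-sided Wilcoxon
rank-sum on per-sample psi: exact enumeration for small tie-free groups,
normal approximation with continuity correction otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSI_THRESHOLD = 0.15
DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_MIN_DEFINED_FRAC = 0.5
_EXACT_MAX_N = 10  # exact rank-sum null below this per-group size (no ties)


@dataclass(frozen=True)
class DifferentialEvent:
    event_id: str
    etype: str
    delta_psi: float  # mean(group A) - mean(group B)
    p_value: float
    q_value: float
    direction: str  # included | skipped | none
    significant: bool


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if not has_ties and len(a) < _EXACT_MAX_N and len(b) < _EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def differential_events(
    psi: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    etypes: Optional[Mapping[str, str]] = None,
    psi_threshold: float = DEFAULT_PSI_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_defined_frac: float = DEFAULT_MIN_DEFINED_FRAC,
) -> list[DifferentialEvent]:
    """Call events differentially spliced between group A and group B.

    Events with a defined-psi fraction below ``min_defined_frac``, or fewer
    than 3 defined values, in either group are dropped before testing; BH
    correction runs across all tested events. ``etypes`` optionally maps
    event_id -> event type for reporting (defaults to "NA").
    """
    ga = sorted(set(map(str, group_a)))
    gb = sorted(set(map(str, group_b)))
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    missing = (set(ga) | set(gb)) - set(map(str, psi.columns))
    if missing:
        raise ValueError(f"samples absent from psi matrix: {sorted(missing)[:5]}")

    mat_a = psi.loc[:, ga].to_numpy(dtype=float)
    mat_b = psi.loc[:, gb].to_numpy(dtype=float)

    tested_ids: list[str] = []
    deltas: list[float] = []
    pvals: list[float] = []
    for i, event_id in enumerate(psi.index):
        a = mat_a[i][~np.isnan(mat_a[i])]
        b = mat_b[i][~np.isnan(mat_b[i])]
        if len(a) < max(3, min_defined_frac * len(ga)):
            continue
        if len(b) < max(3, min_defined_frac * len(gb)):
            continue
        tested_ids.append(str(event_id))
        deltas.append(float(a.mean() - b.mean()))
        if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
            pvals.append(1.0)
        else:
            pvals.append(_rank_sum_p(a, b))

    if not tested_ids:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]

    out = []
    for event_id, dpsi, p, q in zip(tested_ids, deltas, pvals, qvals):
        significant = abs(dpsi) > psi_threshold and q < fdr_threshold
        if significant:
            direction = "included" if dpsi > 0 else "skipped"
        else:
            direction = "none"
        out.append(
            DifferentialEvent(
                event_id=event_id,
                etype=(etypes or {}).get(event_id, "NA"),
                delta_psi=dpsi,
                p_value=float(p),
                q_value=float(q),
                direction=direction,
                significant=significant,
            )
        )
    return out


def count_by_type(events: Sequence[DifferentialEvent]) -> pd.DataFrame:
    """Significant-event counts as a type x direction table.

    Rows are event types observed among significant events; columns are
    "included" / "skipped". Non-significant events are excluded.
    """
    table = pd.DataFrame(
        0, index=pd.Index([], name="etype", dtype=object),
        columns=["included", "skipped"], dtype=int,
    )
    for ev in events:
        if not ev.significant:
            continue
        if ev.etype not in table.index:
            table.loc[ev.etype] = 0
        table.loc[ev.etype, ev.direction] += 1
    return table.sort_index()


def variability_cdf(
    psi: pd.DataFrame, samples: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Empirical CDF of per-event psi standard deviation across samples.

    Events with fewer than 2 defined psi values are excluded. Returns a
    two-column frame (sd, cumulative_fraction); the CDF is non-decreasing
    and reaches 1 at the largest sd.
    """
    sub = psi if samples is None else psi.loc[:, sorted(set(map(str, samples)))]
    vals = sub.to_numpy(dtype=float)
    defined = (~np.isnan(vals)).sum(axis=1)
    sds = np.nanstd(vals[defined >= 2], axis=1, ddof=1)
    if sds.size == 0:
        raise ValueError("no event has >=2 defined psi values")
    sds = np.sort(sds)
    frac = np.arange(1, sds.size + 1) / sds.size
    return pd.DataFrame({"sd": sds, "cumulative_fraction": frac})
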
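"""Quartile stratification and survival testing.

Samples are split at the empirical 25/50/75 percentiles (linear
interpolation between order statistics) of a continuous measure; the
Q4-vs-Q1 design compares the top and bottom quartiles by Kaplan-Meier /
weighted log-rank (uniform weights, or number-at-risk weights for the
Gehan-Breslow-Wilcoxon variant) and by Cox proportional hazards (Efron
handling of tied event times). Estimation is delegated to lifelines.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .types import ClinicalRecord

STRATA = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class StratumAssignment:
    sample_id: str
    value: float
    stratum: str


@dataclass
class CovariateEffect:
    name: str
    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class SurvivalResult:
    test: str
    statistic: float
    p_value: float
    covariates: list[CovariateEffect] = field(default_factory=list)


def quartile_stratify(values: pd.Series) -> list[StratumAssignment]:
    """Assign samples to empirical quartiles Q1 (bottom) .. Q4 (top).

    Samples are ordered by (value, sample_id) and split at the empirical
    quartile ranks, so |Q1| and |Q4| differ by at most 1 and equal values
    straddling a boundary are resolved deterministically by sample
    identifier. Requires >=8 defined values and a non-degenerate
    distribution. For tie-free values this coincides with thresholding at
    the interpolated 25/50/75 percentiles.
    """
    vals = values.dropna().astype(float)
    n = len(vals)
    if n < 8:
        raise ValueError(f"need >=8 samples with defined values, got {n}")
    if vals.nunique() == 1:
        raise ValueError("degenerate stratification: all values identical")
    ordered = sorted(vals.items(), key=lambda kv: (kv[1], str(kv[0])))
    out = []
    for rank, (sample_id, v) in enumerate(ordered):
        stratum = STRATA[min(4 * rank // n, 3)]
        out.append(StratumAssignment(str(sample_id), float(v), stratum))
    return out


def _records_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    rows = [
        {"sample_id": r.sample_id, "os_time": r.os_time, "os_event": r.os_event,
         **r.covariates}
        for r in records
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def km_estimate(records: Iterable[ClinicalRecord], label: str = "KM") -> pd.DataFrame:
    """Kaplan-Meier survival curve (right-censored), via lifelines."""
    df = _records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["os_time"], event_observed=df["os_event"], label=label)
    out = kmf.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    return out


def survival_test(
    group_a: Sequence[ClinicalRecord],
    group_b: Sequence[ClinicalRecord],
    weighting: str = "logrank",
) -> SurvivalResult:
    """Two-group weighted log-rank test.

    ``weighting="logrank"`` uses uniform weights; ``"gehan_breslow_wilcoxon"``
    weights each event time by the number at risk, up-weighting early
    differences. Two-sided p from chi-square with 1 df. A group with zero
    observed events triggers a warning but the statistic is still computed.
    """
    if weighting not in ("logrank", "gehan_breslow_wilcoxon"):
        raise ValueError("weighting must be 'logrank' or 'gehan_breslow_wilcoxon'")
    da, db = _records_frame(group_a), _records_frame(group_b)
    if len(da) == 0 or len(db) == 0:
        raise ValueError("both groups must be non-empty")
    for name, d in (("A", da), ("B", db)):
        if d["os_event"].sum() == 0:
            warnings.warn(f"group {name} has zero observed events", stacklevel=2)
    res = logrank_test(
        da["os_time"], db["os_time"],
        event_observed_A=da["os_event"], event_observed_B=db["os_event"],
        weightings=None if weighting == "logrank" else "wilcoxon",
    )
    return SurvivalResult(
        test=weighting,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def cox_fit(
    records: Sequence[ClinicalRecord],
    covariates: Sequence[str],
    events_per_covariate: int = 5,
) -> SurvivalResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Reports per-covariate hazard ratios with 95% Wald intervals and
    p-values. Guards: no covariate may be constant, and the number of
    observed events must be at least ``events_per_covariate`` times the
    number of covariates.
    """
    df = _records_frame(records)
    missing = set(covariates) - set(df.columns)
    if missing:
        raise ValueError(f"unknown covariates: {sorted(missing)}")
    sub = df[["os_time", "os_event", *covariates]].dropna()
    n_events = int(sub["os_event"].sum())
    if n_events < events_per_covariate * len(covariates):
        raise ValueError(
            f"{n_events} events for {len(covariates)} covariates: below the "
            f"{events_per_covariate} events-per-covariate guard"
        )
    for c in covariates:
        if sub[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col="os_time", event_col="os_event")
    except Exception as exc:  # lifelines raises ConvergenceError on separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    effects = [
        CovariateEffect(
            name=str(name),
            coef=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(np.exp(row["coef lower 95%"])),
            ci_high=float(np.exp(row["coef upper 95%"])),
            p_value=float(row["p"]),
        )
        for name, row in summary.iterrows()
    ]
    return SurvivalResult(
        test="cox_ph",
        statistic=float(cph.log_likelihood_),
        p_value=float(min(e.p_value for e in effects)),
        covariates=effects,
    )
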
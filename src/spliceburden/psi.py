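"""Percent-spliced-in (psi) estimation.

Two routes to the same quantity:

* junction route — from inclusion/skipping read counts with effective-length
  normalization: ``psi = (I/len_inc) / (I/len_inc + S/len_skip)``;
* transcript route — from the ratio of inclusion-isoform to total isoform
  abundance for a designated transcript split (the NF1-I / NF1-II style
  isoform-ratio readout).

On noise-free data from a two-isoform gene differing by a single cassette
exon the two routes agree exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import SpliceEvent

DEFAULT_COVERAGE_FLOOR = 10


@dataclass(frozen=True)
class PsiValue:
    event_id: str
    sample_id: str
    psi: Optional[float]  # None when total support below the coverage floor
    total_support: int


def compute_psi(
    event: SpliceEvent,
    inc_count: int,
    skip_count: int,
    coverage_floor: int = DEFAULT_COVERAGE_FLOOR,
    sample_id: str = "",
) -> PsiValue:
    """Length-normalized junction-count psi for one event in one sample.

    psi is undefined (None) when inclusion + skipping support falls below
    ``coverage_floor``; this distinguishes "no inclusion" (psi = 0) from
    "insufficient coverage".
    """
    if inc_count < 0 or skip_count < 0:
        raise ValueError("junction counts must be non-negative")
    total = inc_count + skip_count
    if total < coverage_floor or total == 0:
        return PsiValue(event.event_id, sample_id, None, total)
    inc_norm = inc_count / event.len_inc
    skip_norm = skip_count / event.len_skip
    return PsiValue(event.event_id, sample_id, inc_norm / (inc_norm + skip_norm), total)


def psi_matrix(
    events: Mapping[str, SpliceEvent] | Iterable[SpliceEvent],
    counts: pd.DataFrame,
    coverage_floor: int = DEFAULT_COVERAGE_FLOOR,
) -> pd.DataFrame:
    """Events x samples psi matrix from a long counts table.

    ``counts`` needs columns event_id, sample_id, inc_count, skip_count.
    Event/sample cells without a counts row, or below the coverage floor,
    are NaN. Rows and columns are sorted for determinism.
    """
    if not isinstance(events, Mapping):
        events = {e.event_id: e for e in events}
    unknown = set(counts["event_id"]) - set(events)
    if unknown:
        raise KeyError(f"counts reference unknown events: {sorted(unknown)[:5]}")
    rows = {}
    for row in counts.itertuples(index=False):
        ev = events[row.event_id]
        pv = compute_psi(ev, int(row.inc_count), int(row.skip_count),
                         coverage_floor, str(row.sample_id))
        rows[(row.event_id, str(row.sample_id))] = math.nan if pv.psi is None else pv.psi
    ser = pd.Series(rows, dtype=float)
    mat = ser.unstack()
    mat.index.name = "event_id"
    return mat.sort_index(axis=0).sort_index(axis=1)


def psi_from_transcript_ratio(
    abundance: pd.DataFrame,
    transcript_to_gene: Mapping[str, str],
    gene: str,
    inclusion_transcripts: Iterable[str],
    exclusion_transcripts: Iterable[str],
    sample: str,
) -> Optional[float]:
    """psi as the inclusion share of isoform abundance for one gene/sample.

    ``abundance`` is a transcripts x samples matrix (TPM-like). The two
    transcript sets must be disjoint, non-empty, and belong to ``gene``.
    Returns None when the combined abundance is zero (ratio undefined).
    """
    inc = set(inclusion_transcripts)
    exc = set(exclusion_transcripts)
    if not inc or not exc:
        raise ValueError("both transcript sets must be non-empty")
    if inc & exc:
        raise ValueError("inclusion and exclusion transcript sets overlap")
    for tid in inc | exc:
        if transcript_to_gene.get(tid) != gene:
            raise ValueError(f"transcript {tid!r} does not belong to gene {gene!r}")
        if tid not in abundance.index:
            raise ValueError(f"transcript {tid!r} absent from abundance matrix")
    inc_sum = float(abundance.loc[sorted(inc), sample].sum())
    exc_sum = float(abundance.loc[sorted(exc), sample].sum())
    denom = inc_sum + exc_sum
    if denom == 0.0 or not math.isfinite(denom):
        return None
    return inc_sum / denom


def transcript_ratio_psi_series(
    abundance: pd.DataFrame,
    transcript_to_gene: Mapping[str, str],
    gene: str,
    inclusion_transcripts: Iterable[str],
    exclusion_transcripts: Iterable[str],
) -> pd.Series:
    """Vectorized :func:`psi_from_transcript_ratio` across all samples."""
    vals = {
        s: psi_from_transcript_ratio(
            abundance, transcript_to_gene, gene,
            inclusion_transcripts, exclusion_transcripts, s,
        )
        for s in abundance.columns
    }
    return pd.Series(
        {s: (math.nan if v is None else v) for s, v in vals.items()}, dtype=float
    ).sort_index()
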
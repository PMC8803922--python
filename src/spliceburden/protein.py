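"""Protein-level consequences of splice events.

The variable genomic region of an event is intersected with the coding span
of a reference transcript and converted, strand-aware, to a 1-based closed
residue interval; an event is frame-preserving when the affected coding
length is a multiple of 3. Gene-level summaries report the percentage of a
gene set whose events hit annotated domains, intrinsically disordered
regions (IDR), or PTM sites.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    GeneModel,
    GeneSet,
    GenomicInterval,
    ProteinFeature,
    SpliceEvent,
    TranscriptModel,
)

FEATURE_CLASSES = ("domain", "IDR", "PTM")


@dataclass(frozen=True)
class ProteinImpact:
    """Residue-level footprint of one event on one reference transcript.

    ``residue_start``/``residue_end`` are 1-based inclusive; both None when
    the event's variable region does not touch the coding sequence.
    """

    event_id: str
    gene: str
    residue_start: Optional[int]
    residue_end: Optional[int]
    frame_preserving: bool
    affected_classes: frozenset[str] = field(default_factory=frozenset)

    @property
    def coding(self) -> bool:
        return self.residue_start is not None


def _coding_segments(tx: TranscriptModel) -> list[GenomicInterval]:
    """Exonic pieces of the CDS span, genomic order."""
    if tx.cds is None:
        raise ValueError(f"transcript {tx.transcript_id} has no CDS")
    segs = []
    for exon in tx.exons:
        s, e = max(exon.start, tx.cds.start), min(exon.end, tx.cds.end)
        if s < e:
            segs.append(GenomicInterval(exon.chrom, s, e, exon.strand))
    if not segs:
        raise ValueError(f"transcript {tx.transcript_id}: CDS outside exons")
    return segs


def map_event_to_protein(event: SpliceEvent, transcript: TranscriptModel) -> ProteinImpact:
    """Project an event's variable region onto protein residues.

    Coding offsets run in transcription order (5'->3' of the mRNA), so the
    mapping is strand-consistent: mirrored plus/minus fixtures give the
    same residue interval. Residue k covers coding offsets 3(k-1)..3k-1.
    """
    segs = _coding_segments(transcript)
    # cumulative coding offset at the transcription-order start of each segment
    ordered = segs if transcript.strand == "+" else list(reversed(segs))
    cum = 0
    offsets: list[tuple[GenomicInterval, int]] = []
    for seg in ordered:
        offsets.append((seg, cum))
        cum += len(seg)

    lo: Optional[int] = None
    hi: Optional[int] = None
    affected_len = 0
    for region in event.variable_regions:
        for seg, base in offsets:
            s, e = max(region.start, seg.start), min(region.end, seg.end)
            if s >= e:
                continue
            affected_len += e - s
            if transcript.strand == "+":
                first, last = base + (s - seg.start), base + (e - 1 - seg.start)
            else:
                first, last = base + (seg.end - e), base + (seg.end - 1 - s)
            lo = first if lo is None else min(lo, first)
            hi = last if hi is None else max(hi, last)

    if lo is None:
        return ProteinImpact(event.event_id, event.gene_id, None, None,
                             frame_preserving=True)
    return ProteinImpact(
        event_id=event.event_id,
        gene=event.gene_id,
        residue_start=lo // 3 + 1,
        residue_end=hi // 3 + 1,
        frame_preserving=(affected_len % 3 == 0),
    )


def pick_reference_transcript(
    gene: GeneModel, event: SpliceEvent
) -> Optional[TranscriptModel]:
    """Reference for protein mapping: the coding transcript containing the
    event's inclusion form (all variable regions inside its exons) with the
    longest coding length; ties broken by transcript identifier."""
    candidates = []
    for tx in gene.transcripts:
        if tx.cds is None:
            continue
        if all(
            any(exon.contains(region) for exon in tx.exons)
            for region in event.variable_regions
        ):
            coding_len = sum(len(s) for s in _coding_segments(tx))
            candidates.append((-coding_len, tx.transcript_id, tx))
    if not candidates:
        return None
    return min(candidates)[2]


def annotate_feature_classes(
    impact: ProteinImpact, features: Iterable[ProteinFeature]
) -> ProteinImpact:
    """Return the impact with the classes of overlapped features filled in.

    Overlap is closed-interval residue intersection; PTM sites must lie
    within the affected interval.
    """
    if not impact.coding:
        return impact
    hit = set()
    for f in features:
        if f.gene != impact.gene:
            continue
        if f.start <= impact.residue_end and impact.residue_start <= f.end:
            hit.add(f.fclass)
    return ProteinImpact(
        impact.event_id, impact.gene, impact.residue_start, impact.residue_end,
        impact.frame_preserving, frozenset(hit),
    )


def affected_feature_fraction(
    impacts: Sequence[ProteinImpact],
    features: Sequence[ProteinFeature],
    genes: GeneSet,
) -> pd.Series:
    """Percentage of set genes whose events hit each feature class.

    A gene counts for a class when any of its events' residue intervals
    intersects a feature of that class; the denominator is set genes with
    at least one coding (mapped) event. Percentages are on the 0-100 scale.
    """
    mapped_genes = {i.gene for i in impacts if i.coding and i.gene in genes.genes}
    counts = {c: set() for c in FEATURE_CLASSES}
    for impact in impacts:
        if not impact.coding or impact.gene not in genes.genes:
            continue
        annotated = annotate_feature_classes(impact, features)
        for c in annotated.affected_classes:
            counts[c].add(impact.gene)
    denom = len(mapped_genes)
    return pd.Series(
        {c: (100.0 * len(counts[c]) / denom if denom else 0.0) for c in FEATURE_CLASSES},
        dtype=float,
    )
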
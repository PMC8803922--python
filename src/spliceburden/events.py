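"""Enumeration of local alternative-splicing events from transcript models.

Events are found by pairwise comparison of a gene's transcripts:

* **SE** — an internal exon of one transcript is absent from the other,
  which instead joins the two flanking exons directly.
* **MXE** — two non-overlapping internal exons, each private to one
  transcript, spliced between the same flanking junction boundaries.
* **A5SS / A3SS** — two exons share one boundary and differ at the other,
  spliced to a common partner exon; whether the variable boundary is the
  donor (5') or acceptor (3') side is resolved by strand.
* **RI** — an intron of one transcript lies strictly inside an exon of the
  other (the intron is retained).

Events are deduplicated on (type, coordinates) across transcript pairs and
returned in a deterministic order, so enumeration is invariant to the input
order of transcripts.
"""
from __future__ import annotations

from .types import (
    EVENT_TYPES,
    GeneModel,
    GenomicInterval,
    SpliceEvent,
    TranscriptModel,
    event_id_for,
)


def _exon_tuples(tx: TranscriptModel) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in tx.exons]


def _se_events(t1: TranscriptModel, t2: TranscriptModel) -> list[dict]:
    """Cassette exons present in t1, skipped by t2."""
    out = []
    j2 = set(t2.junctions())
    exons1 = t1.exons
    for i in range(1, len(exons1) - 1):
        exon = exons1[i]
        left, right = exons1[i - 1], exons1[i + 1]
        skip_junction = (left.end, right.start)
        if skip_junction in j2 and (exon.start, exon.end) not in _exon_tuples(t2):
            out.append(
                dict(
                    etype="SE",
                    coords=(left.end, exon.start, exon.end, right.start),
                    inc={(left.end, exon.start), (exon.end, right.start)},
                    skip={skip_junction},
                    regions=(exon,),
                    len_inc=2,
                    len_skip=1,
                )
            )
    return out


def _mxe_events(t1: TranscriptModel, t2: TranscriptModel) -> list[dict]:
    """Mutually exclusive internal exons between shared flanking boundaries.

    The inclusion form is defined as the one using the genomically upstream
    exon; the other form is the skipping form.
    """
    out = []
    tuples1, tuples2 = _exon_tuples(t1), _exon_tuples(t2)
    for i in range(1, len(t1.exons) - 1):
        e1 = t1.exons[i]
        l1, r1 = t1.exons[i - 1], t1.exons[i + 1]
        for j in range(1, len(t2.exons) - 1):
            e2 = t2.exons[j]
            l2, r2 = t2.exons[j - 1], t2.exons[j + 1]
            if l1.end != l2.end or r1.start != r2.start:
                continue
            if e1.overlaps(e2):
                continue
            if (e1.start, e1.end) in tuples2 or (e2.start, e2.end) in tuples1:
                continue
            first, second = sorted((e1, e2), key=lambda e: (e.start, e.end))
            out.append(
                dict(
                    etype="MXE",
                    coords=(l1.end, first.start, first.end,
                            second.start, second.end, r1.start),
                    inc={(l1.end, first.start), (first.end, r1.start)},
                    skip={(l1.end, second.start), (second.end, r1.start)},
                    regions=(first,),
                    len_inc=2,
                    len_skip=2,
                )
            )
    return out


def _alt_ss_events(t1: TranscriptModel, t2: TranscriptModel) -> list[dict]:
    """Alternative 5'/3' splice sites: exons sharing one boundary, spliced to
    a common partner on the differing side."""
    out = []
    strand = t1.strand
    next1 = {e: (e.end, nxt.start) for e, nxt in zip(t1.exons, t1.exons[1:])}
    next2 = {e: (e.end, nxt.start) for e, nxt in zip(t2.exons, t2.exons[1:])}
    prev1 = {e: (prv.end, e.start) for prv, e in zip(t1.exons, t1.exons[1:])}
    prev2 = {e: (prv.end, e.start) for prv, e in zip(t2.exons, t2.exons[1:])}

    for e1 in t1.exons:
        for e2 in t2.exons:
            if e1.chrom != e2.chrom:
                continue
            # variable genomic end, shared start: alt donor on '+', acceptor on '-'
            if e1.start == e2.start and e1.end != e2.end:
                if e1 in next1 and e2 in next2 and next1[e1][1] == next2[e2][1]:
                    acceptor = next1[e1][1]
                    short, long_ = sorted((e1, e2), key=lambda e: e.end)
                    etype = "A5SS" if strand == "+" else "A3SS"
                    out.append(
                        dict(
                            etype=etype,
                            coords=(e1.start, short.end, long_.end, acceptor),
                            inc={(long_.end, acceptor)},
                            skip={(short.end, acceptor)},
                            regions=(GenomicInterval(e1.chrom, short.end, long_.end, strand),),
                            len_inc=1,
                            len_skip=1,
                        )
                    )
            # variable genomic start, shared end: alt acceptor on '+', donor on '-'
            if e1.end == e2.end and e1.start != e2.start:
                if e1 in prev1 and e2 in prev2 and prev1[e1][0] == prev2[e2][0]:
                    donor = prev1[e1][0]
                    long_, short = sorted((e1, e2), key=lambda e: e.start)
                    etype = "A3SS" if strand == "+" else "A5SS"
                    out.append(
                        dict(
                            etype=etype,
                            coords=(donor, long_.start, short.start, e1.end),
                            inc={(donor, long_.start)},
                            skip={(donor, short.start)},
                            regions=(GenomicInterval(e1.chrom, long_.start, short.start, strand),),
                            len_inc=1,
                            len_skip=1,
                        )
                    )
    return out


def _ri_events(t1: TranscriptModel, t2: TranscriptModel) -> list[dict]:
    """Introns of t2 retained (strictly contained) within an exon of t1.

    The inclusion (retention) form is supported by intron-body coverage and
    carries no diagnostic junction; the skipping form is the spliced intron.
    """
    out = []
    for donor, acceptor in t2.junctions():
        for exon in t1.exons:
            if exon.start < donor and acceptor < exon.end:
                out.append(
                    dict(
                        etype="RI",
                        coords=(exon.start, donor, acceptor, exon.end),
                        inc=set(),
                        skip={(donor, acceptor)},
                        regions=(GenomicInterval(exon.chrom, donor, acceptor, exon.strand),),
                        len_inc=1,
                        len_skip=1,
                    )
                )
    return out


def enumerate_events(gene: GeneModel) -> list[SpliceEvent]:
    """All distinct splice events among a gene's transcripts.

    Returns an empty list for single-transcript genes. Output is ordered by
    (event type, coordinates) and deduplicated across transcript pairs.
    """
    if not gene.multi_isoform:
        return []
    found: dict[tuple, dict] = {}
    txs = sorted(gene.transcripts, key=lambda t: t.transcript_id)
    for a in range(len(txs)):
        for b in range(len(txs)):
            if a == b:
                continue
            t1, t2 = txs[a], txs[b]
            for rec in (
                _se_events(t1, t2)
                + _mxe_events(t1, t2)
                + _alt_ss_events(t1, t2)
                + _ri_events(t1, t2)
            ):
                key = (rec["etype"], rec["coords"])
                found.setdefault(key, rec)

    type_order = {t: i for i, t in enumerate(EVENT_TYPES)}
    events = []
    for (etype, coords), rec in sorted(
        found.items(), key=lambda kv: (type_order[kv[0][0]], kv[0][1])
    ):
        events.append(
            SpliceEvent(
                event_id=event_id_for(gene.gene_id, etype, coords),
                gene_id=gene.gene_id,
                etype=etype,
                chrom=gene.chrom,
                strand=gene.strand,
                inclusion_junctions=frozenset(rec["inc"]),
                skipping_junctions=frozenset(rec["skip"]),
                variable_regions=tuple(rec["regions"]),
                len_inc=rec["len_inc"],
                len_skip=rec["len_skip"],
                coords=coords,
            )
        )
    return events
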
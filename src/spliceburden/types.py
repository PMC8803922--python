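"""Domain types shared across the pipeline.

Coordinate convention: all genomic intervals held in memory are 0-based,
half-open ``[start, end)``. External GTF I/O converts to/from the 1-based
inclusive convention at the boundary (see :mod:`spliceburden.io`).
Protein residue intervals are 1-based inclusive.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

QUALIFYING_IMPACTS = frozenset({"missense", "frameshift", "nonsense", "splice_site"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus an optional coding span.

    Exons are stored sorted by genomic position (ascending start) regardless
    of strand; transcription order is derived from ``strand`` where needed.
    ``cds`` is the genomic span from the first to the last coding base.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons must share chrom and strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or abut "
                    f"([{a.start},{a.end}) then [{b.start},{b.end})); "
                    "adjacent exons need >=1 intronic base"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Intronic intervals between consecutive exons, genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def junctions(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) pairs in genomic coordinates."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def multi_isoform(self) -> bool:
        return len(self.transcripts) >= 2

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand


Junction = tuple[int, int]


@dataclass(frozen=True)
class SpliceEvent:
    """A local alternative-splicing event (SE, MXE, A5SS, A3SS or RI).

    ``inclusion_junctions`` / ``skipping_junctions`` are the intron
    (donor_end, acceptor_start) pairs diagnostic of each form; for RI the
    inclusion form has no junction and is supported by intron-body reads.
    ``variable_regions`` are the genomic segments present in the inclusion
    form but not the skipping form (used for protein-impact mapping).
    ``len_inc`` / ``len_skip`` are the effective normalizing lengths of the
    two forms (number of distinct diagnostic junctions, minimum 1).
    """

    event_id: str
    gene_id: str
    etype: str
    chrom: str
    strand: str
    inclusion_junctions: frozenset[Junction]
    skipping_junctions: frozenset[Junction]
    variable_regions: tuple[GenomicInterval, ...]
    len_inc: int
    len_skip: int
    coords: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if self.len_inc < 1 or self.len_skip < 1:
            raise ValueError("effective lengths must be >= 1")
        if self.inclusion_junctions & self.skipping_junctions:
            raise ValueError("inclusion and skipping junction sets must be disjoint")


def event_id_for(gene_id: str, etype: str, coords: Sequence[int]) -> str:
    """Deterministic event identifier from (gene, type, coordinates)."""
    key = f"{gene_id}|{etype}|{','.join(map(str, coords))}"
    digest = hashlib.sha1(key.encode()).hexdigest()[:10]
    return f"{gene_id}:{etype}:{digest}"


@dataclass(frozen=True)
class MutationCall:
    """One alteration record from a MAF-like table.

    ``copy_number`` is meaningful for CNV records only; SNV/indel records
    carry VAF and depth. A record's mere presence marks the gene as not
    alteration-free; whether it *qualifies* as mutant-making is decided by
    :func:`is_qualifying`.
    """

    sample_id: str
    gene: str
    mclass: str  # SNV | indel | CNV
    impact: str = "other"  # missense | frameshift | nonsense | splice_site | other
    vaf: float = 0.0
    depth: int = 0
    copy_number: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of range: {self.vaf}")
        if self.depth < 0 or self.copy_number < 0:
            raise ValueError("depth and copy_number must be non-negative")


def is_qualifying(call: MutationCall, vaf_min: float = 0.2, depth_min: int = 20,
                  gain_copies: int = 5) -> bool:
    """Mutant-making alteration: medium/high-impact SNV/indel at VAF > 0.2 and
    depth > 20, a copy-number gain of 5+ copies, or a homozygous deletion."""
    if call.mclass in ("SNV", "indel"):
        return (
            call.impact in QUALIFYING_IMPACTS
            and call.vaf > vaf_min
            and call.depth > depth_min
        )
    if call.mclass == "CNV":
        return call.copy_number >= gain_copies or call.copy_number == 0
    return False


@dataclass(frozen=True)
class PathwayStatus:
    sample_id: str
    gene_set: str
    status: str  # mutant | wild_type | indeterminate

    def __post_init__(self) -> None:
        if self.status not in ("mutant", "wild_type", "indeterminate"):
            raise ValueError(f"bad status {self.status!r}")


@dataclass
class ClinicalRecord:
    sample_id: str
    os_time: float  # days
    os_event: int  # 1 death, 0 censored
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.os_time <= 0:
            raise ValueError(f"os_time must be positive, got {self.os_time}")
        if self.os_event not in (0, 1):
            raise ValueError("os_event must be 0 or 1")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @staticmethod
    def of(name: str, genes) -> "GeneSet":
        return GeneSet(name, frozenset(genes))


@dataclass(frozen=True)
class ProteinFeature:
    """A protein-level annotation: structural domain, intrinsically
    disordered region (IDR), or single-residue PTM site. Residues 1-based
    inclusive; a PTM site has start == end."""

    gene: str
    fclass: str  # domain | IDR | PTM
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.fclass not in ("domain", "IDR", "PTM"):
            raise ValueError(f"bad feature class {self.fclass!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")
        if self.fclass == "PTM" and self.start != self.end:
            raise ValueError("PTM sites are single residues")
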
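"""Readers and writers for every external table the pipeline touches.

All tabular formats are UTF-8, tab-delimited with a header row, and use the
literal string ``NA`` for missing values. Floats are serialized with ``%.17g``
so that write-then-read round-trips are bit-identical. GTF I/O converts
between the external 1-based inclusive and the internal 0-based half-open
conventions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    ClinicalRecord,
    GeneModel,
    GeneSet,
    GenomicInterval,
    MutationCall,
    ProteinFeature,
    TranscriptModel,
)

PathLike = Union[str, Path]

NA = "NA"
FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise ParseError(f"GTF line {lineno}: malformed attribute {chunk!r}")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(path: PathLike) -> list[GeneModel]:
    """Parse a GTF file into gene models.

    Only ``exon`` and ``CDS`` feature lines are used. GTF coordinates
    (1-based, inclusive) are converted to internal 0-based half-open.
    Genes are returned ordered by (chrom, start, gene_id); transcripts
    within a gene by transcript_id.
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    cds: dict[tuple[str, str], list[GenomicInterval]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"GTF line {lineno}: non-integer coordinates")
            if strand not in ("+", "-"):
                raise ParseError(f"GTF line {lineno}: bad strand {strand!r}")
            attrs = _gtf_attributes(attr_s, lineno)
            try:
                gid, tid = attrs["gene_id"], attrs["transcript_id"]
            except KeyError as exc:
                raise ParseError(f"GTF line {lineno}: missing attribute {exc}")
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            target = exons if feature == "exon" else cds
            target.setdefault((gid, tid), []).append(iv)

    genes: dict[str, list[TranscriptModel]] = {}
    for (gid, tid), ex in exons.items():
        cds_span: Optional[GenomicInterval] = None
        if (gid, tid) in cds:
            parts = cds[(gid, tid)]
            cds_span = GenomicInterval(
                parts[0].chrom,
                min(p.start for p in parts),
                max(p.end for p in parts),
                parts[0].strand,
            )
        genes.setdefault(gid, []).append(
            TranscriptModel(transcript_id=tid, gene_id=gid, exons=ex, cds=cds_span)
        )
    models = [
        GeneModel(gid, sorted(ts, key=lambda t: t.transcript_id))
        for gid, ts in genes.items()
    ]
    models.sort(key=lambda g: (g.chrom, min(t.span.start for t in g.transcripts), g.gene_id))
    return models


def write_annotation(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as GTF (1-based inclusive); inverse of load_annotation."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                for exon in tx.exons:
                    fh.write(
                        f"{exon.chrom}\tspliceburden\texon\t{exon.start + 1}\t"
                        f"{exon.end}\t.\t{exon.strand}\t.\t{attrs}\n"
                    )
                if tx.cds is not None:
                    fh.write(
                        f"{tx.cds.chrom}\tspliceburden\tCDS\t{tx.cds.start + 1}\t"
                        f"{tx.cds.end}\t.\t{tx.cds.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def load_gene_sets(path: PathLike) -> list[GeneSet]:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line {lineno}: expected name, description and >=1 gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet.of(name, genes))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, NA] + sorted(gs.genes)) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices and tables
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path: PathLike, index_label: str) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FMT,
              index_label=index_label)


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA],
                       keep_default_na=False, float_precision="round_trip")


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FMT, index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False,
                       float_precision="round_trip")


def read_event_counts(path: PathLike) -> pd.DataFrame:
    """Long table with columns event_id, sample_id, inc_count, skip_count."""
    df = read_table(path)
    required = {"event_id", "sample_id", "inc_count", "skip_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"event counts table missing columns: {sorted(missing)}")
    if (df[["inc_count", "skip_count"]] < 0).any().any():
        raise ParseError("negative counts in event counts table")
    return df


def read_mutations(path: PathLike) -> list[MutationCall]:
    df = read_table(path)
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            MutationCall(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                mclass=str(row.mclass),
                impact=str(row.impact),
                vaf=float(row.vaf) if not pd.isna(row.vaf) else 0.0,
                depth=int(row.depth) if not pd.isna(row.depth) else 0,
                copy_number=int(row.copy_number) if not pd.isna(row.copy_number) else 2,
            )
        )
    return calls


def write_mutations(calls: Iterable[MutationCall], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            (c.sample_id, c.gene, c.mclass, c.impact, c.vaf, c.depth, c.copy_number)
            for c in calls
        ],
        columns=["sample_id", "gene", "mclass", "impact", "vaf", "depth", "copy_number"],
    )
    write_table(df, path)


def read_clinical(path: PathLike) -> list[ClinicalRecord]:
    df = read_table(path)
    fixed = {"sample_id", "os_time", "os_event"}
    covar_cols = [c for c in df.columns if c not in fixed]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ClinicalRecord(
                sample_id=str(d["sample_id"]),
                os_time=float(d["os_time"]),
                os_event=int(d["os_event"]),
                covariates={c: d[c] for c in covar_cols},
            )
        )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: PathLike) -> None:
    records = list(records)
    covar_cols = sorted({k for r in records for k in r.covariates})
    rows = [
        {"sample_id": r.sample_id, "os_time": r.os_time, "os_event": r.os_event,
         **{c: r.covariates.get(c) for c in covar_cols}}
        for r in records
    ]
    write_table(pd.DataFrame(rows), path)


def read_protein_features(path: PathLike) -> list[ProteinFeature]:
    df = read_table(path)
    return [
        ProteinFeature(str(r.gene), str(r.fclass), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_protein_features(features: Iterable[ProteinFeature], path: PathLike) -> None:
    df = pd.DataFrame(
        [(f.gene, f.fclass, f.start, f.end) for f in features],
        columns=["gene", "fclass", "start", "end"],
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of cross-table consistency checks.

    ``hard`` violations (out-of-range values, duplicates) must stop the
    pipeline; ``soft`` warnings (sample-set mismatches) are informational.
    """

    hard: list[str] = field(default_factory=list)
    soft: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.hard

    def raise_on_hard(self) -> None:
        if self.hard:
            raise ValueError("bundle validation failed:\n" + "\n".join(self.hard))


def validate_bundle(
    psi: Optional[pd.DataFrame] = None,
    abundance: Optional[pd.DataFrame] = None,
    mutations: Optional[list[MutationCall]] = None,
    clinical: Optional[list[ClinicalRecord]] = None,
) -> ValidationReport:
    """Cross-check a cohort bundle: value ranges, duplicates, sample-ID overlap.

    Any subset of tables may be supplied; checks degrade gracefully.
    """
    report = ValidationReport()
    sample_sets: dict[str, set[str]] = {}

    if psi is not None:
        vals = psi.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            report.hard.append(
                f"psi matrix contains values outside [0, 1] "
                f"(min={finite.min():g}, max={finite.max():g})"
            )
        if psi.index.duplicated().any():
            report.hard.append("psi matrix has duplicate event identifiers")
        sample_sets["psi"] = set(map(str, psi.columns))

    if abundance is not None:
        vals = abundance.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and finite.min() < 0.0:
            report.hard.append("abundance matrix contains negative values")
        if abundance.index.duplicated().any():
            report.hard.append("abundance matrix has duplicate transcript identifiers")
        sample_sets["abundance"] = set(map(str, abundance.columns))

    if mutations is not None:
        seen = set()
        for c in mutations:
            key = (c.sample_id, c.gene, c.mclass, c.impact, c.vaf, c.depth, c.copy_number)
            if key in seen:
                report.hard.append(f"duplicate mutation record: {key}")
            seen.add(key)
        sample_sets["mutations"] = {c.sample_id for c in mutations}

    if clinical is not None:
        ids = [r.sample_id for r in clinical]
        if len(ids) != len(set(ids)):
            report.hard.append("duplicate sample_id in clinical table")
        for r in clinical:
            if not math.isfinite(r.os_time) or r.os_time <= 0:
                report.hard.append(f"clinical sample {r.sample_id}: invalid os_time")
        sample_sets["clinical"] = set(ids)

    names = [n for n in ("psi", "abundance", "clinical") if n in sample_sets]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            only_a = sample_sets[a] - sample_sets[b]
            only_b = sample_sets[b] - sample_sets[a]
            if only_a:
                report.soft.append(
                    f"{len(only_a)} sample(s) in {a} but not {b}: "
                    + ", ".join(sorted(only_a)[:5])
                )
            if only_b:
                report.soft.append(
                    f"{len(only_b)} sample(s) in {b} but not {a}: "
                    + ", ".join(sorted(only_b)[:5])
                )
    return report
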
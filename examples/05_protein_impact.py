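"""Enumerate splice events from transcript models and map one onto protein
residues and annotated features.

A cassette exon of 30 coding nucleotides removes 10 residues without
shifting the reading frame; whether it clips a domain, disordered region,
or PTM site is decided by closed-interval residue overlap.
"""
from spliceburden import GeneModel, GenomicInterval, TranscriptModel
from spliceburden.events import enumerate_events
from spliceburden.protein import (
    affected_feature_fraction, annotate_feature_classes, map_event_to_protein,
    pick_reference_transcript,
)
from spliceburden.types import GeneSet, ProteinFeature

def tx(tid, exons, cds):
    return TranscriptModel(tid, "NF1like", [GenomicInterval("chr1", s, e) for s, e in exons],
                           cds=GenomicInterval("chr1", *cds))

gene = GeneModel("NF1like", [
    tx("inc", [(100, 220), (300, 330), (400, 500)], (130, 480)),
    tx("exc", [(100, 220), (400, 500)], (130, 480)),
])
events = enumerate_events(gene)
print(f"events found: {[(e.etype, e.coords) for e in events]}")

(event,) = events
ref = pick_reference_transcript(gene, event)
impact = map_event_to_protein(event, ref)
print(f"cassette maps to residues {impact.residue_start}-{impact.residue_end}, "
      f"frame-preserving: {impact.frame_preserving}")

features = [ProteinFeature("NF1like", "domain", 25, 45),
            ProteinFeature("NF1like", "PTM", 33, 33)]
annotated = annotate_feature_classes(impact, features)
print(f"feature classes hit: {sorted(annotated.affected_classes)}")
pct = affected_feature_fraction([impact], features, GeneSet.of("drivers", ["NF1like"]))
print("percent of driver genes affected per class:")
print(pct.to_string())
# The 10-residue insertion sits inside the annotated domain and covers the
# PTM site - the in-frame alteration the isoform switch produces.
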
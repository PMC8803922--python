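"""Generate a seeded synthetic tumor/normal cohort and write its bundle.

The generator plants the structures the analysis is built to detect:
differential splice events, an isoform-diversity (entropy) gradient between
tumor and normal, driver-gene mutations with sub-threshold decoys, a
pathway expression program coupled to an NF1-like isoform switch, and
survival times tied to splicing burden.
"""
from spliceburden import CohortConfig, simulate_cohort, write_bundle

config = CohortConfig(seed=7)
bundle = simulate_cohort(config)
write_bundle(bundle, "scratch/cohort")

truth = bundle.event_truth
print(f"samples: {len(bundle.tumor_samples)} tumor, {len(bundle.normal_samples)} normal")
print(f"genes: {len(bundle.genes)} ({sum(g.multi_isoform for g in bundle.genes)} multi-isoform)")
print(f"events: {len(bundle.events)} ({int(truth['planted'].sum())} with a planted shift)")
print(f"mutation calls: {len(bundle.mutations)}")
print(f"NF1-like gene: {bundle.nf1_gene} "
      f"(inclusion isoform {bundle.nf1_inclusion_transcript})")
# Planted events move tumor psi by ~0.30; everything else is noise around a
# shared baseline, so the differential caller has a known answer key.
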
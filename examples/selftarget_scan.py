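"""Scan a genome for self-targeting spacers (protospacers outside arrays).

Plants one spacer copy on a locus contig and one reverse-complement copy,
then runs the mismatch-tolerant two-strand scan and prints every event.
"""

from acrminer import FixtureConfig, find_self_targets, generate_synthetic_genome
from acrminer.synthetic import plant_self_target

bundle = generate_synthetic_genome(FixtureConfig(seed=11, decoy_classes=()))
bundle = plant_self_target(bundle, "ctg_pos2", same_contig=True, revcomp=True)

events = find_self_targets(
    bundle.arrays, bundle.genome.contigs, bundle.systems, max_mismatch=2
)
print("spacer      contig        target          strand  mm  subtype")
for ev in events:
    print(f"{ev.spacer_id:<11} {ev.target_contig:<13} "
          f"{ev.target_start}-{ev.target_end:<9} {ev.target_strand:<6} "
          f"{ev.mismatches:<3} {ev.subtype}")
print()
print("Each event is a spacer whose matching protospacer lies outside every")
print("CRISPR array — evidence the host must silence its own system, e.g.")
print("through an anti-CRISPR locus on the targeted contig. The '-' strand")
print("event is the reverse-complement copy planted above.")
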
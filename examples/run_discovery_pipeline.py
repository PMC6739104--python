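"""Run the four-step Acr-Aca discovery cascade on a synthetic genome.

Builds a genome with three planted anti-CRISPR operons plus seven decoys
(each violating exactly one discovery rule), runs homology + GBA, operon
calling, the MGE-context filter and the self-targeting filter, and prints
the per-step attrition.
"""

import tempfile

from acrminer import FixtureConfig, RunConfig, generate_synthetic_genome, run_pipeline

bundle = generate_synthetic_genome(FixtureConfig(seed=7, n_positive_loci=3))
with tempfile.TemporaryDirectory() as tmp:
    paths = bundle.write(tmp)
    report = run_pipeline(
        RunConfig(
            gff=str(paths["gff"]),
            proteins_faa=str(paths["proteins_faa"]),
            acr_hits=str(paths["acr_hits"]),
            domain_hits=str(paths["domain_hits"]),
            contigs_fna=str(paths["contigs_fna"]),
            mge_bed=str(paths["mge_bed"]),
            crispr_tsv=str(paths["crispr_tsv"]),
            genome_id="synthetic_genome",
            log_level="WARNING",
        )
    )

print("filter-step strata (loci surviving each combination):")
for s in report.summaries:
    print(f"  steps {{{s.stratum}}}: {s.n_loci} loci, "
          f"{s.n_loci_with_acr} with Acr homologs")
print()
final = report.surviving("aca_locus", "mge", "self_target")
print(f"{len(final)} loci pass all four filters:")
for lc in sorted(final, key=lambda l: l.contig_id):
    fams = ",".join(c.family for c in lc.acr_calls)
    print(f"  {lc.contig_id}:{lc.start}-{lc.end} ({lc.operon.strand})  "
          f"Acr={fams}  Aca={','.join(sorted(lc.aca_protein_ids))}")
print()
print("Only the three planted operons survive: each keeps an Acr homolog")
print("(<200 aa, E<1e-2), a downstream HTH gene, a prophage context and a")
print("same-contig self-targeting protospacer; every decoy fails one rule.")
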
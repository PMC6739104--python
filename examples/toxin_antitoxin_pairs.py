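"""Annotate candidate loci as putative type-II toxin-antitoxin operons.

Builds a two-gene locus, supplies toxin/antitoxin homology hits for its
genes and reports whether the locus matches the canonical TA layout
(antitoxin = HTH protein downstream of the toxin in transcription order).
"""

from acrminer.genome_io import Gene, HomologyHit
from acrminer.loci import CandidateLocus, Operon, locus_id_for
from acrminer.subtyping import check_ta_pairs

genes = (
    Gene("acr_candidate", "c1", 1000, 1422, "+", "acr_candidate", 140),
    Gene("hth_partner", "c1", 1463, 1735, "+", "hth_partner", 90),
)
op = Operon("c1", "+", genes)
locus = CandidateLocus(
    locus_id=locus_id_for(op, "demo"), operon=op, genome_id="demo",
    aca_protein_ids=frozenset({"hth_partner"}),
    filters_passed=("aca_locus",),
)

toxin_hits = [HomologyHit("RelE_toxin", "acr_candidate", 88.0, 90, 5.2e-10, 120.0)]
antitoxin_hits = [HomologyHit("ParE_antitoxin", "hth_partner", 80.0, 85, 1e-3 / 2, 95.0)]

call = check_ta_pairs(locus, toxin_hits, antitoxin_hits, evalue_max=1e-3)
print(f"locus {call.locus_id}")
print(f"  toxin hit:     {call.toxin_protein}")
print(f"  antitoxin hit: {call.antitoxin_protein}")
print(f"  paired: {call.paired}   canonical order: {call.canonical_order}")
print()
print("paired=True with canonical order means the HTH (Aca-like) gene sits")
print("downstream of the candidate toxin — the composition shared by Acr-Aca")
print("operons and type-II TA modules, which is why the two can be confused.")
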
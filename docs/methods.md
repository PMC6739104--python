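# Methods

## The discovery model

`acrminer` treats anti-CRISPR discovery as a conjunction of four
independent observables over an annotated genome:

1. **Acr homology.** A protein is an Acr homolog when some hit to a known
   Acr family representative has E-value `< 1e-2` and the protein is
   `< 200` aa. Both comparisons are strict: a hit at exactly the cutoff
   does not qualify. The family of the minimum-E-value hit names the call;
   ties break by higher bitscore, then lexicographic query id (the choice
   is arbitrary but deterministic; multi-family resolution has no canonical
   rule in the field).
2. **Operon structure.** An operon is a maximal run of same-strand genes on
   one contig in which every protein is `< 200` aa and every intergenic gap
   is `< 150` bp. The gap between genes sorted by start is
   `b.start − a.end − 1` with 1-based inclusive coordinates, so abutting
   genes have gap 0 and overlapping genes a negative gap (which satisfies
   the rule). A gene at or above 200 aa *breaks* the run rather than being
   skipped: the short-protein criterion is read as a property of the whole
   run. Candidate loci are operons holding ≥ 1 Aca homolog and, by default,
   ≥ 2 genes (`min_locus_genes=1` restores single-gene loci, which occur
   among characterized Acr operons).
3. **Guilt-by-association.** Aca candidates are HTH-domain proteins
   (`Pfam HTH_*` names plus DUF1870, domain E-value `< 1e-3`) that are
   `< 200` aa and lie in the same operon as an Acr homolog or within
   ±3 genes of that operon on the same contig (strand-agnostic flank — the
   published locus layouts all fit inside this window). An Acr homolog
   itself counts as an Aca candidate only when it independently carries an
   HTH domain (the AcrIIA1 dual-role case). The Aca-homolog E-value cutoff
   (`1e-3`) and the HTH criteria are package defaults, stricter than the
   Acr cutoff because HTH families are far more conserved; both are
   configurable.
4. **Genomic context.** The MGE filter keeps a locus when its closest-edge
   distance to a prophage or genomic-island interval on the same contig is
   ≤ 5,000 bp (inclusive; partial overlap suffices — the permissive reading,
   since no edge arithmetic is canonical). Prophages and genomic islands
   are pooled. The self-targeting filter requires (a) a complete CRISPR-Cas
   system in the genome — every gene of the packaged subtype-defining set
   present, plus ≥ 1 array with ≥ 1 spacer — and (b) ≥ 1 protospacer on the
   locus contig.

Subtype inference runs by two routes: the Acr family name encodes the
inhibited subtype (`AcrIF3 → I-F`, hybrids map to the union of their
parts), and each self-targeting event carries the subtype of the complete
system governing its source array. A conflict is a locus whose two subtype
sets are *disjoint*; any overlap (e.g. a hybrid family covering the
self-target subtype) counts as agreement. Conflicts are de-duplicated on
(homology families, self-target subtypes, Acr protein ids), collapsing the
copies that near-identical strain genomes produce.

## Tunable parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `acr_evalue_max` | 1e-2 | — | Acr homology cutoff (exclusive) |
| `aca_evalue_max` | 1e-3 | — | Aca homology cutoff (exclusive) |
| `max_protein_len` | 200 | aa | short-protein cutoff (exclusive) |
| `hth_domain_evalue_max` | 1e-3 | — | HTH domain evidence cutoff |
| `max_intergenic_gap` | 150 | bp | operon gap cutoff (exclusive) |
| `gba_flank_genes` | 3 | genes | GBA neighborhood beyond the operon |
| `min_locus_genes` | 2 | genes | minimum operon size for a locus |
| `margin_bp` | 5000 | bp | MGE adjacency margin (inclusive) |
| `max_mismatch` | 2 | nt | spacer-protospacer substitutions |
| TA `evalue_max` | 1e-3 | — | toxin/antitoxin hit cutoff |

`max_mismatch=2` tolerates seed-distal mutations in a ~32 nt protospacer
without flooding the scan with spurious matches; 0 reduces the detector to
exact two-strand string search. The detector is deliberately PAM-agnostic:
externally produced self-targeting tables are consumed verbatim when
supplied, and the internal scan makes no protospacer-adjacent-motif
assumption.

## Numerical and representational choices

- Coordinates are 1-based inclusive everywhere internally; BED input is
  converted at the parser boundary. Protein length from an explicit protein
  FASTA takes precedence over the GFF-span estimate `(end−start+1)/3 − 1`.
- Cas-system completeness is a pure set-cover test against an editable
  packaged table of minimal subtype-defining gene sets (cas1, cas2-3,
  cas5f–cas8f for I-F, etc.). It is a deliberate simplification of
  interference/adaptation-module annotation; required array-to-cas distance
  is ignored because no quantitative rule exists for "nearby".
- Spacer-to-system attribution prefers a complete system on the array's
  contig, then any complete system, ties broken lexicographically by system
  id (system records carry no coordinates, so genomic distance is not
  computed; multi-system genomes report all subtypes through their events).
- The built-in protein search is Smith-Waterman (BLOSUM62, BLAST-style gap
  open 11 / extend 1, via Biopython's `PairwiseAligner`) with Karlin-
  Altschul E-values `E = K·m·n·exp(−λS)` using the standard gapped
  parameters λ = 0.267, K = 0.041, m = query length, n = total database
  residues. It serves tests and small analyses; production runs consume
  external tabular hits.
- Percentages round half away from zero to one decimal (`Decimal`
  arithmetic, not binary-float rounding). One published ratio (1,516/2,022)
  prints as 75.1 in the literature but recomputes to 75.0 under any
  round-half rule; it is documented here and excluded from the acceptance
  quantities.
- Locus ids are SHA1-derived from (genome, contig, span, strand), so
  identical inputs always produce identical ids and re-runs are
  byte-identical.
- Degenerate inputs: empty hit tables and empty genomes yield empty results
  (not errors); spacers containing N are skipped with a warning; unresolved
  hit subject ids are warned about, never silently dropped.

## The synthetic-data generator

`generate_synthetic_genome` builds one multi-contig genome in which every
discovery rule is exercised by construction. Each positive locus sits on
its own 40 kb contig: a 140 aa Acr gene (planted blast6 hit at E = 1e-30,
protein sequence a 70%-identity mutated copy of the family seed so the
built-in aligner can rediscover it), a 40 bp gap, a 90 aa HTH partner
(planted domtblout hit at 1e-6), an enclosing prophage interval and a
protospacer copied from the genome's I-F-governed array. Each of the seven
decoy classes perturbs exactly one number or placement (partner 250 aa, gap
exactly 150 bp, partner on the opposite strand, no HTH hit, MGE > 5 kb
away, no protospacer, protospacer on a different contig), so a pipeline
failure maps one-to-one onto a rule. Cross-contig protospacers land on a
dedicated gene-free contig so they cannot rescue another decoy at the
colocalization step.

The generator emulates the *logic* of real genomes, not their texture:
intergenic sequence is i.i.d. random DNA, proteins are i.i.d. random amino
acids, gene density is far below natural, and hit tables are planted rather
than computed. Passing the cascade on these fixtures therefore
demonstrates that the filters implement their rules exactly (boundaries
included) — it does not measure sensitivity or specificity on real
annotation noise, overlapping CDS calls, or degenerate CRISPR arrays.

## Problem sizes used in tests

Oracle-equivalence checks run the implementation against independent
brute-force re-implementations: 200 random gene layouts (≤ 50 genes) for
operon building, 50 random genomes (2–100 kb, spacers planted) for the
self-targeting scan at `max_mismatch=0`, and 100 random protein pairs
(50–200 aa) for the aligner against a plain-Python affine-gap DP. These
sizes give well over 10³ independently verified decisions per rule while
keeping the suite fast on one CPU.

## Known limitations

- No PAM or seed-region scoring in self-targeting detection.
- Completeness checking does not validate cas gene order, orientation or
  distance to the array.
- The naive ORF caller (ATG-only starts, table-11 stops, no frameshift
  model) is a fixture-grade stand-in for a real gene caller on unannotated
  contigs.
- GFF parsing keeps overlapping CDS annotations; de-duplication is left to
  operon building, where overlaps simply produce negative gaps.
- Taxonomy and habitat are consumed as user-supplied metadata columns; no
  database lookups.
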
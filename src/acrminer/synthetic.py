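"""Deterministic synthetic genomes with planted Acr-Aca loci and decoys.

The generator emits one multi-contig genome in the exact dialects the parsers
read: contig FASTA, GFF3 gene calls, protein FASTA, blast6 Acr hit table,
domtblout HTH table, MGE BED, CRISPR array/system TSV and a truth table.

Every positive locus satisfies all published discovery criteria: an Acr gene
under 200 aa with a planted homology hit far below the 1e-2 cutoff, an
immediately downstream HTH (Aca) gene on the same strand with a gap under
150 bp, an enclosing prophage interval, and a genome-wide complete I-F
CRISPR-Cas system whose array holds a spacer copied to a protospacer on the
locus contig. Each decoy class breaks exactly one of those rules on its own
contig, so a pipeline failure maps one-to-one onto a rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .crispr_selftarget import (
    CasSystem,
    CrisprArray,
    reverse_complement,
    write_crispr_tsv,
)
from .genome_io import (
    Contig,
    DomainHit,
    Gene,
    Genome,
    HomologyHit,
    MgeInterval,
    write_blast6,
    write_domtbl,
    write_fasta,
    write_gff_genes,
    write_mge_bed,
)

DECOY_CLASSES = (
    "long_protein",
    "big_gap",
    "wrong_strand",
    "no_aca",
    "outside_mge",
    "no_selftarget",
    "cross_contig_target",
)

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed layout positions (1-based) on every locus-bearing contig
_OPERON_START = 10001
_ACR_AA = 140
_ACA_AA = 90
_GAP_BP = 40
_MGE_SPAN = (9500, 12500)
_PROTOSPACER_POS = 20001
_LONG_GENE = (30001, 299)  # start, aa
_BG_GENE = (35001, 80)
_MIN_CONTIG = 36000


class FixtureConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 7
    contig_len_bp: int = 40000
    n_positive_loci: int = 3
    decoy_classes: tuple[str, ...] = DECOY_CLASSES
    spacer_len: int = 32
    planted_identity: float = 70.0  # percent identity of planted Acr homologs

    def __post_init__(self) -> None:
        if self.contig_len_bp < _MIN_CONTIG:
            raise FixtureConfigError(
                f"contig_len_bp must be >= {_MIN_CONTIG} for the fixed layout"
            )
        bad = set(self.decoy_classes) - set(DECOY_CLASSES)
        if bad:
            raise FixtureConfigError(f"unknown decoy classes: {sorted(bad)}")
        if not 0 < self.planted_identity <= 100:
            raise FixtureConfigError("planted_identity must be in (0, 100]")


@dataclass
class SyntheticBundle:
    """In-memory fixture plus writers for the on-disk dialects."""

    genome: Genome
    proteins: dict[str, str]
    acr_hits: list[HomologyHit]
    domain_hits: list[DomainHit]
    mge_intervals: list[MgeInterval]
    arrays: list[CrisprArray]
    systems: list[CasSystem]
    truth: pd.DataFrame
    acr_query_proteins: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs_fna": outdir / "genome.fna",
            "gff": outdir / "genome.gff",
            "proteins_faa": outdir / "proteins.faa",
            "acr_hits": outdir / "acr_hits.blast6.tsv",
            "domain_hits": outdir / "hth_hits.domtbl.txt",
            "mge_bed": outdir / "mge.bed",
            "crispr_tsv": outdir / "crispr.tsv",
            "truth": outdir / "truth.csv",
        }
        write_fasta(
            {c.contig_id: c.sequence for c in self.genome.contigs}, paths["contigs_fna"]
        )
        write_gff_genes(self.genome.genes, paths["gff"])
        write_fasta(self.proteins, paths["proteins_faa"])
        write_blast6(self.acr_hits, paths["acr_hits"])
        write_domtbl(self.domain_hits, paths["domain_hits"])
        write_mge_bed(self.mge_intervals, paths["mge_bed"])
        write_crispr_tsv(self.arrays, self.systems, paths["crispr_tsv"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _random_dna(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_NT[rng.integers(0, 4, n)].tobytes())


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return _AA[rng.integers(0, 20, n)].tobytes().decode()


def _mutate_protein(rng: np.random.Generator, seq: str, identity_pct: float) -> str:
    """Substitute positions so ~identity_pct of residues stay identical."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = int(round(len(seq) * (1 - identity_pct / 100.0)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = _AA[_AA != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _cds_span(start: int, aa: int) -> tuple[int, int]:
    """1-based inclusive CDS span for a protein of `aa` residues (+ stop)."""
    return start, start + 3 * (aa + 1) - 1


def generate_synthetic_genome(cfg: FixtureConfig = FixtureConfig()) -> SyntheticBundle:
    """Build the fixture bundle; a fixed seed yields byte-identical files."""
    rng = np.random.default_rng(cfg.seed)
    genome_id = "synthetic_genome"

    locus_specs = [(f"pos{i+1}", "positive") for i in range(cfg.n_positive_loci)]
    locus_specs += [(cls, cls) for cls in sorted(cfg.decoy_classes)]

    contig_ids = [f"ctg_{name}" for name, _ in locus_specs] + ["ctg_arrays", "ctg_dump"]
    sequences = {cid: _random_dna(rng, cfg.contig_len_bp) for cid in contig_ids}

    genes: list[Gene] = []
    proteins: dict[str, str] = {}
    acr_hits: list[HomologyHit] = []
    domain_hits: list[DomainHit] = []
    mge_intervals: list[MgeInterval] = []
    spacers: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    acr_seed = _random_protein(rng, _ACR_AA)

    def add_gene(pid: str, contig: str, start: int, aa: int, strand: str) -> Gene:
        s, e = _cds_span(start, aa)
        g = Gene(
            gene_id=pid, contig_id=contig, start=s, end=e,
            strand=strand, protein_id=pid, protein_length=aa,
        )
        genes.append(g)
        return g

    for name, klass in locus_specs:
        contig = f"ctg_{name}"
        acr_pid, partner_pid = f"{name}_acr", f"{name}_aca"

        # Acr gene: mutated copy of the family seed, planted blast6 hit
        acr = add_gene(acr_pid, contig, _OPERON_START, _ACR_AA, "+")
        proteins[acr_pid] = _mutate_protein(rng, acr_seed, cfg.planted_identity)
        acr_hits.append(
            HomologyHit(
                query_id="AcrIF3", subject_id=acr_pid, pident=cfg.planted_identity,
                aln_len=_ACR_AA, evalue=1e-30, bitscore=250.0,
            )
        )

        # partner (Aca) gene: each decoy class perturbs exactly one rule
        partner_aa = 250 if klass == "long_protein" else _ACA_AA
        gap = 150 if klass == "big_gap" else _GAP_BP
        strand = "-" if klass == "wrong_strand" else "+"
        add_gene(partner_pid, contig, acr.end + gap + 1, partner_aa, strand)
        proteins[partner_pid] = _random_protein(rng, partner_aa)
        if klass != "no_aca":
            domain_hits.append(DomainHit(partner_pid, "HTH_XRE", 1e-6))

        # background genes: one long breaker, one distant short singleton
        for pid_suffix, (start, aa) in (("_long", _LONG_GENE), ("_bg", _BG_GENE)):
            add_gene(name + pid_suffix, contig, start, aa, "+")
            proteins[name + pid_suffix] = _random_protein(rng, aa)

        # MGE context: prophage over the operon, or far away for outside_mge
        if klass == "outside_mge":
            mge_intervals.append(MgeInterval(contig, 500, 1500, "prophage"))
        else:
            mge_intervals.append(MgeInterval(contig, *_MGE_SPAN, "prophage"))

        # self-targeting: spacer copied to a protospacer site
        if klass != "no_selftarget":
            target_contig = "ctg_dump" if klass == "cross_contig_target" else contig
            spacer = _NT[rng.integers(0, 4, cfg.spacer_len)].tobytes().decode()
            spacers.append((f"sp_{name}", spacer))
            pos = _PROTOSPACER_POS if target_contig == contig else 1001 + 100 * len(spacers)
            sequences[target_contig][pos - 1 : pos - 1 + cfg.spacer_len] = spacer.encode()

        truth_rows.append(
            {
                "element": name,
                "contig": contig,
                "class": klass,
                "expect_full_pipeline": klass == "positive",
            }
        )

    # one extra spacer with no genomic target
    spacers.append(("sp_unused", _NT[rng.integers(0, 4, cfg.spacer_len)].tobytes().decode()))

    # CRISPR array written into ctg_arrays, flanked by its repeat sequence
    repeat = _NT[rng.integers(0, 4, 28)].tobytes().decode()
    array_seq = repeat + "".join(seq + repeat for _, seq in spacers)
    array_start = 1001
    sequences["ctg_arrays"][array_start - 1 : array_start - 1 + len(array_seq)] = (
        array_seq.encode()
    )
    arrays = [
        CrisprArray(
            array_id="array1",
            contig_id="ctg_arrays",
            start=array_start,
            end=array_start + len(array_seq) - 1,
            spacers=tuple(spacers),
            repeats=(repeat,),
        )
    ]

    # complete I-F cas gene set on the array contig
    cas_genes = ("cas1", "cas2-3", "cas5f", "cas6f", "cas7f", "cas8f")
    pos = 8001
    for cg in cas_genes:
        g = add_gene(cg, "ctg_arrays", pos, 300, "+")
        proteins[cg] = _random_protein(rng, 300)
        pos = g.end + 201
    systems = [
        CasSystem(
            system_id="sys1", subtype="I-F", contig_id="ctg_arrays",
            cas_gene_ids=frozenset(cas_genes),
        )
    ]

    contigs = [
        Contig(cid, cfg.contig_len_bp, sequences[cid].decode()) for cid in contig_ids
    ]
    genome = Genome(genome_id=genome_id, contigs=contigs, genes=genes)
    return SyntheticBundle(
        genome=genome,
        proteins=proteins,
        acr_hits=acr_hits,
        domain_hits=domain_hits,
        mge_intervals=mge_intervals,
        arrays=arrays,
        systems=systems,
        truth=pd.DataFrame(truth_rows),
        acr_query_proteins={"AcrIF3": acr_seed},
    )


def plant_self_target(
    bundle: SyntheticBundle,
    locus_contig: str,
    same_contig: bool = True,
    revcomp: bool = False,
    seed: int = 0,
) -> SyntheticBundle:
    """Copy the first array spacer to a fresh protospacer site.

    The site lands on ``locus_contig`` (``same_contig=True``) or on the dump
    contig otherwise, always outside every array interval; the copy may be
    reverse-complemented.
    """
    if not bundle.arrays or not bundle.arrays[0].spacers:
        raise ValueError("bundle has no array with spacers")
    rng = np.random.default_rng(seed)
    spacer = bundle.arrays[0].spacers[0][1]
    insert = reverse_complement(spacer) if revcomp else spacer
    target = locus_contig if same_contig else "ctg_dump"
    contigs = {c.contig_id: c for c in bundle.genome.contigs}
    if target not in contigs:
        raise ValueError(f"no contig {target!r} in bundle")
    seq = bytearray(contigs[target].sequence.encode())
    forbidden = [
        (a.start, a.end) for a in bundle.arrays if a.contig_id == target
    ]
    gene_spans = [
        (g.start, g.end) for g in bundle.genome.genes if g.contig_id == target
    ]
    for _ in range(200):
        pos = int(rng.integers(1, len(seq) - len(insert)))
        span = (pos, pos + len(insert) - 1)
        clashes = any(span[0] <= e and span[1] >= s for s, e in forbidden + gene_spans)
        if not clashes:
            seq[pos - 1 : pos - 1 + len(insert)] = insert.encode()
            contigs[target] = Contig(target, contigs[target].length, seq.decode())
            bundle.genome.contigs = [contigs[c.contig_id] for c in bundle.genome.contigs]
            return bundle
    raise ValueError(f"no free insertion site found on {target}")
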
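"""Operon building and Acr-Aca candidate locus calling.

An operon here is a maximal run of same-strand genes on one contig in which
every protein is shorter than 200 aa and every intergenic gap is below 150 bp.
Genes at or above the length cutoff do not merely drop out of an operon —
they break the run, since the rule is a property of the whole gene run.

Guilt-by-association then nominates Aca candidates: short HTH proteins in the
same operon as an Acr homolog or within a few flanking genes of its operon.
A candidate locus is an operon that carries at least one Aca homolog gene.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .genome_io import Gene
from .search import AcrHomologCall

#: Ordered names of the four pipeline filters a locus can pass.
FILTER_ORDER = ("homology_gba", "aca_locus", "mge", "self_target")


@dataclass(frozen=True)
class LocusThresholds:
    max_protein_len: int = 200  # exclusive, aa
    max_intergenic_gap: int = 150  # exclusive, bp
    gba_flank_genes: int = 3
    min_locus_genes: int = 2

    def __post_init__(self) -> None:
        for name in ("max_protein_len", "max_intergenic_gap", "gba_flank_genes", "min_locus_genes"):
            if getattr(self, name) <= 0 and name != "gba_flank_genes":
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Operon:
    """A maximal same-strand run of short genes with short intergenic gaps."""

    contig_id: str
    strand: str
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("operon must contain at least one gene")
        if any(g.contig_id != self.contig_id or g.strand != self.strand for g in self.genes):
            raise ValueError("all operon genes must share contig and strand")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError("operon genes must be sorted by start")

    @property
    def start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(g.protein_id for g in self.genes)


@dataclass
class CandidateLocus:
    """An operon annotated with Acr/Aca evidence and per-filter provenance."""

    locus_id: str
    operon: Operon
    genome_id: str
    aca_protein_ids: frozenset[str] = frozenset()
    acr_calls: tuple[AcrHomologCall, ...] = ()
    filters_passed: tuple[str, ...] = ()
    supporting_mge: tuple = ()
    supporting_events: tuple[str, ...] = ()

    @property
    def contig_id(self) -> str:
        return self.operon.contig_id

    @property
    def start(self) -> int:
        return self.operon.start

    @property
    def end(self) -> int:
        return self.operon.end

    @property
    def has_acr(self) -> bool:
        return bool(self.acr_calls)

    def with_filter(self, name: str) -> "CandidateLocus":
        if name not in FILTER_ORDER:
            raise ValueError(f"unknown filter {name!r}")
        if name in self.filters_passed:
            return self
        passed = tuple(f for f in FILTER_ORDER if f in (*self.filters_passed, name))
        return replace(self, filters_passed=passed)


def intergenic_gap(a: Gene, b: Gene) -> int:
    """Gap in bp between two genes sorted by start: b.start - a.end - 1.

    Adjacent genes give 0; overlapping genes give a negative gap, which still
    satisfies the '< 150 bp' rule.
    """
    return b.start - a.end - 1


def build_operons(
    genes: Sequence[Gene], t: LocusThresholds = LocusThresholds()
) -> list[Operon]:
    """Partition short genes into maximal operons.

    A run breaks at a contig change, a strand change, an intergenic gap of
    ``max_intergenic_gap`` or more, or a long (>= ``max_protein_len`` aa)
    protein, which acts as a breaker rather than a skipped member.
    """
    order = [(g.contig_id, g.start) for g in genes]
    if order != sorted(order):
        raise ValueError("genes must be sorted by (contig_id, start)")
    operons: list[Operon] = []
    run: list[Gene] = []

    def flush() -> None:
        nonlocal run
        if run:
            operons.append(Operon(run[0].contig_id, run[0].strand, tuple(run)))
            run = []

    for g in genes:
        if g.protein_length >= t.max_protein_len:
            flush()
            continue
        if run:
            prev = run[-1]
            if (
                g.contig_id != prev.contig_id
                or g.strand != prev.strand
                or intergenic_gap(prev, g) >= t.max_intergenic_gap
            ):
                flush()
        run.append(g)
    flush()
    return operons


def discover_aca_by_gba(
    acr_calls: Iterable[AcrHomologCall],
    operons: Sequence[Operon],
    genes: Mapping[str, Gene],
    hth: Callable[[str], bool],
    t: LocusThresholds = LocusThresholds(),
) -> set[str]:
    """Find Aca candidates: short HTH proteins in the gene neighborhood of
    Acr homologs (same operon, or within ``gba_flank_genes`` genes of the
    Acr's operon on the same contig, strand-agnostic for the flank).

    Acr-homolog proteins themselves are excluded unless they independently
    carry an HTH domain (the AcrIIA1 case, which is both Acr and Aca).
    """
    acr_ids = {c.protein_id for c in acr_calls}
    if not acr_ids:
        return set()
    # genes sorted per contig for flank lookups
    by_contig: dict[str, list[Gene]] = {}
    for g in sorted(genes.values(), key=lambda g: (g.contig_id, g.start)):
        by_contig.setdefault(g.contig_id, []).append(g)

    neighborhood: set[str] = set()
    for op in operons:
        if not acr_ids & set(op.protein_ids):
            continue
        neighborhood.update(op.protein_ids)
        contig_genes = by_contig.get(op.contig_id, [])
        idx = [i for i, g in enumerate(contig_genes) if g.protein_id in op.protein_ids]
        if idx:
            lo = max(min(idx) - t.gba_flank_genes, 0)
            hi = min(max(idx) + t.gba_flank_genes, len(contig_genes) - 1)
            neighborhood.update(g.protein_id for g in contig_genes[lo : hi + 1])

    out: set[str] = set()
    for pid in neighborhood:
        g = genes.get(pid)
        if g is None or g.protein_length >= t.max_protein_len:
            continue
        if not hth(pid):
            # excludes plain Acr homologs too: an Acr counts as Aca candidate
            # only when it independently carries an HTH domain (AcrIIA1 case)
            continue
        out.add(pid)
    return out


def locus_id_for(operon: Operon, genome_id: str) -> str:
    """Stable locus id from genome, contig, span and strand."""
    key = f"{genome_id}:{operon.contig_id}:{operon.start}-{operon.end}:{operon.strand}"
    digest = hashlib.sha1(key.encode()).hexdigest()[:8]
    return f"locus_{digest}"


def call_candidate_loci(
    operons: Sequence[Operon],
    aca_homolog_ids: set[str],
    acr_calls: Iterable[AcrHomologCall],
    t: LocusThresholds = LocusThresholds(),
    genome_id: str = "genome",
) -> list[CandidateLocus]:
    """Emit one candidate locus per operon that contains at least one Aca
    homolog gene and at least ``min_locus_genes`` genes; Acr calls are
    attached when the operon also holds an Acr-homolog gene."""
    calls_by_pid = {c.protein_id: c for c in acr_calls}
    loci: list[CandidateLocus] = []
    for op in operons:
        pids = set(op.protein_ids)
        acas = frozenset(pids & aca_homolog_ids)
        if not acas or len(op.genes) < t.min_locus_genes:
            continue
        attached = tuple(
            calls_by_pid[p] for p in op.protein_ids if p in calls_by_pid
        )
        filters = ("homology_gba", "aca_locus") if attached else ("aca_locus",)
        loci.append(
            CandidateLocus(
                locus_id=locus_id_for(op, genome_id),
                operon=op,
                genome_id=genome_id,
                aca_protein_ids=acas,
                acr_calls=attached,
                filters_passed=filters,
            )
        )
    return loci


def loci_to_table(loci: Sequence[CandidateLocus]):
    """Locus collection as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for lc in loci:
        rows.append(
            {
                "genome_id": lc.genome_id,
                "locus_id": lc.locus_id,
                "contig": lc.contig_id,
                "start": lc.start,
                "end": lc.end,
                "strand": lc.operon.strand,
                "gene_ids": ",".join(g.gene_id for g in lc.operon.genes),
                "protein_ids": ",".join(lc.operon.protein_ids),
                "aca_ids": ",".join(sorted(lc.aca_protein_ids)),
                "acr_families": ",".join(c.family for c in lc.acr_calls),
                "filters_passed": ",".join(lc.filters_passed),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "locus_id", "contig", "start", "end", "strand",
            "gene_ids", "protein_ids", "aca_ids", "acr_families", "filters_passed",
        ],
    )


def loci_to_bed(loci: Sequence[CandidateLocus], path) -> None:
    """Write loci as BED (0-based half-open) for genome browsers."""
    with open(path, "w") as fh:
        for lc in sorted(loci, key=lambda l: (l.contig_id, l.start)):
            fh.write(f"{lc.contig_id}\t{lc.start - 1}\t{lc.end}\t{lc.locus_id}\t0\t{lc.operon.strand}\n")
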
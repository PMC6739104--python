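"""Readers, writers and core data model for the formats the pipeline touches.

Internally every coordinate is 1-based inclusive (GFF3 convention). BED-like
mobile-genetic-element input is 0-based half-open on disk and converted here,
at the parser boundary, so no other module ever sees a 0-based number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

Strand = Literal["+", "-"]

NUCLEOTIDE_CHARS = set("ACGTN")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

STOP_CODONS = {"TAA", "TAG", "TGA"}  # translation table 11


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a contract (duplicate id, bad strand ...)."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 1-based inclusive coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: Strand
    protein_id: str
    protein_length: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.protein_length < 1:
            raise ValidationError(f"gene {self.gene_id}: protein_length < 1")


@dataclass(frozen=True)
class Contig:
    contig_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"contig {self.contig_id}: length < 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"contig {self.contig_id}: sequence length {len(self.sequence)} != {self.length}"
            )


@dataclass
class Genome:
    genome_id: str
    contigs: list[Contig]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {c.contig_id: c for c in self.contigs}
        for g in self.genes:
            c = known.get(g.contig_id)
            if c is None:
                raise ValidationError(f"gene {g.gene_id} on unknown contig {g.contig_id}")
            if g.end > c.length:
                raise ValidationError(
                    f"gene {g.gene_id} extends past contig {g.contig_id} ({g.end} > {c.length})"
                )
        self.genes.sort(key=lambda g: (g.contig_id, g.start))

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def gene_index(self) -> dict[str, Gene]:
        """Map protein_id -> Gene."""
        return {g.protein_id: g for g in self.genes}


MGE_KINDS = ("prophage", "genomic_island")


@dataclass(frozen=True)
class MgeInterval:
    """A prophage or genomic-island interval, 1-based inclusive."""

    contig_id: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"MGE interval on {self.contig_id}: start > end")
        if self.kind not in MGE_KINDS:
            raise ValidationError(f"MGE kind {self.kind!r} not in {MGE_KINDS}")


@dataclass(frozen=True)
class HomologyHit:
    """One row of a BLAST/DIAMOND tabular (outfmt 6) protein search."""

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError("evalue < 0")
        if not 0 <= self.pident <= 100:
            raise ValidationError("pident outside [0, 100]")


@dataclass(frozen=True)
class DomainHit:
    """One domain row of an HMMER3 domtblout table."""

    protein_id: str
    domain_name: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError("evalue < 0")


# ---------------------------------------------------------------------------
# GFF3


def read_gff_genes(
    path: str | Path, protein_lengths: Mapping[str, int] | None = None
) -> list[Gene]:
    """Read CDS features of a GFF3 file into Gene records.

    ``protein_lengths`` (protein_id -> aa length) takes precedence over the
    span-derived estimate ``(end - start + 1) // 3 - 1``; the short-protein
    criterion downstream concerns the protein, not the CDS span.
    """
    protein_lengths = protein_lengths or {}
    genes: list[Gene] = []
    seen: set[tuple[str, int, int, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in ("CDS", "gene"):
                continue
            if ftype == "gene":
                # CDS rows are authoritative; plain gene rows are skipped to
                # avoid double counting when both are present.
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attr_map = _parse_gff_attributes(attrs, path, lineno)
            pid = attr_map.get("protein_id") or attr_map.get("ID")
            if pid is None:
                raise ParseError(f"{path}:{lineno}: CDS lacks ID/protein_id attribute")
            gid = attr_map.get("ID", pid)
            plen = protein_lengths.get(pid, max((end - start + 1) // 3 - 1, 1))
            key = (seqid, start, end, strand)
            if key in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate CDS at {key}")
            seen.add(key)
            genes.append(
                Gene(
                    gene_id=gid,
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,  # type: ignore[arg-type]
                    protein_id=pid,
                    protein_length=plen,
                )
            )
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes


def _parse_gff_attributes(attrs: str, path: str | Path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ParseError(f"{path}:{lineno}: malformed attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def write_gff_genes(genes: Sequence[Gene], path: str | Path) -> None:
    """Write genes as GFF3 CDS features (round-trips through read_gff_genes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            attrs = f"ID={g.gene_id};protein_id={g.protein_id}"
            fh.write(
                f"{g.contig_id}\tacrminer\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "protein") -> dict[str, str]:
    """Read FASTA into {id: uppercased sequence}; ids truncate at whitespace.

    ``alphabet`` is ``"nucleotide"`` or ``"protein"``; characters outside the
    alphabet or duplicate ids raise :class:`ValidationError`.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = NUCLEOTIDE_CHARS if alphabet == "nucleotide" else PROTEIN_CHARS
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} has illegal {alphabet} characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular hit files


def read_tabular_hits(
    path: str | Path, dialect: str
) -> list[HomologyHit] | list[DomainHit]:
    """Read a blast6 (12-column outfmt 6) or HMMER3 domtblout hit table."""
    if dialect == "blast6":
        return _read_blast6(path)
    if dialect == "domtbl":
        return _read_domtbl(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_blast6(path: str | Path) -> list[HomologyHit]:
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        aln_len=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _read_domtbl(path: str | Path) -> list[DomainHit]:
    # HMMER3 domtblout: whitespace-delimited, >= 23 columns; col 1 = target
    # (protein), col 4 = query (domain) name, col 13 = this-domain i-Evalue.
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 23 whitespace columns, got {len(fields)}"
                )
            try:
                hits.append(
                    DomainHit(
                        protein_id=fields[0],
                        domain_name=fields[3],
                        evalue=float(fields[12]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast6(hits: Sequence[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.1f}\t{h.aln_len}\t0\t0\t"
                f"1\t{h.aln_len}\t1\t{h.aln_len}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def write_domtbl(hits: Sequence[DomainHit], path: str | Path) -> None:
    """Write a minimal HMMER3-layout domain table (23 columns, placeholders)."""
    with open(path, "w") as fh:
        fh.write("# target name" + " -" * 22 + "\n")
        for h in hits:
            fields = [h.protein_id, "-", "100", h.domain_name, "-", "50"] + ["0"] * 6
            fields += [f"{h.evalue:.3g}"] + ["0"] * 10
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED (MGE intervals)


def read_mge_bed(path: str | Path) -> list[MgeInterval]:
    """Read MGE intervals from BED (0-based half-open, cols contig/start/end/kind).

    Coordinates are converted to 1-based inclusive here, at the boundary.
    """
    out: list[MgeInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            out.append(MgeInterval(fields[0], start0 + 1, end0, fields[3]))
    return out


def write_mge_bed(intervals: Sequence[MgeInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig_id}\t{iv.start - 1}\t{iv.end}\t{iv.kind}\n")


# ---------------------------------------------------------------------------
# Naive ORF calling (stand-in gene caller for unannotated contigs)


def call_orfs_naive(contig: Contig, min_len: int = 30, table: int = 11) -> list[Gene]:
    """Call maximal ATG->stop ORFs of >= min_len aa in all six frames.

    Reverse-frame ORFs are reported with strand '-' and forward-strand
    coordinates. This is a deliberately simple stand-in gene caller for test
    fixtures; no frameshift model, ATG-only starts, table-11 stops.
    """
    if contig.sequence is None:
        raise ValueError(f"contig {contig.contig_id} has no sequence")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = contig.sequence.upper()
    n = len(seq)
    genes: list[Gene] = []
    counter = 0
    for strand in ("+", "-"):
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            i = frame
            while i + 3 <= n:
                codon = s[i : i + 3]
                if codon == "ATG":
                    # scan for in-frame stop
                    j = i + 3
                    while j + 3 <= n and s[j : j + 3] not in STOP_CODONS:
                        j += 3
                    if j + 3 <= n:  # found a stop; ORF spans i .. j+2
                        aa_len = (j - i) // 3
                        if aa_len >= min_len:
                            counter += 1
                            if strand == "+":
                                start, end = i + 1, j + 3
                            else:
                                start, end = n - (j + 3) + 1, n - i
                            genes.append(
                                Gene(
                                    gene_id=f"{contig.contig_id}_orf{counter}",
                                    contig_id=contig.contig_id,
                                    start=start,
                                    end=end,
                                    strand=strand,  # type: ignore[arg-type]
                                    protein_id=f"{contig.contig_id}_orf{counter}",
                                    protein_length=aa_len,
                                )
                            )
                        i = j + 3  # maximal ORFs: skip past this stop
                        continue
                i += 3
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes
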
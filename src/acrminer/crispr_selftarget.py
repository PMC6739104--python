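"""CRISPR arrays, Cas-system completeness and self-targeting spacers.

A genome qualifies for the last pipeline filter when it carries a complete
CRISPR-Cas system — a full subtype-defining cas gene set (packaged table)
plus at least one array with a spacer — and at least one spacer whose
protospacer (target) lies outside every array. Candidate loci are then kept
only when a protospacer sits on the same contig as the locus.

The detector is PAM-agnostic and allows a configurable number of substitution
mismatches (default 2). Externally produced self-targeting tables can be
supplied verbatim instead of running the built-in scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._data import cas_required_genes
from .genome_io import Contig, ParseError, ValidationError
from .loci import CandidateLocus

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CrisprArray:
    array_id: str
    contig_id: str
    start: int
    end: int
    spacers: tuple[tuple[str, str], ...]  # (spacer_id, sequence)
    repeats: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"array {self.array_id}: start > end")
        for sid, seq in self.spacers:
            if set(seq) - set("ACGTN"):
                raise ValidationError(f"spacer {sid}: non-ACGTN characters")


@dataclass(frozen=True)
class CasSystem:
    system_id: str
    subtype: str
    contig_id: str
    cas_gene_ids: frozenset[str]
    complete: bool = field(init=False)

    def __post_init__(self) -> None:
        required = cas_required_genes()
        if self.subtype not in required:
            raise ValidationError(
                f"unknown CRISPR-Cas subtype {self.subtype!r}; accepted: "
                f"{sorted(required)}"
            )
        object.__setattr__(self, "complete", required[self.subtype] <= self.cas_gene_ids)


@dataclass(frozen=True)
class SelfTargetEvent:
    spacer_id: str
    source_array: str
    target_contig: str
    target_start: int
    target_end: int
    target_strand: str
    mismatches: int
    subtype: str

    @property
    def event_id(self) -> str:
        return (
            f"{self.spacer_id}@{self.target_contig}:"
            f"{self.target_start}-{self.target_end}{self.target_strand}"
        )


def genome_has_complete_system(
    systems: Iterable[CasSystem], arrays: Iterable[CrisprArray]
) -> dict[str, bool]:
    """Per-subtype completeness: a complete cas gene set for the subtype plus
    at least one array with at least one spacer anywhere in the genome."""
    has_array = any(len(a.spacers) >= 1 for a in arrays)
    out: dict[str, bool] = {}
    for s in systems:
        out[s.subtype] = out.get(s.subtype, False) or (s.complete and has_array)
    return out


def _attribute_subtype(array: CrisprArray, systems: Sequence[CasSystem]) -> str | None:
    """Subtype of the complete system governing an array: prefer a complete
    system on the array's contig, else any complete system in the genome;
    ties break lexicographically by system id."""
    complete = [s for s in systems if s.complete]
    if not complete:
        return None
    same = sorted((s for s in complete if s.contig_id == array.contig_id),
                  key=lambda s: s.system_id)
    if same:
        return same[0].subtype
    return min(complete, key=lambda s: s.system_id).subtype


def _mismatch_positions(contig_arr: np.ndarray, spacer: str) -> np.ndarray:
    """Mismatch count of `spacer` against every window of the contig."""
    k = len(spacer)
    n = contig_arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    sp = np.frombuffer(spacer.encode(), dtype=np.uint8)
    counts = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        counts += contig_arr[j : n - k + 1 + j] != sp[j]
    return counts


def find_self_targets(
    arrays: Sequence[CrisprArray],
    contigs: Sequence[Contig],
    systems: Sequence[CasSystem],
    max_mismatch: int = 2,
) -> list[SelfTargetEvent]:
    """Locate protospacers: occurrences of each spacer (either strand, up to
    ``max_mismatch`` substitutions) in any contig, outside all array
    intervals. Spacers containing N are skipped with a warning.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    array_spans: dict[str, list[tuple[int, int]]] = {}
    for a in arrays:
        array_spans.setdefault(a.contig_id, []).append((a.start, a.end))
    encoded = {
        c.contig_id: np.frombuffer(c.sequence.upper().encode(), dtype=np.uint8)
        for c in contigs
        if c.sequence is not None
    }
    events: list[SelfTargetEvent] = []
    for a in arrays:
        subtype = _attribute_subtype(a, systems)
        for sid, spacer in a.spacers:
            spacer = spacer.upper()
            if "N" in spacer:
                warnings.warn(f"spacer {sid} contains N; skipped", stacklevel=2)
                continue
            k = len(spacer)
            for contig_id, arr in encoded.items():
                for strand, probe in (("+", spacer), ("-", reverse_complement(spacer))):
                    counts = _mismatch_positions(arr, probe)
                    for pos0 in np.nonzero(counts <= max_mismatch)[0]:
                        start, end = int(pos0) + 1, int(pos0) + k
                        if _overlaps_any(array_spans.get(contig_id, ()), start, end):
                            continue
                        events.append(
                            SelfTargetEvent(
                                spacer_id=sid,
                                source_array=a.array_id,
                                target_contig=contig_id,
                                target_start=start,
                                target_end=end,
                                target_strand=strand,
                                mismatches=int(counts[pos0]),
                                subtype=subtype or "unknown",
                            )
                        )
    for ev in events:  # output invariant: targets never overlap arrays
        assert not _overlaps_any(
            array_spans.get(ev.target_contig, ()), ev.target_start, ev.target_end
        )
    events.sort(key=lambda e: (e.target_contig, e.target_start, e.spacer_id, e.target_strand))
    return events


def _overlaps_any(spans: Iterable[tuple[int, int]], start: int, end: int) -> bool:
    return any(start <= e and end >= s for s, e in spans)


def colocalize_loci(
    loci: Sequence[CandidateLocus],
    events: Sequence[SelfTargetEvent],
    completeness: Mapping[str, bool],
) -> list[CandidateLocus]:
    """Keep loci whose genome has a complete self-targeting system and whose
    contig carries at least one protospacer; record supporting event ids."""
    if not any(completeness.values()):
        return []
    by_contig: dict[str, list[SelfTargetEvent]] = {}
    for ev in events:
        by_contig.setdefault(ev.target_contig, []).append(ev)
    kept: list[CandidateLocus] = []
    for lc in loci:
        support = by_contig.get(lc.contig_id, [])
        if support:
            out = lc.with_filter("self_target")
            out.supporting_events = tuple(ev.event_id for ev in support)
            kept.append(out)
    return kept


# ---------------------------------------------------------------------------
# TSV dialect: array and system rows in one file
#
#   array   <array_id> <contig> <start> <end> <spacer_id> <spacer_seq>
#   system  <system_id> <subtype> <contig> <comma-joined cas gene names>
#
# (tab-separated; one array row per spacer; '#' comments allowed)


def read_crispr_tsv(path: str | Path) -> tuple[list[CrisprArray], list[CasSystem]]:
    array_rows: dict[str, dict] = {}
    systems: list[CasSystem] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "array":
                if len(fields) != 7:
                    raise ParseError(f"{path}:{lineno}: array row needs 7 columns")
                _, aid, contig, start, end, sid, sseq = fields
                rec = array_rows.setdefault(
                    aid, {"contig": contig, "start": int(start), "end": int(end), "spacers": []}
                )
                rec["spacers"].append((sid, sseq.upper()))
            elif kind == "system":
                if len(fields) != 5:
                    raise ParseError(f"{path}:{lineno}: system row needs 5 columns")
                _, sysid, subtype, contig, genes = fields
                systems.append(
                    CasSystem(
                        system_id=sysid,
                        subtype=subtype,
                        contig_id=contig,
                        cas_gene_ids=frozenset(g.strip() for g in genes.split(",")),
                    )
                )
            else:
                raise ParseError(f"{path}:{lineno}: unknown record kind {kind!r}")
    arrays = [
        CrisprArray(
            array_id=aid,
            contig_id=rec["contig"],
            start=rec["start"],
            end=rec["end"],
            spacers=tuple(rec["spacers"]),
        )
        for aid, rec in array_rows.items()
    ]
    return arrays, systems


def write_crispr_tsv(
    arrays: Sequence[CrisprArray], systems: Sequence[CasSystem], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# array rows: array_id contig start end spacer_id spacer_seq\n")
        for a in arrays:
            for sid, seq in a.spacers:
                fh.write(f"array\t{a.array_id}\t{a.contig_id}\t{a.start}\t{a.end}\t{sid}\t{seq}\n")
        for s in systems:
            genes = ",".join(sorted(s.cas_gene_ids))
            fh.write(f"system\t{s.system_id}\t{s.subtype}\t{s.contig_id}\t{genes}\n")


def read_selftarget_table(path: str | Path) -> list[SelfTargetEvent]:
    """Read an externally produced self-targeting table, used verbatim.

    Tab-separated columns: genome, contig, spacer_id, target_start,
    target_end, strand, subtype. The genome column is carried for provenance
    but not interpreted here.
    """
    events: list[SelfTargetEvent] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            genome, contig, sid, start, end, strand, subtype = fields
            events.append(
                SelfTargetEvent(
                    spacer_id=sid,
                    source_array=f"{genome}:external",
                    target_contig=contig,
                    target_start=int(start),
                    target_end=int(end),
                    target_strand=strand,
                    mismatches=0,
                    subtype=subtype,
                )
            )
    return events
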
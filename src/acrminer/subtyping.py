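"""Subtype assignment, conflict detection and toxin-antitoxin annotation.

Every locus that survives the self-targeting filter has two independent
subtype assignments: from the Acr family names of its homologs (the family
name encodes the inhibited subtype) and from the subtype(s) of the
self-targeting events on its contig. A conflict is a locus whose two subtype
sets are disjoint; overlapping sets — including hybrid-family unions — count
as agreement. Conflicts repeated across near-identical strain genomes are
collapsed to nonredundant groups keyed on (families, self-target subtypes,
Acr protein ids).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .crispr_selftarget import SelfTargetEvent
from .genome_io import HomologyHit
from .loci import CandidateLocus


@dataclass(frozen=True)
class SubtypeCall:
    locus_id: str
    method: str  # "homology" | "self_target"
    subtypes: frozenset[str]
    provenance: tuple[str, ...] = ()  # family names or event ids

    def __post_init__(self) -> None:
        if self.method not in ("homology", "self_target"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.subtypes:
            raise ValueError("subtypes must be nonempty")


@dataclass(frozen=True)
class ConflictRecord:
    locus_id: str
    homology_families: frozenset[str]
    homology_subtypes: frozenset[str]
    selftarget_subtypes: frozenset[str]
    acr_protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.homology_subtypes & self.selftarget_subtypes:
            raise ValueError("overlapping subtype sets are not a conflict")

    @property
    def group_key(self) -> tuple:
        return (
            tuple(sorted(self.homology_families)),
            tuple(sorted(self.selftarget_subtypes)),
            tuple(sorted(self.acr_protein_ids)),
        )


@dataclass(frozen=True)
class TaPairCall:
    locus_id: str
    toxin_protein: str | None
    antitoxin_protein: str | None
    paired: bool
    canonical_order: bool

    def __post_init__(self) -> None:
        if self.paired:
            if self.toxin_protein is None or self.antitoxin_protein is None:
                raise ValueError("paired call requires both proteins")
            if self.toxin_protein == self.antitoxin_protein:
                raise ValueError("toxin and antitoxin must be distinct proteins")


def assign_subtypes(
    locus: CandidateLocus, events: Sequence[SelfTargetEvent]
) -> tuple[SubtypeCall | None, SubtypeCall | None]:
    """Build the (homology, self_target) subtype call pair for a locus.

    The homology call is the union of subtypes encoded by the locus' Acr
    family names (None when the locus has no Acr homolog); the self-target
    call collects the subtypes of events on the locus contig (None when the
    locus did not pass the self-targeting filter).
    """
    homology = None
    if locus.acr_calls:
        subtypes = frozenset().union(*(c.subtypes for c in locus.acr_calls))
        homology = SubtypeCall(
            locus_id=locus.locus_id,
            method="homology",
            subtypes=subtypes,
            provenance=tuple(sorted({c.family for c in locus.acr_calls})),
        )
    selftarget = None
    if "self_target" in locus.filters_passed:
        onto_contig = [e for e in events if e.target_contig == locus.contig_id]
        if onto_contig:
            selftarget = SubtypeCall(
                locus_id=locus.locus_id,
                method="self_target",
                subtypes=frozenset(e.subtype for e in onto_contig),
                provenance=tuple(e.event_id for e in onto_contig),
            )
    return homology, selftarget


def find_conflicts(
    call_pairs: Iterable[tuple[SubtypeCall, SubtypeCall]],
    acr_ids: Mapping[str, frozenset[str]],
) -> tuple[list[ConflictRecord], list[ConflictRecord]]:
    """Detect conflicting subtype assignments and collapse them to a
    nonredundant set.

    A pair conflicts iff the two subtype sets are disjoint. The nonredundant
    collection keeps one representative per identical
    (homology families, self-target subtypes, Acr protein ids) group.
    """
    conflicts: list[ConflictRecord] = []
    for homology, selftarget in call_pairs:
        if homology is None or selftarget is None:
            raise ValueError("both calls must be present for conflict analysis")
        if homology.subtypes & selftarget.subtypes:
            continue
        conflicts.append(
            ConflictRecord(
                locus_id=homology.locus_id,
                homology_families=frozenset(homology.provenance),
                homology_subtypes=homology.subtypes,
                selftarget_subtypes=selftarget.subtypes,
                acr_protein_ids=acr_ids.get(homology.locus_id, frozenset()),
            )
        )
    seen: dict[tuple, ConflictRecord] = {}
    for rec in conflicts:
        seen.setdefault(rec.group_key, rec)
    return conflicts, list(seen.values())


def conflict_report(conflicts: Sequence[ConflictRecord]) -> pd.DataFrame:
    """Aggregate conflicts as a table of nonredundant groups with counts
    (count, homology families, self-target subtype, unique Acr homolog ids)."""
    rows: dict[tuple, dict] = {}
    for rec in conflicts:
        row = rows.setdefault(
            rec.group_key,
            {
                "n_loci": 0,
                "homology_families": ";".join(sorted(rec.homology_families)),
                "selftarget_subtype": ";".join(sorted(rec.selftarget_subtypes)),
                "acr_ids": set(),
            },
        )
        row["n_loci"] += 1
        row["acr_ids"] |= rec.acr_protein_ids
    out = pd.DataFrame(
        [
            {
                "n_loci": r["n_loci"],
                "homology_families": r["homology_families"],
                "selftarget_subtype": r["selftarget_subtype"],
                "n_unique_acr_ids": len(r["acr_ids"]),
            }
            for r in rows.values()
        ],
        columns=["n_loci", "homology_families", "selftarget_subtype", "n_unique_acr_ids"],
    )
    return out.sort_values("n_loci", ascending=False, ignore_index=True)


def conflict_calls_from_groups(
    groups: pd.DataFrame,
) -> tuple[list[tuple[SubtypeCall, SubtypeCall]], dict[str, frozenset[str]]]:
    """Expand a nonredundant conflict-group table into per-locus call pairs.

    Input columns: ``n_loci``, ``homology_families`` (';'-joined),
    ``selftarget_subtype``, ``n_unique_acr_ids``. Each group becomes
    ``n_loci`` duplicate loci sharing one Acr protein id per unique id, the
    way near-identical strain genomes replicate a locus. The expansion is
    the inverse of :func:`conflict_report`.
    """
    from .search import family_to_subtypes

    pairs: list[tuple[SubtypeCall, SubtypeCall]] = []
    acr_ids: dict[str, frozenset[str]] = {}
    for gi, row in groups.iterrows():
        families = tuple(sorted(str(row["homology_families"]).split(";")))
        homology_subtypes = frozenset().union(
            *(family_to_subtypes(f) for f in families)
        )
        st_subtypes = frozenset(str(row["selftarget_subtype"]).split(";"))
        ids = frozenset(
            f"group{gi}_acr{k}" for k in range(int(row["n_unique_acr_ids"]))
        )
        for li in range(int(row["n_loci"])):
            locus_id = f"group{gi}_locus{li}"
            pairs.append(
                (
                    SubtypeCall(locus_id, "homology", homology_subtypes, families),
                    SubtypeCall(locus_id, "self_target", st_subtypes),
                )
            )
            acr_ids[locus_id] = ids
    return pairs, acr_ids


def check_ta_pairs(
    locus: CandidateLocus,
    toxin_hits: Iterable[HomologyHit],
    antitoxin_hits: Iterable[HomologyHit],
    evalue_max: float = 1e-3,
) -> TaPairCall:
    """Annotate a locus as a putative type-II toxin-antitoxin pair.

    ``paired`` requires distinct locus genes carrying a toxin hit and an
    antitoxin hit (each with E-value below ``evalue_max``). ``canonical_order``
    is the usual layout for these operons: the antitoxin (the HTH protein,
    here the Aca candidate) downstream of the toxin in transcription
    direction, i.e. on the 3' side along the operon strand.
    """
    order = list(locus.operon.protein_ids)
    if locus.operon.strand == "-":
        order.reverse()  # transcription order
    pids = set(order)
    toxin_pids = {
        h.subject_id for h in toxin_hits if h.subject_id in pids and h.evalue < evalue_max
    }
    anti_pids = {
        h.subject_id for h in antitoxin_hits if h.subject_id in pids and h.evalue < evalue_max
    }
    # prefer a pair with distinct members; earliest toxin, then an antitoxin
    for tox in sorted(toxin_pids, key=order.index):
        for anti in sorted(anti_pids - {tox}, key=order.index):
            return TaPairCall(
                locus_id=locus.locus_id,
                toxin_protein=tox,
                antitoxin_protein=anti,
                paired=True,
                canonical_order=order.index(anti) > order.index(tox),
            )
    return TaPairCall(
        locus_id=locus.locus_id,
        toxin_protein=next(iter(sorted(toxin_pids, key=order.index)), None),
        antitoxin_protein=next(iter(sorted(anti_pids, key=order.index)), None),
        paired=False,
        canonical_order=False,
    )
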
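import pandas as pd
import pytest

from acrminer import data
from acrminer.crispr_selftarget import SelfTargetEvent
from acrminer.genome_io import Gene, HomologyHit
from acrminer.loci import CandidateLocus, Operon, locus_id_for
from acrminer.search import AcrHomologCall, family_to_subtypes
from acrminer.subtyping import (
    ConflictRecord,
    SubtypeCall,
    check_ta_pairs,
    conflict_calls_from_groups,
    conflict_report,
    find_conflicts,
    assign_subtypes,
)


def _locus(families=("AcrIF3",), strand="+", contig="c1", passed_selftarget=True):
    genes, pos = [], 1000
    pids = [f"acr{i}" for i in range(len(families))] + ["aca1"]
    for pid in pids:
        genes.append(Gene(pid, contig, pos, pos + 299, strand, pid, 90))
        pos += 350
    if strand == "-":
        pass  # coordinates identical; transcription order handled by caller
    op = Operon(contig, strand, tuple(genes))
    calls = tuple(
        AcrHomologCall(f"acr{i}", fam, family_to_subtypes(fam), 1e-20, 96.0)
        for i, fam in enumerate(families)
    )
    filters = ("homology_gba", "aca_locus", "mge")
    if passed_selftarget:
        filters += ("self_target",)
    return CandidateLocus(
        locus_id=locus_id_for(op, "g"), operon=op, genome_id="g",
        aca_protein_ids=frozenset({"aca1"}), acr_calls=calls,
        filters_passed=filters,
    )


def _event(contig="c1", subtype="I-E", start=5000):
    return SelfTargetEvent("sp1", "a1", contig, start, start + 31, "+", 0, subtype)


class TestAssignSubtypes:
    def test_conflicting_pair_for_acrif3_in_ie_genome(self):
        locus = _locus(("AcrIF3",))
        hom, st = assign_subtypes(locus, [_event(subtype="I-E")])
        assert hom.subtypes == {"I-F"}
        assert st.subtypes == {"I-E"}

    def test_agreeing_pair(self):
        locus = _locus(("AcrIIA4",))
        hom, st = assign_subtypes(locus, [_event(subtype="II-A")])
        assert hom.subtypes == st.subtypes == {"II-A"}

    def test_locus_without_acr_has_only_selftarget_call(self):
        locus = _locus(())
        hom, st = assign_subtypes(locus, [_event(subtype="I-B")])
        assert hom is None
        assert st.subtypes == {"I-B"}

    def test_locus_failing_selftarget_filter_has_no_selftarget_call(self):
        locus = _locus(("AcrIF3",), passed_selftarget=False)
        hom, st = assign_subtypes(locus, [_event()])
        assert hom is not None and st is None

    def test_events_on_other_contigs_ignored(self):
        locus = _locus(("AcrIF3",), contig="c1")
        _, st = assign_subtypes(locus, [_event(contig="c2")])
        assert st is None


class TestFindConflicts:
    def _pair(self, lid, hom_subtypes, st_subtypes, families=("AcrIF3",)):
        return (
            SubtypeCall(lid, "homology", frozenset(hom_subtypes), tuple(families)),
            SubtypeCall(lid, "self_target", frozenset(st_subtypes)),
        )

    def test_duplicate_strain_loci_collapse_to_one_nonredundant(self):
        pairs = [self._pair(f"L{i}", {"I-F"}, {"I-E"}) for i in range(42)]
        acr_ids = {f"L{i}": frozenset({"WP_SHARED"}) for i in range(42)}
        conflicts, nonredundant = find_conflicts(pairs, acr_ids)
        assert len(conflicts) == 42
        assert len(nonredundant) == 1

    def test_overlapping_sets_are_agreement(self):
        pairs = [self._pair("L1", {"I-E", "I-F"}, {"I-F"})]
        conflicts, nonredundant = find_conflicts(pairs, {"L1": frozenset({"x"})})
        assert conflicts == [] and nonredundant == []

    def test_empty_input(self):
        assert find_conflicts([], {}) == ([], [])

    def test_agreement_and_conflict_partition_loci(self):
        pairs = (
            [self._pair(f"A{i}", {"II-A"}, {"II-A"}) for i in range(5)]
            + [self._pair(f"C{i}", {"I-F"}, {"I-B"}) for i in range(3)]
        )
        conflicts, _ = find_conflicts(pairs, {p[0].locus_id: frozenset() for p in pairs})
        agreeing = [p for p in pairs if p[0].subtypes & p[1].subtypes]
        assert len(agreeing) + len(conflicts) == len(pairs)

    def test_conflict_record_rejects_overlap(self):
        with pytest.raises(ValueError):
            ConflictRecord("L", frozenset({"AcrIF3"}), frozenset({"I-F"}),
                           frozenset({"I-F"}), frozenset())

    def test_nonredundant_distinct_ids_keep_everything(self):
        pairs = [self._pair(f"L{i}", {"I-F"}, {"I-E"}) for i in range(4)]
        acr_ids = {f"L{i}": frozenset({f"WP_{i}"}) for i in range(4)}
        conflicts, nonredundant = find_conflicts(pairs, acr_ids)
        assert len(nonredundant) == len(conflicts) == 4


class TestConflictFixture:
    def test_fixture_expansion_reproduces_group_table(self):
        groups = data.conflict_groups()
        pairs, acr_ids = conflict_calls_from_groups(groups)
        conflicts, nonredundant = find_conflicts(pairs, acr_ids)
        assert len(pairs) == len(conflicts) == groups["n_loci"].sum() == 59
        assert len(nonredundant) == len(groups) == 8
        report = conflict_report(conflicts)
        merged = report.merge(
            groups.assign(
                homology_families=lambda d: d["homology_families"]
                .str.split(";").map(lambda fs: ";".join(sorted(fs)))
            ),
            on=["homology_families", "selftarget_subtype"],
        )
        assert len(merged) == 8
        assert (merged["n_loci_x"] == merged["n_loci_y"]).all()
        assert (merged["n_unique_acr_ids_x"] == merged["n_unique_acr_ids_y"]).all()


class TestTaPairs:
    def _hits(self, *pids, evalue=1e-6):
        return [HomologyHit("tox_ref", pid, 90.0, 80, evalue, 100.0) for pid in pids]

    def test_toxin_then_antitoxin_on_plus_strand_is_canonical(self):
        locus = _locus(("AcrIF3",))  # genes acr0, aca1 in coordinate order
        call = check_ta_pairs(locus, self._hits("acr0"), self._hits("aca1"))
        assert call.paired and call.canonical_order
        assert (call.toxin_protein, call.antitoxin_protein) == ("acr0", "aca1")

    def test_antitoxin_only_not_paired(self):
        locus = _locus(("AcrIF3",))
        call = check_ta_pairs(locus, [], self._hits("aca1"))
        assert not call.paired and call.antitoxin_protein == "aca1"

    def test_antitoxin_upstream_is_noncanonical(self):
        locus = _locus(("AcrIF3",))
        call = check_ta_pairs(locus, self._hits("aca1"), self._hits("acr0"))
        assert call.paired and not call.canonical_order

    def test_order_follows_transcription_on_minus_strand(self):
        locus = _locus(("AcrIF3",), strand="-")
        # '-' strand: transcription order reverses the coordinate order, so
        # the downstream (3') gene is acr0
        call = check_ta_pairs(locus, self._hits("aca1"), self._hits("acr0"))
        assert call.paired and call.canonical_order

    def test_weak_hits_above_cutoff_ignored(self):
        locus = _locus(("AcrIF3",))
        call = check_ta_pairs(
            locus, self._hits("acr0", evalue=1e-2), self._hits("aca1"), evalue_max=1e-3
        )
        assert not call.paired

    def test_same_gene_cannot_pair_with_itself(self):
        locus = _locus(("AcrIF3",))
        call = check_ta_pairs(locus, self._hits("aca1"), self._hits("aca1"))
        assert not call.paired
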
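import numpy as np
import pytest

from acrminer.crispr_selftarget import (
    CasSystem,
    CrisprArray,
    colocalize_loci,
    find_self_targets,
    genome_has_complete_system,
    read_crispr_tsv,
    reverse_complement,
    write_crispr_tsv,
)
from acrminer.genome_io import Contig, Gene, ValidationError
from acrminer.loci import CandidateLocus, Operon, locus_id_for

from oracles import selftarget_bruteforce

IF_GENES = frozenset({"cas1", "cas2-3", "cas5f", "cas6f", "cas7f", "cas8f"})


def _array(spacers, contig="c1", start=100, array_id="a1"):
    end = start + 61 * len(spacers) + 28
    return CrisprArray(array_id, contig, start, end, tuple(spacers))


def _random_contig(rng, n, cid="c1"):
    return Contig(cid, n, "".join(rng.choice(list("ACGT"), n)))


def _locus(contig):
    gene = Gene("g1", contig, 1000, 1299, "+", "p1", 90)
    op = Operon(contig, "+", (gene,))
    return CandidateLocus(
        locus_id=locus_id_for(op, "g"), operon=op, genome_id="g",
        aca_protein_ids=frozenset({"p1"}),
        filters_passed=("aca_locus", "mge"),
    )


class TestCompleteness:
    def test_complete_system_plus_array(self):
        sys = CasSystem("s1", "I-F", "c1", IF_GENES)
        arr = _array([("sp1", "ACGT" * 8)])
        assert genome_has_complete_system([sys], [arr]) == {"I-F": True}

    def test_arrays_only_no_cas(self):
        assert genome_has_complete_system([], [_array([("sp1", "ACGT" * 8)])]) == {}

    def test_missing_required_gene_incomplete(self):
        sys = CasSystem("s1", "I-F", "c1", IF_GENES - {"cas7f"})
        arr = _array([("sp1", "ACGT" * 8)])
        assert genome_has_complete_system([sys], [arr]) == {"I-F": False}

    def test_complete_cas_without_array_incomplete(self):
        sys = CasSystem("s1", "II-C", "c1", frozenset({"cas9", "cas1", "cas2"}))
        assert genome_has_complete_system([sys], []) == {"II-C": False}

    def test_unknown_subtype_rejected_listing_accepted(self):
        with pytest.raises(ValidationError, match="I-F"):
            CasSystem("s1", "IX-Z", "c1", frozenset())


class TestFindSelfTargets:
    def _genome(self, seed=1, n=5000):
        rng = np.random.default_rng(seed)
        spacer = "".join(rng.choice(list("ACGT"), 32))
        seq = list("".join(rng.choice(list("ACGT"), n)))
        return rng, spacer, seq

    def test_verbatim_copy_yields_zero_mismatch_event(self):
        rng, spacer, seq = self._genome()
        seq[3000:3032] = spacer
        arr = _array([("sp1", spacer)], start=100)
        seq[100 - 1 : 100 - 1 + 32] = spacer  # spacer inside its own array too
        contig = Contig("c1", len(seq), "".join(seq))
        sys = CasSystem("s1", "I-F", "c1", IF_GENES)
        (ev,) = find_self_targets([arr], [contig], [sys], max_mismatch=0)
        assert (ev.target_start, ev.target_end, ev.target_strand, ev.mismatches) == (
            3001, 3032, "+", 0,
        )
        assert ev.subtype == "I-F"

    def test_occurrence_only_inside_array_excluded(self):
        _, spacer, seq = self._genome(seed=2)
        arr = _array([("sp1", spacer)], start=100)
        seq[100 - 1 : 100 - 1 + 32] = spacer
        contig = Contig("c1", len(seq), "".join(seq))
        assert find_self_targets([arr], [contig], [], max_mismatch=0) == []

    def test_reverse_complement_copy_reported_on_minus_strand(self):
        _, spacer, seq = self._genome(seed=3)
        seq[2000:2032] = reverse_complement(spacer)
        contig = Contig("c1", len(seq), "".join(seq))
        arr = _array([("sp1", spacer)], start=100)
        (ev,) = find_self_targets([arr], [contig], [], max_mismatch=0)
        assert (ev.target_start, ev.target_strand) == (2001, "-")

    def test_spacer_with_n_skipped_with_warning(self):
        _, _, seq = self._genome(seed=4)
        contig = Contig("c1", len(seq), "".join(seq))
        arr = _array([("spN", "ACGTN" + "A" * 27)])
        with pytest.warns(UserWarning, match="spN"):
            assert find_self_targets([arr], [contig], [], 0) == []

    def test_event_count_monotone_in_max_mismatch(self):
        rng, spacer, seq = self._genome(seed=5)
        mutated = list(spacer)
        mutated[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[5]]
        seq[1000:1032] = spacer
        seq[3000:3032] = mutated
        contig = Contig("c1", len(seq), "".join(seq))
        arr = _array([("sp1", spacer)], start=100)
        counts = [
            len(find_self_targets([arr], [contig], [], mm)) for mm in (0, 1, 2)
        ]
        assert counts == sorted(counts)
        assert counts[0] == 1 and counts[1] >= 2

    def test_matches_bruteforce_scan_on_random_genomes(self):
        rng = np.random.default_rng(99)
        for trial in range(8):
            contigs = [
                _random_contig(rng, int(rng.integers(800, 4000)), f"c{k}")
                for k in range(2)
            ]
            spacers = [
                (f"sp{k}", "".join(rng.choice(list("ACGT"), 20))) for k in range(2)
            ]
            # plant one copy to guarantee non-trivial hits
            seq = list(contigs[0].sequence)
            seq[500:520] = spacers[0][1]
            contigs[0] = Contig("c0", contigs[0].length, "".join(seq))
            arrays = [_array(spacers, contig="c1", start=50)]
            got = {
                (e.spacer_id, e.target_contig, e.target_start, e.target_end,
                 e.target_strand, e.mismatches)
                for e in find_self_targets(arrays, contigs, [], 0)
            }
            assert got == selftarget_bruteforce(arrays, contigs, 0)

    def test_no_event_overlaps_an_array(self):
        rng = np.random.default_rng(12)
        spacer = "".join(rng.choice(list("ACGT"), 24))
        seq = list("".join(rng.choice(list("ACGT"), 3000)))
        seq[100:124] = spacer
        seq[150:174] = spacer  # partially overlapping the array below
        seq[2000:2024] = spacer
        contig = Contig("c1", 3000, "".join(seq))
        arr = CrisprArray("a1", "c1", 90, 160, (("sp1", spacer),))
        events = find_self_targets([arr], [contig], [], 0)
        for ev in events:
            assert not (ev.target_start <= 160 and ev.target_end >= 90)


class TestColocalize:
    def test_same_contig_with_complete_system_kept(self, bundle):
        events = find_self_targets(
            bundle.arrays, bundle.genome.contigs, bundle.systems, 0
        )
        locus = _locus("ctg_pos1")
        (kept,) = colocalize_loci([locus], events, {"I-F": True})
        assert "self_target" in kept.filters_passed
        assert kept.supporting_events

    def test_event_on_other_contig_only_dropped(self, bundle):
        events = find_self_targets(
            bundle.arrays, bundle.genome.contigs, bundle.systems, 0
        )
        locus = _locus("ctg_no_selftarget")
        assert colocalize_loci([locus], events, {"I-F": True}) == []

    def test_no_complete_system_drops_everything(self):
        locus = _locus("c1")
        assert colocalize_loci([locus], [], {"I-F": False}) == []


class TestCrisprTsvRoundTrip:
    def test_round_trip(self, tmp_path, bundle):
        path = tmp_path / "crispr.tsv"
        write_crispr_tsv(bundle.arrays, bundle.systems, path)
        arrays, systems = read_crispr_tsv(path)
        assert [(a.array_id, a.contig_id, a.start, a.end, a.spacers) for a in arrays] == [
            (a.array_id, a.contig_id, a.start, a.end, a.spacers) for a in bundle.arrays
        ]
        assert [(s.system_id, s.subtype, s.cas_gene_ids, s.complete) for s in systems] == [
            (s.system_id, s.subtype, s.cas_gene_ids, s.complete) for s in bundle.systems
        ]
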
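import numpy as np
import pytest

from acrminer.genome_io import (
    Contig,
    Gene,
    ParseError,
    ValidationError,
    call_orfs_naive,
    read_fasta,
    read_gff_genes,
    read_mge_bed,
    read_tabular_hits,
    write_gff_genes,
)

from oracles import orf_scan_bruteforce


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGff:
    def test_two_cds_coordinates_and_strands(self, tmp_path):
        gff = _write(
            tmp_path,
            "two.gff",
            "##gff-version 3\n"
            "c1\tsrc\tCDS\t100\t399\t.\t+\t0\tID=g1;protein_id=p1\n"
            "c1\tsrc\tCDS\t500\t799\t.\t-\t0\tID=g2;protein_id=p2\n",
        )
        genes = read_gff_genes(gff)
        assert [(g.start, g.end, g.strand) for g in genes] == [
            (100, 399, "+"),
            (500, 799, "-"),
        ]
        # span-derived protein length: (300)/3 - 1
        assert genes[0].protein_length == 99

    def test_header_only_gives_empty(self, tmp_path):
        gff = _write(tmp_path, "empty.gff", "##gff-version 3\n")
        assert read_gff_genes(gff) == []

    def test_protein_length_map_takes_precedence(self, tmp_path):
        gff = _write(
            tmp_path, "one.gff",
            "##gff-version 3\nc1\tsrc\tCDS\t100\t399\t.\t+\t0\tID=g1;protein_id=p1\n",
        )
        genes = read_gff_genes(gff, {"p1": 150})
        assert genes[0].protein_length == 150

    def test_malformed_line_names_line_number(self, tmp_path):
        gff = _write(
            tmp_path, "bad.gff",
            "##gff-version 3\nc1\tsrc\tCDS\t100\t399\t.\t+\t0\n",
        )
        with pytest.raises(ParseError, match=":2:"):
            read_gff_genes(gff)

    def test_unknown_strand_rejected(self, tmp_path):
        gff = _write(
            tmp_path, "strand.gff",
            "##gff-version 3\nc1\tsrc\tCDS\t1\t9\t.\t*\t0\tID=g1\n",
        )
        with pytest.raises(ValidationError, match="strand"):
            read_gff_genes(gff)

    def test_round_trip(self, tmp_path):
        genes = [
            Gene("g1", "c1", 100, 399, "+", "p1", 99),
            Gene("g2", "c2", 5, 37, "-", "p2", 10),
        ]
        out = tmp_path / "rt.gff"
        write_gff_genes(genes, out)
        back = read_gff_genes(out, {"p1": 99, "p2": 10})
        assert back == sorted(genes, key=lambda g: (g.contig_id, g.start))


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = _write(tmp_path, "a.faa", ">p1\nMKV\n")
        assert read_fasta(p, "protein") == {"p1": "MKV"}

    def test_wrapped_lines_concatenate(self, tmp_path):
        seq = "ACGT" * 45  # 180 nt over 3 rows of 60
        rows = "\n".join(seq[i : i + 60] for i in range(0, 180, 60))
        p = _write(tmp_path, "n.fna", f">c1 some description\n{rows}\n")
        out = read_fasta(p, "nucleotide")
        assert out == {"c1": seq}  # id truncated at whitespace

    def test_duplicate_id_rejected(self, tmp_path):
        p = _write(tmp_path, "dup.faa", ">p1\nMK\n>p1\nMV\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_fasta(p, "protein")

    def test_illegal_character_names_record(self, tmp_path):
        p = _write(tmp_path, "bad.fna", ">c1\nACGTQ\n")
        with pytest.raises(ValidationError, match="c1"):
            read_fasta(p, "nucleotide")


class TestTabularHits:
    def test_blast6_row(self, tmp_path):
        p = _write(
            tmp_path, "h.tsv",
            "AcrIF3\tWP_X\t99.0\t100\t1\t0\t1\t100\t1\t100\t1e-50\t200\n",
        )
        (hit,) = read_tabular_hits(p, "blast6")
        assert (hit.query_id, hit.subject_id, hit.evalue) == ("AcrIF3", "WP_X", 1e-50)

    def test_comments_only_gives_empty(self, tmp_path):
        p = _write(tmp_path, "c.tsv", "# a\n# b\n")
        assert read_tabular_hits(p, "blast6") == []

    def test_zero_evalue_accepted(self, tmp_path):
        p = _write(
            tmp_path, "z.tsv",
            "q\ts\t100.0\t50\t0\t0\t1\t50\t1\t50\t0.0\t99\n",
        )
        assert read_tabular_hits(p, "blast6")[0].evalue == 0.0

    def test_wrong_column_count_reports_row(self, tmp_path):
        p = _write(tmp_path, "w.tsv", "q\ts\t100.0\n")
        with pytest.raises(ParseError, match=":1:"):
            read_tabular_hits(p, "blast6")

    def test_no_rows_silently_dropped(self, tmp_path):
        text = "# comment\nq\ts\t9.0\t5\t0\t0\t1\t5\t1\t5\t1e-3\t20\n\n"
        p = _write(tmp_path, "mix.tsv", text)
        hits = read_tabular_hits(p, "blast6")
        n_lines = len(text.splitlines())
        n_skipped = sum(
            1 for l in text.splitlines() if not l or l.startswith("#")
        )
        assert len(hits) + n_skipped == n_lines

    def test_domtbl_row(self, tmp_path):
        fields = ["WP_A", "-", "100", "HTH_XRE", "-", "50"] + ["0"] * 6 + ["1e-6"] + ["0"] * 10
        p = _write(tmp_path, "d.txt", "# header\n" + " ".join(fields) + "\n")
        (hit,) = read_tabular_hits(p, "domtbl")
        assert (hit.protein_id, hit.domain_name, hit.evalue) == ("WP_A", "HTH_XRE", 1e-6)


class TestBed:
    def test_zero_based_half_open_converted(self, tmp_path):
        p = _write(tmp_path, "m.bed", "c1\t0\t100\tprophage\n")
        (iv,) = read_mge_bed(p)
        assert (iv.start, iv.end, iv.kind) == (1, 100, "prophage")

    def test_unknown_kind_rejected(self, tmp_path):
        p = _write(tmp_path, "m.bed", "c1\t0\t100\tplasmid\n")
        with pytest.raises(ValidationError):
            read_mge_bed(p)


class TestOrfCalling:
    def test_single_orf_in_n_padding(self):
        contig = Contig("c", 17, "NNNN" + "ATGAAATAA" + "NNNN")
        (gene,) = call_orfs_naive(contig, min_len=2)
        assert (gene.start, gene.end, gene.strand, gene.protein_length) == (5, 13, "+", 2)

    def test_all_n_contig_empty(self):
        assert call_orfs_naive(Contig("c", 30, "N" * 30), min_len=1) == []

    def test_min_len_threshold(self):
        contig = Contig("c", 6, "ATGTAA")  # 1-codon ORF
        assert call_orfs_naive(contig, min_len=2) == []

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValueError, match="sequence"):
            call_orfs_naive(Contig("c", 10), min_len=1)

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(60, 3000))
            seq = "".join(rng.choice(list("ACGT"), n))
            contig = Contig("c", n, seq)
            got = {
                (g.start, g.end, g.strand, g.protein_length)
                for g in call_orfs_naive(contig, min_len=10)
            }
            assert got == orf_scan_bruteforce(seq, 10)
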
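"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the rule definitions alone, deliberately
naive (exhaustive enumeration, quadratic scans, plain-Python DP), and shares
no code path with the package modules it checks.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# six-frame maximal ORF enumeration


def orf_scan_bruteforce(seq: str, min_len: int) -> set[tuple[int, int, str, int]]:
    """All maximal ATG->stop ORFs as (start, end, strand, aa_len), 1-based
    inclusive forward-strand coordinates."""
    seq = seq.upper()
    n = len(seq)
    out: set[tuple[int, int, str, int]] = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            prev_stop = -1
            for ci, codon in enumerate(codons):
                if codon in STOPS:
                    # first ATG strictly after the previous stop gives the
                    # maximal ORF ending at this stop
                    for ai in range(prev_stop + 1, ci):
                        if codons[ai] == "ATG":
                            aa_len = ci - ai
                            if aa_len >= min_len:
                                i0 = frame + 3 * ai  # 0-based on s
                                i1 = frame + 3 * ci + 2
                                if strand == "+":
                                    out.add((i0 + 1, i1 + 1, "+", aa_len))
                                else:
                                    out.add((n - i1, n - i0, "-", aa_len))
                            break
                    prev_stop = ci
    return out


# ---------------------------------------------------------------------------
# local alignment with affine gaps (Gotoh), BLAST-style gap costs


def sw_affine_oracle(a: str, b: str, matrix, gap_open: int = 11,
                     gap_extend: int = 1) -> float:
    """Best Smith-Waterman score; a gap of length L costs open + L*extend."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (left move)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (up move)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - (gap_open + gap_extend),
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - (gap_open + gap_extend),
                          F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


# ---------------------------------------------------------------------------
# maximal compliant gene windows (operon rule check)


def operon_windows_bruteforce(genes, max_len: int = 200, max_gap: int = 150):
    """All maximal contiguous windows of the sorted gene list that satisfy
    the operon rules, as tuples of protein ids."""
    genes = sorted(genes, key=lambda g: (g.contig_id, g.start))
    n = len(genes)

    def compliant(i: int, j: int) -> bool:  # inclusive window
        w = genes[i : j + 1]
        if any(g.protein_length >= max_len for g in w):
            return False
        if len({(g.contig_id, g.strand) for g in w}) > 1:
            return False
        return all(
            w[k + 1].start - w[k].end - 1 < max_gap for k in range(len(w) - 1)
        )

    windows = set()
    for i in range(n):
        for j in range(i, n):
            if compliant(i, j):
                left_ext = i > 0 and compliant(i - 1, j)
                right_ext = j < n - 1 and compliant(i, j + 1)
                if not left_ext and not right_ext:
                    windows.add(tuple(g.protein_id for g in genes[i : j + 1]))
    return windows


# ---------------------------------------------------------------------------
# spacer -> protospacer scan


def selftarget_bruteforce(arrays, contigs, max_mismatch: int = 0):
    """(spacer_id, contig, start, end, strand, mismatches) for every spacer
    occurrence outside all array intervals, both strands."""
    spans = {}
    for a in arrays:
        spans.setdefault(a.contig_id, []).append((a.start, a.end))
    hits = set()
    for a in arrays:
        for sid, spacer in a.spacers:
            if "N" in spacer:
                continue
            k = len(spacer)
            for c in contigs:
                if c.sequence is None:
                    continue
                seq = c.sequence.upper()
                for strand, probe in (("+", spacer), ("-", revcomp(spacer))):
                    for i in range(len(seq) - k + 1):
                        mm = sum(x != y for x, y in zip(seq[i : i + k], probe))
                        if mm > max_mismatch:
                            continue
                        start, end = i + 1, i + k
                        if any(start <= e and end >= s
                               for s, e in spans.get(c.contig_id, [])):
                            continue
                        hits.add((sid, c.contig_id, start, end, strand, mm))
    return hits


# ---------------------------------------------------------------------------
# locus-vs-MGE overlap


def mge_bruteforce(loci, intervals, margin: int = 5000):
    """Locus ids kept by an all-pairs closest-edge distance check."""
    kept = set()
    for lc in loci:
        for iv in intervals:
            if iv.contig_id != lc.contig_id:
                continue
            if lc.start <= iv.end + margin and lc.end >= iv.start - margin:
                kept.add(lc.locus_id)
                break
    return kept
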
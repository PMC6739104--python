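"""Homology and domain evidence -> Acr-homolog and HTH (Aca) protein calls.

The thresholds mirror the discovery criteria: an Acr homolog needs an E-value
below 1e-2 to a known Acr family and a protein shorter than 200 aa; HTH (Aca)
evidence uses Pfam HTH_* family names plus DUF1870. All threshold comparisons
are strict inequalities, so a hit at exactly the cutoff does not qualify.

A small built-in Smith-Waterman search (:func:`builtin_protein_search`) lets
tests and toy analyses run with no external aligner; production runs consume
DIAMOND/BLAST tabular files instead.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import DomainHit, Gene, HomologyHit


class FamilyNameError(ValueError):
    """A string does not follow the Acr family naming grammar."""


@dataclass(frozen=True)
class SearchThresholds:
    """Numeric criteria of the homology/GBA discovery steps (all exclusive)."""

    acr_evalue_max: float = 1e-2
    aca_evalue_max: float = 1e-3
    max_protein_len: int = 200
    hth_domain_evalue_max: float = 1e-3
    hth_domain_names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name in ("acr_evalue_max", "aca_evalue_max", "hth_domain_evalue_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_protein_len <= 0:
            raise ValueError("max_protein_len must be > 0")

    def is_hth_domain(self, name: str) -> bool:
        if self.hth_domain_names is not None:
            return name in self.hth_domain_names
        return name.startswith("HTH_") or name == "DUF1870"


@dataclass(frozen=True)
class AcrHomologCall:
    """A protein called as homolog of a known Acr family."""

    protein_id: str
    family: str
    subtypes: frozenset[str]
    best_evalue: float
    best_pident: float

    def __post_init__(self) -> None:
        if not self.subtypes:
            raise ValueError("subtypes must be nonempty")


_ROMAN = ("VI", "IV", "V", "III", "II", "I")
_PART_RE = re.compile(r"^(VI|IV|V|III|II|I)([A-Z])(\d*)$")


def family_to_subtypes(family: str) -> frozenset[str]:
    """Derive the inhibited CRISPR-Cas subtype(s) from an Acr family name.

    The family name encodes the subtype: ``AcrIF3`` -> ``{"I-F"}``,
    ``AcrIIA4`` -> ``{"II-A"}``. Hybrid names such as ``AcrIE4-IF7`` map to
    the union of both parts.
    """
    if not family.startswith("Acr"):
        raise FamilyNameError(f"{family!r} does not start with 'Acr'")
    body = family[3:]
    if not body:
        raise FamilyNameError(f"{family!r} has no subtype part")
    subtypes: set[str] = set()
    for part in body.split("-"):
        m = _PART_RE.match(part)
        if m is None:
            raise FamilyNameError(f"{family!r}: cannot parse part {part!r}")
        subtypes.add(f"{m.group(1)}-{m.group(2)}")
    return frozenset(subtypes)


def filter_acr_candidates(
    hits: Iterable[HomologyHit],
    genes: Mapping[str, Gene],
    t: SearchThresholds = SearchThresholds(),
) -> list[AcrHomologCall]:
    """Call Acr homologs from tabular hits under the E-value and length rules.

    A subject qualifies when at least one hit has ``evalue < acr_evalue_max``
    and its protein is shorter than ``max_protein_len`` aa. The reported family
    is the query of the minimum-E-value hit; ties break by higher bitscore,
    then lexicographic query id. Subject ids that resolve to no gene are
    reported through a warning, never silently dropped.
    """
    by_subject: dict[str, list[HomologyHit]] = {}
    unresolved: set[str] = set()
    for h in hits:
        if h.subject_id not in genes:
            unresolved.add(h.subject_id)
            continue
        by_subject.setdefault(h.subject_id, []).append(h)
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} hit subject id(s) not resolvable to genes: "
            f"{sorted(unresolved)[:5]}...",
            stacklevel=2,
        )
    calls: list[AcrHomologCall] = []
    for subject, subject_hits in sorted(by_subject.items()):
        gene = genes[subject]
        passing = [h for h in subject_hits if h.evalue < t.acr_evalue_max]
        if not passing or gene.protein_length >= t.max_protein_len:
            continue
        best = min(passing, key=lambda h: (h.evalue, -h.bitscore, h.query_id))
        calls.append(
            AcrHomologCall(
                protein_id=subject,
                family=best.query_id,
                subtypes=family_to_subtypes(best.query_id),
                best_evalue=best.evalue,
                best_pident=best.pident,
            )
        )
    return calls


def detect_hth(
    protein_id: str,
    domain_hits: Iterable[DomainHit],
    t: SearchThresholds = SearchThresholds(),
) -> bool:
    """True iff the protein has an HTH-family (or DUF1870) domain hit below
    the domain E-value cutoff."""
    return any(
        h.protein_id == protein_id
        and t.is_hth_domain(h.domain_name)
        and h.evalue < t.hth_domain_evalue_max
        for h in domain_hits
    )


def hth_predicate(
    domain_hits: Sequence[DomainHit], t: SearchThresholds = SearchThresholds()
) -> Callable[[str], bool]:
    """Precomputed protein_id -> bool HTH predicate over a hit table."""
    positive = {
        h.protein_id
        for h in domain_hits
        if t.is_hth_domain(h.domain_name) and h.evalue < t.hth_domain_evalue_max
    }
    return positive.__contains__


# ---------------------------------------------------------------------------
# Built-in protein search (Smith-Waterman + Karlin-Altschul E-values)

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class AlignerParams:
    gap_open: int = 11
    gap_extend: int = 1
    matrix: str = "BLOSUM62"
    evalue_max: float = 10.0


def sw_score(a: str, b: str, params: AlignerParams = AlignerParams()) -> float:
    """Smith-Waterman local alignment score (BLAST-style affine gaps: a gap of
    length L costs open + L*extend)."""
    aligner = _make_aligner(params)
    return float(aligner.score(a, b))


def _make_aligner(params: AlignerParams) -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(params.matrix),
        open_gap_score=-(params.gap_open + params.gap_extend),
        extend_gap_score=-params.gap_extend,
    )
    return aligner


def builtin_protein_search(
    queries: Mapping[str, str],
    db: Mapping[str, str],
    params: AlignerParams = AlignerParams(),
) -> list[HomologyHit]:
    """All-vs-all local alignment of queries against a protein database.

    E-values use the Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)``
    with m = query length and n = total database residues; hits with
    E < ``params.evalue_max`` are returned sorted by (evalue, query, subject).
    """
    if not queries or not db:
        return []
    n_db = sum(len(s) for s in db.values())
    aligner = _make_aligner(params)
    hits: list[HomologyHit] = []
    for qid, qseq in queries.items():
        for sid, sseq in db.items():
            alns = aligner.align(qseq, sseq)
            score = float(alns.score)
            if score <= 0:
                continue
            ev = karlin_altschul_evalue(score, len(qseq), n_db)
            if ev >= params.evalue_max:
                continue
            pident, aln_len = _alignment_identity(alns[0], qseq, sseq)
            hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=sid,
                    pident=pident,
                    aln_len=aln_len,
                    evalue=ev,
                    bitscore=score,
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.query_id, h.subject_id))
    return hits


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S) with the fixed gapped parameters."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def _alignment_identity(aln, qseq: str, sseq: str) -> tuple[float, int]:
    """Percent identity over alignment columns (gap columns included)."""
    qblocks, sblocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        aligned_cols += qe - qs
        matches += sum(1 for i in range(qe - qs) if qseq[qs + i] == sseq[ss + i])
    # gap columns: difference between block spans on either side
    q_span = qblocks[-1][1] - qblocks[0][0]
    s_span = sblocks[-1][1] - sblocks[0][0]
    aln_len = aligned_cols + (q_span - aligned_cols) + (s_span - aligned_cols)
    pident = 100.0 * matches / aln_len if aln_len else 0.0
    return round(pident, 2), aln_len
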
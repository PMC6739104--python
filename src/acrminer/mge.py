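"""Mobile-genetic-element context filter.

A candidate locus is kept only when it lies within, or within ±5 kb of, an
annotated prophage or genomic-island interval on the same contig. Both MGE
kinds are treated identically; the supporting interval(s) are recorded on the
kept locus. The 5 kb margin is an inclusive closest-edge distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .genome_io import MgeInterval
from .loci import CandidateLocus


@dataclass(frozen=True)
class MgeConfig:
    margin_bp: int = 5000  # inclusive

    def __post_init__(self) -> None:
        if self.margin_bp < 0:
            raise ValueError("margin_bp must be >= 0")


def filter_by_mge(
    loci: Sequence[CandidateLocus],
    intervals: Sequence[MgeInterval],
    cfg: MgeConfig = MgeConfig(),
) -> list[CandidateLocus]:
    """Keep loci overlapping an MGE interval grown by ``margin_bp`` on each
    side; kept loci gain the 'mge' filter flag and record supporting
    intervals. Loci on contigs with no intervals are dropped."""
    trees: dict[str, IntervalTree] = {}
    payload: dict[str, list[MgeInterval]] = {}
    for iv in intervals:
        # half-open tree coordinates; grow by margin and one for inclusivity
        trees.setdefault(iv.contig_id, IntervalTree()).addi(
            iv.start - cfg.margin_bp, iv.end + cfg.margin_bp + 1, iv
        )
    kept: list[CandidateLocus] = []
    for lc in loci:
        tree = trees.get(lc.contig_id)
        if tree is None:
            continue
        overlapping = sorted(
            (hit.data for hit in tree.overlap(lc.start, lc.end + 1)),
            key=lambda iv: (iv.start, iv.end, iv.kind),
        )
        if overlapping:
            out = lc.with_filter("mge")
            out.supporting_mge = tuple(overlapping)
            kept.append(out)
    return kept
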
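"""Accounting over candidate loci: stratified counts, crosstabs, percentages.

The stratification mirrors the four filter-step combinations a run can
produce: {1,2} (all Aca-anchored loci), {1,2,3} (MGE-supported), {1,2,3,4}
(MGE- and self-targeting-supported) and {1,2,4} (self-targeting-supported
with the MGE step skipped). Percentages are printed with one decimal,
rounded half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .loci import CandidateLocus

#: filter-step combinations and the locus flags they require
STRATA: dict[str, frozenset[str]] = {
    "1,2": frozenset({"aca_locus"}),
    "1,2,3": frozenset({"aca_locus", "mge"}),
    "1,2,3,4": frozenset({"aca_locus", "mge", "self_target"}),
    "1,2,4": frozenset({"aca_locus", "self_target"}),
}


@dataclass(frozen=True)
class StratumSummary:
    stratum: str
    n_loci: int
    n_genomes: int
    n_genomes_multilocus: int
    n_genomes_selftarget: int
    n_loci_with_acr: int
    unique_acr_ids: int
    unique_aca_ids: int

    def __post_init__(self) -> None:
        if self.n_loci_with_acr > self.n_loci:
            raise ValueError("n_loci_with_acr > n_loci")
        if self.n_genomes_multilocus > self.n_genomes:
            raise ValueError("n_genomes_multilocus > n_genomes")


def percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half away from zero to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator < 0:
        raise ValueError("numerator must be >= 0")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_strata(
    loci: Sequence[CandidateLocus],
    selftarget_genomes: set[str] | None = None,
) -> list[StratumSummary]:
    """One summary per filter-step combination.

    A locus belongs to every stratum whose required filter flags it carries,
    so the strata are nested the way the filter cascade is. Unique Acr/Aca
    counts are over protein ids, not locus rows. ``selftarget_genomes``
    optionally names genomes known to carry self-targeting spacers; when
    omitted, it is inferred from loci passing the self-target filter.
    """
    if selftarget_genomes is None:
        selftarget_genomes = {
            lc.genome_id for lc in loci if "self_target" in lc.filters_passed
        }
    out: list[StratumSummary] = []
    for stratum, required in STRATA.items():
        members = [lc for lc in loci if required <= set(lc.filters_passed)]
        genomes: dict[str, int] = {}
        for lc in members:
            genomes[lc.genome_id] = genomes.get(lc.genome_id, 0) + 1
        with_acr = [lc for lc in members if lc.has_acr]
        acr_ids = {c.protein_id for lc in with_acr for c in lc.acr_calls}
        aca_ids = {pid for lc in members for pid in lc.aca_protein_ids}
        out.append(
            StratumSummary(
                stratum=stratum,
                n_loci=len(members),
                n_genomes=len(genomes),
                n_genomes_multilocus=sum(1 for n in genomes.values() if n > 1),
                n_genomes_selftarget=sum(1 for g in genomes if g in selftarget_genomes),
                n_loci_with_acr=len(with_acr),
                unique_acr_ids=len(acr_ids),
                unique_aca_ids=len(aca_ids),
            )
        )
    return out


def strata_table(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def crosstab(rows: Sequence[str], cols: Sequence[str]) -> pd.DataFrame:
    """Contingency matrix with row/column margins; grand total = item count."""
    if len(rows) != len(cols):
        raise ValueError(f"length mismatch: {len(rows)} rows vs {len(cols)} cols")
    if not rows:
        return pd.DataFrame({"All": {"All": 0}})
    return pd.crosstab(
        pd.Series(rows, name="row"),
        pd.Series(cols, name="col"),
        margins=True,
        margins_name="All",
    )
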
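"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


def _path(name: str):
    return resources.files("acrminer.data").joinpath(name)


@lru_cache(maxsize=None)
def acr_family_names() -> tuple[str, ...]:
    """The 45 characterized Acr family names."""
    df = pd.read_csv(_path("acr_families.csv"))
    return tuple(df["family"])


@lru_cache(maxsize=None)
def aca_family_names() -> tuple[str, ...]:
    """The 8 named Aca (HTH) family names."""
    df = pd.read_csv(_path("aca_families.csv"))
    return tuple(df["family"])


@lru_cache(maxsize=None)
def cas_required_genes() -> dict[str, frozenset[str]]:
    """Subtype -> mandatory cas gene set for the completeness check."""
    out: dict[str, frozenset[str]] = {}
    with _path("cas_required_genes.tsv").open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            subtype, genes = line.split("\t")
            out[subtype] = frozenset(g.strip() for g in genes.split(","))
    return out


def published_loci_status() -> pd.DataFrame:
    """The 16 experimentally characterized bacterial Acr-Aca loci and their
    CRISPR-Cas / self-targeting status."""
    return pd.read_csv(_path("published_loci_status.csv"))


def conflict_groups() -> pd.DataFrame:
    """Nonredundant groups of loci whose homology- and self-targeting-based
    subtype assignments disagree (count, families, subtype, unique Acr ids)."""
    return pd.read_csv(_path("conflict_groups.csv"))


def phylum_locus_counts() -> pd.DataFrame:
    """Per-phylum counts of self-targeting-supported Acr-Aca loci."""
    return pd.read_csv(_path("phylum_locus_counts.csv"))


def headline_counts() -> pd.DataFrame:
    """Numerator/denominator pairs behind the study's headline percentages."""
    return pd.read_csv(_path("headline_counts.csv"))
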
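"""End-to-end orchestration of the four discovery steps.

Step 1: Acr homology + guilt-by-association HTH (Aca) discovery.
Step 2: Aca-anchored operon (candidate locus) calling.
Step 3: mobile-genetic-element context filter (skippable, as the accounting
        distinguishes runs with and without it).
Step 4: complete-CRISPR-Cas + self-targeting colocalization filter.

Each step's surviving loci are materialized as TSV so any filter combination
can be audited; a run on identical inputs and config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import genome_io
from .crispr_selftarget import (
    colocalize_loci,
    find_self_targets,
    genome_has_complete_system,
    read_crispr_tsv,
    read_selftarget_table,
)
from .loci import (
    CandidateLocus,
    LocusThresholds,
    build_operons,
    call_candidate_loci,
    discover_aca_by_gba,
    loci_to_table,
)
from .mge import MgeConfig, filter_by_mge
from .report import StratumSummary, strata_table, summarize_strata
from .search import (
    SearchThresholds,
    filter_acr_candidates,
    hth_predicate,
)

logger = logging.getLogger("acrminer")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    gff: str
    proteins_faa: str
    acr_hits: str
    domain_hits: str
    genome_id: str = "genome"
    contigs_fna: str | None = None
    aca_hits: str | None = None
    mge_bed: str | None = None
    crispr_tsv: str | None = None
    selftarget_table: str | None = None
    outdir: str | None = None
    steps_enabled: tuple[int, ...] = (1, 2, 3, 4)
    search: SearchThresholds = field(default_factory=SearchThresholds)
    locus: LocusThresholds = field(default_factory=LocusThresholds)
    mge: MgeConfig = field(default_factory=MgeConfig)
    max_mismatch: int = 2
    log_level: str = "INFO"

    def validate(self) -> None:
        steps = set(self.steps_enabled)
        if not steps <= {1, 2, 3, 4}:
            raise ConfigError(f"unknown steps: {sorted(steps - {1, 2, 3, 4})}")
        if (3 in steps or 4 in steps) and not {1, 2} <= steps:
            raise ConfigError("steps 3 and 4 require steps 1 and 2")
        required = {"gff": self.gff, "proteins_faa": self.proteins_faa,
                    "acr_hits": self.acr_hits, "domain_hits": self.domain_hits}
        if 3 in steps:
            required["mge_bed"] = self.mge_bed
        if 4 in steps:
            if self.selftarget_table is None and self.contigs_fna is None:
                raise ConfigError(
                    "step 4 needs a selftarget_table or contigs_fna for the scan"
                )
            required["crispr_tsv"] = self.crispr_tsv
        for name, path in required.items():
            if path is None:
                raise ConfigError(f"step set {sorted(steps)} requires input {name!r}")
            if not Path(path).exists():
                raise ConfigError(f"input {name!r} not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (("search", SearchThresholds), ("locus", LocusThresholds),
                           ("mge", MgeConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if "steps_enabled" in raw:
            raw["steps_enabled"] = tuple(raw["steps_enabled"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        for key in ("search", "locus", "mge"):
            val = raw[key]
            if "hth_domain_names" in val and val["hth_domain_names"] is not None:
                val["hth_domain_names"] = sorted(val["hth_domain_names"])
        raw["steps_enabled"] = list(self.steps_enabled)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class RunReport:
    loci: dict[str, CandidateLocus]  # locus_id -> most-filtered version
    summaries: list[StratumSummary]
    dropped: dict[str, str]  # locus_id -> first filter that dropped it
    files: dict[str, Path] = field(default_factory=dict)

    def surviving(self, *flags: str) -> list[CandidateLocus]:
        want = set(flags)
        return [lc for lc in self.loci.values() if want <= set(lc.filters_passed)]


def run_pipeline(cfg: RunConfig) -> RunReport:
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    steps = set(cfg.steps_enabled)

    proteins = genome_io.read_fasta(cfg.proteins_faa, "protein")
    lengths = {pid: len(seq) for pid, seq in proteins.items()}
    genes = genome_io.read_gff_genes(cfg.gff, lengths)
    gene_index = {g.protein_id: g for g in genes}
    acr_hit_rows = genome_io.read_tabular_hits(cfg.acr_hits, "blast6")
    domain_rows = genome_io.read_tabular_hits(cfg.domain_hits, "domtbl")
    logger.info("read %d genes, %d acr hits, %d domain hits",
                len(genes), len(acr_hit_rows), len(domain_rows))

    # step 1: homology + GBA
    acr_calls = filter_acr_candidates(acr_hit_rows, gene_index, cfg.search)
    operons = build_operons(genes, cfg.locus)
    hth = hth_predicate(domain_rows, cfg.search)
    aca_ids = discover_aca_by_gba(acr_calls, operons, gene_index, hth, cfg.locus)
    if cfg.aca_hits:
        for h in genome_io.read_tabular_hits(cfg.aca_hits, "blast6"):
            g = gene_index.get(h.subject_id)
            if (g is not None and h.evalue < cfg.search.aca_evalue_max
                    and g.protein_length < cfg.search.max_protein_len):
                aca_ids.add(h.subject_id)
    logger.info("step 1: %d acr calls, %d aca candidates", len(acr_calls), len(aca_ids))

    # step 2: Aca-anchored loci
    loci = call_candidate_loci(operons, aca_ids, acr_calls, cfg.locus, cfg.genome_id)
    registry = {lc.locus_id: lc for lc in loci}
    dropped: dict[str, str] = {}
    current = loci
    logger.info("step 2: %d candidate loci", len(loci))

    if 3 in steps:
        intervals = genome_io.read_mge_bed(cfg.mge_bed)
        kept = filter_by_mge(current, intervals, cfg.mge)
        _note_drops(current, kept, "mge", dropped)
        registry.update({lc.locus_id: lc for lc in kept})
        current = kept
        logger.info("step 3: %d loci within/near MGEs", len(kept))

    if 4 in steps:
        arrays, systems = read_crispr_tsv(cfg.crispr_tsv)
        completeness = genome_has_complete_system(systems, arrays)
        if cfg.selftarget_table:
            events = read_selftarget_table(cfg.selftarget_table)
        else:
            contig_seqs = genome_io.read_fasta(cfg.contigs_fna, "nucleotide")
            contigs = [genome_io.Contig(cid, len(s), s) for cid, s in contig_seqs.items()]
            events = find_self_targets(arrays, contigs, systems, cfg.max_mismatch)
        kept = colocalize_loci(current, events, completeness)
        _note_drops(current, kept, "self_target", dropped)
        registry.update({lc.locus_id: lc for lc in kept})
        current = kept
        logger.info("step 4: %d loci colocalized with self-targets", len(kept))

    summaries = summarize_strata(list(registry.values()))
    report = RunReport(loci=registry, summaries=summaries, dropped=dropped)
    if cfg.outdir:
        report.files = _write_outputs(cfg, report)
    return report


def _note_drops(before: Sequence[CandidateLocus], after: Sequence[CandidateLocus],
                filter_name: str, dropped: dict[str, str]) -> None:
    kept_ids = {lc.locus_id for lc in after}
    for lc in before:
        if lc.locus_id not in kept_ids and lc.locus_id not in dropped:
            dropped[lc.locus_id] = filter_name
            logger.debug("locus %s dropped at filter %s", lc.locus_id, filter_name)


def _write_outputs(cfg: RunConfig, report: RunReport) -> dict[str, Path]:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    stages = {
        "loci_step12.tsv": ("aca_locus",),
        "loci_step123.tsv": ("aca_locus", "mge"),
        "loci_step124.tsv": ("aca_locus", "self_target"),
        "loci_step1234.tsv": ("aca_locus", "mge", "self_target"),
    }
    for fname, flags in stages.items():
        table = loci_to_table(
            sorted(report.surviving(*flags), key=lambda l: l.locus_id)
        )
        path = outdir / fname
        table.to_csv(path, sep="\t", index=False)
        files[fname] = path
    path = outdir / "strata_summary.tsv"
    strata_table(report.summaries).to_csv(path, sep="\t", index=False)
    files["strata_summary.tsv"] = path
    cfg_path = outdir / "run_config.yaml"
    cfg.to_yaml(cfg_path)
    files["run_config.yaml"] = cfg_path
    drops = outdir / "dropped_loci.tsv"
    with open(drops, "w") as fh:
        fh.write("locus_id\tfirst_dropping_filter\n")
        for lid, flt in sorted(report.dropped.items()):
            fh.write(f"{lid}\t{flt}\n")
    files["dropped_loci.tsv"] = drops
    return files
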
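import pytest

from acrminer.pipeline import RunConfig
from acrminer.synthetic import FixtureConfig, generate_synthetic_genome


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle: 3 positives, all decoy classes, seed 7."""
    return generate_synthetic_genome(FixtureConfig())


@pytest.fixture(scope="session")
def bundle_paths(bundle, tmp_path_factory):
    return bundle.write(tmp_path_factory.mktemp("bundle"))


@pytest.fixture()
def run_config(bundle_paths):
    def make(**overrides) -> RunConfig:
        kwargs = dict(
            gff=str(bundle_paths["gff"]),
            proteins_faa=str(bundle_paths["proteins_faa"]),
            acr_hits=str(bundle_paths["acr_hits"]),
            domain_hits=str(bundle_paths["domain_hits"]),
            contigs_fna=str(bundle_paths["contigs_fna"]),
            mge_bed=str(bundle_paths["mge_bed"]),
            crispr_tsv=str(bundle_paths["crispr_tsv"]),
            genome_id="synthetic_genome",
            log_level="WARNING",
        )
        kwargs.update(overrides)
        return RunConfig(**kwargs)

    return make
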
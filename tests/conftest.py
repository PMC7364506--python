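import pytest

from homeoprime import DesignParameters, load_genome_config, run_pipeline
from homeoprime.synthetic_fixtures import (FixtureSpec, generate_fixture,
                                           write_fixture)


@pytest.fixture(scope="session")
def tetraploid_fixture(tmp_path_factory):
    """The reference study condition: 2400 bp gene, homeologues at 93/93/80%
    identity, the 80% one partial from 325 bases into the gene, 1000-base
    flanks, plus a second variety carrying 10 varietal SNPs."""
    spec = FixtureSpec(seed=11, gene_length=2400,
                       homeologue_identities=(0.93, 0.93, 0.80),
                       partial_homologue=(325, 2400 - 325),
                       n_varieties=2, varietal_snp_count=10)
    fx = generate_fixture(spec)
    paths = write_fixture(fx, tmp_path_factory.mktemp("tetra"))
    return fx, paths


@pytest.fixture(scope="session")
def tetraploid_run(tetraploid_fixture):
    fx, paths = tetraploid_fixture
    genomes = load_genome_config(paths["config"])
    result = run_pipeline(fx.input_record, genomes, DesignParameters())
    return fx, result
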
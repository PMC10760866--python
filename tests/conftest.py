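import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """A reduced synthetic genome for fast pipeline tests."""
    from dadsim import synthetic_data as sd

    spec = sd.SyntheticGenomeSpec(n_chromosomes=3, chrom_length=30_000_000,
                                  offset_factor=2.0)
    return sd.synth_genome(spec, seed=2024)


@pytest.fixture(scope="session")
def small_genome_dir(small_genome, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("genome")
    paths = small_genome.write(outdir)
    return paths
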
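import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kinome_evo.synthetic import SynthGenomeConfig, gen_genome


@pytest.fixture(scope="session")
def small_genome():
    """One modest synthetic genome shared by read-only tests."""
    return gen_genome(
        SynthGenomeConfig(
            n_chromosomes=4,
            genes_per_chromosome=120,
            n_tandem_arrays=3,
            tandem_array_size=2,
            n_collinear_blocks=2,
            block_length=6,
            n_decoys=250,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_genome_files(small_genome, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("genome")
    return small_genome.write(outdir)
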
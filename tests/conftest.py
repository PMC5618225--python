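import numpy as np
import pytest

from mdsrna.simulate import GenomeSpec, ReadSimParams, generate_genome, simulate_reads


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def small_genome():
    """An M2-4-like genome: 1723 nt with 87/44-nt terminal extras."""
    spec = GenomeSpec(
        total_length=1723, extra5_length=87, extra3_length=44, seed=7
    )
    return generate_genome(spec, genome_id="m2_4_like")


@pytest.fixture
def small_reads(small_genome):
    genome, _ = small_genome
    return simulate_reads(genome, ReadSimParams(coverage=80.0, seed=11))
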
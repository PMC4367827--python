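import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")

from bactrokit.simulate import (
    GeneSpec,
    GenomeSpec,
    SatelliteArraySpec,
    TransposonSpec,
    build_genome,
    random_sequence,
    simulate_reads,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140101)


@pytest.fixture(scope="session")
def monomer():
    return random_sequence(166, np.random.default_rng(42))


@pytest.fixture(scope="session")
def transposon_seq():
    return random_sequence(1500, np.random.default_rng(43))


@pytest.fixture(scope="session")
def small_genome(monomer, transposon_seq):
    """A 80 kb genome with one satellite array, six transposon copies and
    eight gene segments; the workhorse fixture for unit tests."""
    spec = GenomeSpec(
        length=80_000,
        satellites=[SatelliteArraySpec(monomer=monomer, copies=60)],
        transposon=TransposonSpec(
            sequence=transposon_seq, n_insertions=6, fragmentation_rate=0.3
        ),
        genes=GeneSpec(count=8),
        seed=11,
    )
    genome, truth = build_genome(spec)
    return {"spec": spec, "genome": genome, "truth": truth}


@pytest.fixture(scope="session")
def small_reads(small_genome):
    return simulate_reads(
        small_genome["genome"], depth=25, read_len=100, error_rate=0.0,
        paired=True, seed=12,
    )
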
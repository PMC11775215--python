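import numpy as np
import pytest

from crispramp.simulate import SimConfig, build_default_references


@pytest.fixture(scope="session")
def amps():
    """The bundled synthetic stand-in amplicons for the duplicated loci."""
    return build_default_references()


@pytest.fixture(scope="session")
def amp_a(amps):
    return amps[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cfg():
    return SimConfig(seed=11, n_individuals=2, read_depth=300)


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
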
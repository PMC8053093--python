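import numpy as np
import pytest

from replimut.io import Genome, OriginTable
from replimut.replicon import build_model
from replimut.simulate import SimConfig, SnvSimulator, make_toy_genome


@pytest.fixture(scope="session")
def toy():
    """A deterministic two-chromosome toy genome with origins and planted
    T-homopolymers."""
    return make_toy_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def toy_model(toy):
    return build_model(toy.origins)


@pytest.fixture(scope="session")
def neutral_simulator(toy, toy_model):
    """SNV sampler with no strand asymmetry (all odds 1)."""
    cfg = SimConfig(seed=1, asymmetry={})
    return SnvSimulator(toy.genome, toy_model, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def flat_genome():
    """A small hand-made genome for arithmetic-level checks."""
    seq = "".join(
        np.random.default_rng(7).choice(list("ACGT"), size=3000)
    )
    return Genome({"chrT": seq})


@pytest.fixture()
def two_origin_table():
    """Origins whose ARS midpoints are 100 and 1900 on one chromosome."""
    return OriginTable({"chrT": [(90, 110), (1890, 1910)]})
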
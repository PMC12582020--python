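import numpy as np
import pytest
from hypothesis import settings

from nanotrna.reference import TRNAGeneRecord
from nanotrna.simulate import SimulationConfig, Simulator

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_gene(gene_id, sequence, isotype="Gly", anticodon="GCC", labels=None):
    return TRNAGeneRecord(
        gene_id=gene_id,
        sequence=sequence,
        isotype=isotype,
        anticodon=anticodon,
        sprinzl_labels=labels,
    )


@pytest.fixture(scope="session")
def sim():
    """Default-condition simulator with a fixed seed."""
    return Simulator(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A moderate full dataset (reference, SAMs, bedMethyls, truth)."""
    out = tmp_path_factory.mktemp("simdata")
    simulator = Simulator(SimulationConfig(seed=1, reads_per_sample=3000))
    manifest = simulator.write_all(out)
    return simulator, manifest, out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
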
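import pytest

from g4families.config import RunConfig
from g4families.model import G4FamilyModel
from g4families.simulate import SimConfig, simulate_families


@pytest.fixture(scope="session")
def sim_benchmark():
    """The standard synthetic benchmark: 5 families x 20 members."""
    seqs, truth, templates = simulate_families(SimConfig(seed=1))
    return seqs, truth, templates


@pytest.fixture(scope="session")
def fitted_results(sim_benchmark):
    """One fitted family model shared across tests (deterministic)."""
    seqs, truth, _ = sim_benchmark
    return G4FamilyModel(seqs, RunConfig()).fit()
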
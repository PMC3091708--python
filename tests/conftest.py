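import pytest

from ventannot.frames import FrameCall
from ventannot.synthetic import (SimulationConfig, simulate_contigs,
                                 simulate_hits, simulate_ontology,
                                 simulate_taxonomy)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_contigs=80)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    contigs, truth = simulate_contigs(small_config)
    hits = simulate_hits(contigs, truth, small_config)
    return contigs, truth, hits


@pytest.fixture(scope="session")
def dag():
    return simulate_ontology(n_terms=120, max_parents=2, seed=3)


@pytest.fixture(scope="session")
def taxonomy():
    return simulate_taxonomy(depth=4, breadth=3, seed=5)


def truth_calls(contigs, truth, tier="strict"):
    """Frame calls straight from ground truth (for training tests)."""
    return {
        c.id: FrameCall(c.id, truth.frames[c.id], tier, "", 1e-9)
        for c in contigs if truth.frames.get(c.id, 0) != 0
    }
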
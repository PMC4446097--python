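import numpy as np
import pytest

from splicecons import SimulationConfig, simulate_exon_array


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small three-group dataset with injected consistent events."""
    config = SimulationConfig(
        n_transcripts=60,
        exons_per_transcript=5,
        probes_per_exon=4,
        groups=[("caseA", 4), ("caseB", 4), ("ctrl", 8)],
        n_consistent_events_per_group=8,
        p_share=0.9,
        n_random_events=30,
        seed=1234,
    )
    matrix, truth = simulate_exon_array(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Event-free dataset: pure additive structure plus noise."""
    config = SimulationConfig(
        n_transcripts=50,
        exons_per_transcript=4,
        probes_per_exon=4,
        groups=[("a", 5), ("b", 5)],
        seed=99,
    )
    matrix, truth = simulate_exon_array(config)
    return config, matrix, truth
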
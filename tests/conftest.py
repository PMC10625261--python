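import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from tetrack.core import PipelineParams
from tetrack.simulate import default_family_specs, simulate_genome


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def small_sim():
    """A compact zero-divergence simulation shared across unit tests:
    two 250-kb chromosomes, five families, four copies each, no
    fragmentation."""
    specs = default_family_specs(divergence=0.0, fragmentation_rate=0.0, copy_number=4)
    genome, truth = simulate_genome({"chr1": 250_000, "chr2": 250_000}, specs, seed=7)
    return genome, truth


@pytest.fixture(scope="session")
def study_sim():
    """The discovery-scale simulation: a two-chromosome 2-Mb genome with
    five families at ten copies each, zero divergence, 30% fragmentation."""
    specs = default_family_specs(divergence=0.0, fragmentation_rate=0.3, copy_number=10)
    genome, truth = simulate_genome({"chr1": 1_000_000, "chr2": 1_000_000}, specs, seed=20260101)
    return genome, truth
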
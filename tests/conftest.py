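import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from earphase.synthdata import SimulationConfig, simulate_experiment, simulate_genetic_maps


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment shared across read-only tests."""
    return simulate_experiment(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_maps():
    return simulate_genetic_maps(SimulationConfig(seed=0))
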
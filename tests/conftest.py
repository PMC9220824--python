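import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from isletpulse.synthetic import (  # noqa: E402
    TraceSimConfig, make_abundance_table, make_genomic_fixture,
    simulate_ramp_traces,
)


@pytest.fixture(scope="session")
def small_ramp():
    """A small but realistic ramp simulation shared across tests."""
    config = TraceSimConfig(seed=42, n_islets_per_group=4, n_animals_per_group=2)
    traces, truth = simulate_ramp_traces(config)
    return config, traces, truth


@pytest.fixture(scope="session")
def genomic_fixture():
    return make_genomic_fixture(40, seed=7)


@pytest.fixture(scope="session")
def abundance_fixture():
    table, truth = make_abundance_table(
        600, planted_up=25, planted_down=12, seed=3
    )
    return table, truth
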
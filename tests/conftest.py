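import random

import pytest

from coiauth import (
    ReferencePanel,
    ReferenceRecord,
    SimulationConfig,
    default_rules,
    load_fixture,
    simulate_panel,
)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def fixture_all(rules):
    return load_fixture("all", rules)


@pytest.fixture(scope="session")
def small_panel():
    """Three well-diverged synthetic reference species at default length."""
    panel, _ = simulate_panel(SimulationConfig(seed=42, n_species=3))
    return panel


@pytest.fixture()
def rng():
    return random.Random(12345)


@pytest.fixture()
def tiny_panel():
    """Hand-built panel with two species sharing one genus, for rank rules."""
    return ReferencePanel(
        records=[
            ReferenceRecord("A1", "Alpha one", "Alpha", "Alphidae", "ACGT" * 120),
            ReferenceRecord("A2", "Alpha two", "Alpha", "Alphidae", "TGCA" * 120),
            ReferenceRecord("B1", "Beta one", "Beta", "Betidae", "AATT" * 120),
        ]
    )
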
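import pytest

from mendelseek.splice_consensus import builtin_scorers
from mendelseek.synthetic_data import (
    SimulationConfig,
    build_transcript_fixture,
    simulate_cohort,
)
from mendelseek.variant_io import load_table1


@pytest.fixture(scope="session")
def model():
    """The constraint-built EZH2-like transcript model."""
    m, _ = build_transcript_fixture()
    return m


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def scorers():
    return builtin_scorers()


@pytest.fixture(scope="session")
def cohort11():
    """The default 4-case discovery cohort at seed 11 (in memory)."""
    return simulate_cohort(SimulationConfig(seed=11))
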
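import datetime as dt

import pytest
from hypothesis import settings

from ppx.claims import InpatientStay, parse_claims, stays_to_frame
from ppx.config import SimulationConfig
from ppx.simulate import simulate_population

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def make_stay(patient_id="P1", age=30, admission="2010-06-01", los=5,
              primary="O80", assoc=(), procs=()):
    """Terse stay builder for hand-crafted fixtures."""
    return InpatientStay(
        patient_id=patient_id, age_years=age, sex="F",
        admission_date=admission, length_of_stay=los, primary_dx=primary,
        associated_dx=tuple(assoc), procedures=tuple(procs))


@pytest.fixture
def build_claims():
    """Factory turning stay specs into a parsed claims table."""
    def _build(stays):
        return parse_claims(stays_to_frame(stays))
    return _build


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_women=15_000, seed=11)


@pytest.fixture(scope="session")
def sim_claims(sim_config):
    """One moderately sized seeded population shared across tests."""
    return simulate_population(sim_config)


@pytest.fixture(scope="session")
def sim_parsed(sim_claims):
    return parse_claims(sim_claims)


@pytest.fixture(scope="session")
def five_year_span():
    return dt.date(2007, 1, 1), dt.date(2011, 12, 31)
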
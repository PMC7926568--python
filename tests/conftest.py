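import logging
from importlib import resources
from pathlib import Path

import pytest

from hwfplan.fixtures import (
    SyntheticSpec,
    generate_synthetic_scenario,
    ghana_printed_fixture,
    known_answer_scenario,
)

# warnings from intentionally degenerate inputs clutter test output
logging.getLogger("hwfplan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ghana():
    return ghana_printed_fixture()


@pytest.fixture()
def known():
    """(scenario, expected) pair with hand-derivable results; fresh per test."""
    return known_answer_scenario()


@pytest.fixture(scope="session")
def demo_config_path() -> Path:
    return Path(str(resources.files("hwfplan") / "data" / "synthetic_demo" / "scenario.yaml"))


@pytest.fixture()
def small_scenario():
    """A compact random-but-valid scenario for orchestration tests."""
    return generate_synthetic_scenario(
        SyntheticSpec(seed=42, n_age_cohorts=3, n_locations=2, n_services=4, horizon_years=5)
    )
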
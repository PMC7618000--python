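import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from dcmburden import FilterConfig, fixture_table1_cohort, fixture_ukb_cohort


@pytest.fixture(scope="session")
def table1():
    """In-memory deterministic 830-sample cohort and its manifest."""
    return fixture_table1_cohort()


@pytest.fixture(scope="session")
def ukb():
    """In-memory deterministic 1,304-case validation cohort and manifest."""
    return fixture_ukb_cohort()


@pytest.fixture(scope="session")
def filter_cfg():
    return FilterConfig()
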
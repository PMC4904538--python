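import pytest

from mesoapportion import (
    CaseConfig,
    RoundingMode,
    example_config,
    example_history,
)


@pytest.fixture(scope="session")
def table1_entries():
    """The built-in 8-entry worked example (diagnosis 2013)."""
    return example_history()


@pytest.fixture(scope="session")
def paper_config():
    """Diagnosis 2013, lag 10, exponent 2, per-entry integer truncation."""
    return example_config(RoundingMode.PAPER_TRUNCATE)


@pytest.fixture(scope="session")
def exact_config():
    return CaseConfig(diagnosis_year=2013)
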
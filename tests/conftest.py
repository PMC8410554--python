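import pytest

from valk.filtering import FilterConfig, run_filter
from valk.fixtures import table2_fixture


@pytest.fixture(scope="session")
def default_config():
    return FilterConfig()


@pytest.fixture(scope="session")
def cohort(default_config):
    """The embedded 28-sample cohort with verdicts under default config."""
    tables, dpcr_ref = table2_fixture(default_config)
    verdicts = [(t, run_filter(t, default_config)) for t in tables]
    return verdicts, dpcr_ref
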
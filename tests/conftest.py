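import pytest

from ifmiecon import ParameterSet, load_parameters


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    """The published base case, via the packaged default configuration."""
    return load_parameters()
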
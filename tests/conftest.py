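import pytest

from scoliscreen import CascadeCounts, default_parameters


@pytest.fixture(scope="session")
def params():
    """Base-case parameter set with derived per-cycle probabilities filled."""
    return default_parameters().with_derived().validate()


@pytest.fixture(scope="session")
def program_counts():
    """The screening program's observed cascade counts."""
    return CascadeCounts(
        n_screened=52678, n_suspected=1211, n_xrayed=336,
        n_mild=118, n_moderate=41, n_severe=13, n_braced=37,
    )
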
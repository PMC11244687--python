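import matplotlib

matplotlib.use("Agg")

import pytest

from tg51mc.scenarios import build_scenario


@pytest.fixture(scope="session")
def run_6mv():
    """Full-budget 6 MV run at n=1e6, shared across tests."""
    return build_scenario("6MV").run(n=10**6, seed=1)


@pytest.fixture(scope="session")
def run_6mev():
    """Full-budget 6 MeV electron run at n=5e5, shared across tests."""
    return build_scenario("6MeV").run(n=5 * 10**5, seed=1)
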
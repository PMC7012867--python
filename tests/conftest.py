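import pytest

from antnet.io_formats import InteractionNetwork
from antnet.synthetic_data import ScenarioConfig, generate_bundle


def make_network(edges, nodes=()):
    return InteractionNetwork.from_edges(edges, nodes)


@pytest.fixture(scope="session")
def demo_bundle():
    """Default desk-scale scenario; shared read-only across tests."""
    return generate_bundle(ScenarioConfig(rng_seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    """A smaller, faster bundle for stages that iterate."""
    return generate_bundle(
        ScenarioConfig(n_template_proteins=150, n_template_edges=450, rng_seed=7)
    )
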
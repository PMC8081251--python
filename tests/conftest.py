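import numpy as np
import pytest

from netmse.io_contacts import ContactEventList
from netmse.netmodel import ModelConfig, generate_network


@pytest.fixture
def small_events():
    """Pair {a,b} active at t=1 and t=3; pair {a,c} at t=3."""
    return ContactEventList.from_records([(1, "a", "b"), (3, "a", "b"), (3, "a", "c")])


@pytest.fixture(scope="session")
def sim_network():
    """One reference-configuration simulator run, shared across tests."""
    return generate_network(ModelConfig(seed=1))


@pytest.fixture(scope="session")
def sim_two_day_events(sim_network):
    """Two simulated days concatenated into one event stream (T=2000 each)."""
    second = generate_network(ModelConfig(seed=2))
    records = list(sim_network.events)
    records += [(t + 2000, i, j) for t, i, j in second.events]
    return ContactEventList.from_records(records)


def random_event_records(rng, n_nodes=6, t_max=12, n_events=15):
    nodes = [chr(ord("a") + k) for k in range(n_nodes)]
    recs = []
    for _ in range(n_events):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        recs.append((int(rng.integers(1, t_max + 1)), nodes[i], nodes[j]))
    return recs
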
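import numpy as np
import pytest

from symptomnet import IsingNetwork


def make_random_network(
    p: int,
    seed: int,
    edge_prob: float = 0.5,
    weight_low: float = -1.0,
    weight_high: float = 1.0,
    threshold_low: float = -1.0,
    threshold_high: float = 1.0,
    community_split: int | None = None,
) -> IsingNetwork:
    """Seeded random network; communities split at ``community_split``."""
    rng = np.random.default_rng(seed)
    labels = [f"s{i + 1}" for i in range(p)]
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                w[i, j] = w[j, i] = rng.uniform(weight_low, weight_high)
    tau = rng.uniform(threshold_low, threshold_high, size=p)
    split = community_split if community_split is not None else p // 2
    community = {lab: ("A" if i < split else "B") for i, lab in enumerate(labels)}
    return IsingNetwork(labels, tau, w, community)


@pytest.fixture
def random_network():
    return make_random_network


@pytest.fixture
def two_node_ln2():
    """Hand-enumerable 2-node network: tau = 0, omega12 = ln 2.

    Unnormalized state weights are (1, 1, 1, 2), so Z = 5 and
    P(1,1) = 2/5 while each other state has probability 1/5.
    """
    return IsingNetwork(
        ["a", "b"], np.zeros(2), np.array([[0.0, np.log(2)], [np.log(2), 0.0]])
    )
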
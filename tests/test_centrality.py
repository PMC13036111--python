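"""Expected influence, bridge indices, bootstrap stability, CS coefficient."""

import numpy as np
import pandas as pd
import pytest

from symptomnet import (
    BinaryDataset,
    IsingNetwork,
    StabilityResult,
    bridge_indices,
    case_drop_bootstrap,
    cs_coefficient,
    expected_influence,
    sample_exact,
)
from .conftest import make_random_network
from .oracles import oracle_bridge_centrality

FAST_ESTIMATOR = {"grid_size": 20}


def net_from_edges(labels, edges, community, tau=None):
    p = len(labels)
    w = np.zeros((p, p))
    idx = {lab: i for i, lab in enumerate(labels)}
    for a, b, weight in edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = weight
    tau = np.zeros(p) if tau is None else np.asarray(tau)
    return IsingNetwork(labels, tau, w, community)


class TestExpectedInfluence:
    def test_signed_sum_of_incident_weights(self):
        net = net_from_edges(
            ["x", "a", "b", "c"],
            [("x", "a", 0.5), ("x", "b", 0.3), ("x", "c", -0.2)],
            {"x": "A", "a": "B", "b": "B", "c": "B"},
        )
        assert expected_influence(net)["x"] == pytest.approx(0.6)

    def test_edgeless_network_all_zero(self):
        net = net_from_edges(list("ab"), [], {"a": "A", "b": "B"})
        assert (expected_influence(net) == 0).all()

    def test_permutation_equivariance(self, random_network):
        net = random_network(6, seed=21)
        order = [5, 2, 0, 1, 4, 3]
        ei = expected_influence(net)
        ei_perm = expected_influence(net.permute(order))
        for lab in net.item_labels:
            assert ei_perm[lab] == pytest.approx(ei[lab])


class TestBridgeIndices:
    def test_strength_and_ei_by_definition(self):
        net = net_from_edges(
            ["x", "y", "o1", "o2"],
            [("x", "o1", 0.4), ("x", "o2", -0.1), ("x", "y", 0.9)],
            {"x": "A", "y": "A", "o1": "B", "o2": "B"},
        )
        table = bridge_indices(net)
        assert table.loc["x", "bridge_strength"] == pytest.approx(0.5)
        assert table.loc["x", "bridge_expected_influence"] == pytest.approx(0.3)

    def test_three_node_path_betweenness(self):
        net = net_from_edges(
            ["A1", "B1", "B2"],
            [("A1", "B1", 0.5), ("B1", "B2", 0.5)],
            {"A1": "A", "B1": "B", "B2": "B"},
        )
        table = bridge_indices(net)
        assert table.loc["B1", "bridge_betweenness"] == pytest.approx(1.0)
        assert table.loc["A1", "bridge_betweenness"] == 0.0
        assert table.loc["B2", "bridge_betweenness"] == 0.0

    def test_isolated_node_scores_zero_everywhere(self):
        net = net_from_edges(
            ["iso", "a", "b"],
            [("a", "b", 0.7)],
            {"iso": "A", "a": "A", "b": "B"},
        )
        table = bridge_indices(net)
        raw = [c for c in table.columns if not c.startswith("z_")]
        assert (table.loc["iso", raw] == 0).all()

    def test_single_community_rejected(self):
        net = net_from_edges(["a", "b"], [("a", "b", 0.5)],
                             {"a": "A", "b": "A"})
        with pytest.raises(ValueError, match="two communities"):
            bridge_indices(net)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        net = make_random_network(p=4 + seed % 7, seed=seed, edge_prob=0.45)
        table = bridge_indices(net)
        comms = np.array([net.community[lab] for lab in net.item_labels])
        oracle = oracle_bridge_centrality(net.weights, comms)
        for name, values in oracle.items():
            np.testing.assert_allclose(
                table[name].to_numpy(), values, atol=1e-8, err_msg=name
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_strength_bounds_expected_influence(self, seed):
        net = make_random_network(p=7, seed=100 + seed)
        table = bridge_indices(net)
        assert (
            table["bridge_strength"]
            >= table["bridge_expected_influence"].abs() - 1e-12
        ).all()

    def test_all_positive_weights_make_strength_equal_ei(self):
        net = make_random_network(p=7, seed=5, weight_low=0.1, weight_high=1.0)
        table = bridge_indices(net)
        np.testing.assert_allclose(
            table["bridge_strength"], table["bridge_expected_influence"]
        )

    def test_z_columns_are_standardized(self, random_network):
        table = bridge_indices(random_network(8, seed=33))
        z = table["z_bridge_strength"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def data():
    net = make_random_network(
        p=5, seed=77, edge_prob=0.6, weight_low=0.5, weight_high=1.2,
        threshold_low=-1.0, threshold_high=0.0,
    )
    samples = sample_exact(net, 400, seed=2)
    return BinaryDataset(
        samples.draws.astype(int), list(net.item_labels),
        community=dict(net.community),
    )


class TestCaseDropBootstrap:
    def test_full_sample_limit_has_correlation_one(self, data):
        # drop proportion so small the subsample is the full sample
        result = case_drop_bootstrap(
            data, index="bridge_strength", drop_proportions=[0.001], B=2,
            seed=1, estimator_config=FAST_ESTIMATOR,
        )
        np.testing.assert_allclose(result.correlations(0.001), 1.0)

    def test_seeded_determinism(self, data):
        kwargs = dict(
            index="bridge_expected_influence", drop_proportions=[0.2, 0.4],
            B=3, seed=9, estimator_config=FAST_ESTIMATOR,
        )
        a = case_drop_bootstrap(data, **kwargs)
        b = case_drop_bootstrap(data, **kwargs)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_constant_index_recorded_as_failed(self):
        # independent noise at small n: the estimated network is empty, the
        # index is constant, correlation undefined -> every replicate fails
        rng = np.random.default_rng(0)
        data = BinaryDataset(
            rng.integers(0, 2, size=(120, 4)), list("abcd"),
            community={"a": "A", "b": "A", "c": "B", "d": "B"},
        )
        result = case_drop_bootstrap(
            data, index="bridge_strength", drop_proportions=[0.3], B=2,
            seed=4, estimator_config=FAST_ESTIMATOR,
        )
        assert result.n_failed == 2
        assert result.correlations(0.3).size == 0

    def test_invalid_proportions_rejected(self, data):
        with pytest.raises(ValueError):
            case_drop_bootstrap(data, drop_proportions=[0.0], B=1)


class TestCsCoefficient:
    def make_stability(self, table):
        rows = []
        for q, cors in table.items():
            for b, c in enumerate(cors):
                rows.append((q, b, c, not np.isfinite(c)))
        records = pd.DataFrame(
            rows, columns=["proportion", "replicate", "correlation", "failed"]
        )
        return StabilityResult(
            index="bridge_strength",
            drop_proportions=np.array(sorted(table)),
            records=records,
        )

    def test_perfect_correlations_reach_grid_maximum(self):
        grid = np.round(np.arange(0.05, 0.751, 0.05), 2)
        stability = self.make_stability({q: [1.0, 1.0] for q in grid})
        assert cs_coefficient(stability) == 0.75

    def test_all_below_threshold_gives_zero(self):
        stability = self.make_stability({0.1: [0.5, 0.6], 0.2: [0.4, 0.3]})
        assert cs_coefficient(stability) == 0.0

    def test_non_monotone_profile_stops_at_first_failure(self):
        table = {q: [1.0] * 10 for q in (0.05, 0.10, 0.15, 0.20, 0.25, 0.35)}
        table[0.30] = [0.5] * 10  # fails here, passes again at 0.35
        assert cs_coefficient(self.make_stability(table)) == 0.25

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(1)
        cors = list(rng.uniform(0.5, 1.0, size=20))
        a = self.make_stability({0.1: cors})
        b = self.make_stability({0.1: cors[::-1]})
        assert cs_coefficient(a) == cs_coefficient(b)

    def test_prob_threshold_is_respected(self):
        # 94% of replicates pass at 0.1 -> below the 95% requirement
        cors = [1.0] * 94 + [0.0] * 6
        assert cs_coefficient(self.make_stability({0.1: cors})) == 0.0
        cors = [1.0] * 95 + [0.0] * 5
        assert cs_coefficient(self.make_stability({0.1: cors})) == 0.1
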
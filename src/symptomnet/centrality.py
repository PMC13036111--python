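"""Expected influence, bridge centrality, and case-dropping stability.

Bridge indices quantify how strongly each symptom connects its own
community to the other community, relative to a fixed partition (here
the two instruments, not a detected clustering):

* bridge strength:            sum of |omega_ij| over cross-community edges of i
* bridge expected influence:  the same sum without absolute values (signed)
* bridge betweenness:         number of shortest paths between cross-community
                              node pairs passing through i (fractional when
                              shortest paths tie)
* bridge closeness:           inverse mean shortest-path distance from i to
                              all nodes outside its community

Shortest paths use the network-psychometrics distance convention: edge
length = 1 / |omega|; absent (zero-weight) pairs are non-adjacent.  A
node with no path to any outside node gets closeness 0; an isolated node
scores 0 on every index.

Stability of an index is assessed by case-dropping bootstrap: drop a
proportion of persons, re-estimate the whole network, recompute the
index, and correlate (Spearman) with the full-sample index.  The CS
coefficient is the largest drop proportion at which at least 95% of
replicates still correlate >= 0.7.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datasets import BinaryDataset
from .estimation import DegenerateItemError, estimate_network
from .network import IsingNetwork

BRIDGE_INDEX_NAMES = (
    "bridge_strength",
    "bridge_expected_influence",
    "bridge_betweenness",
    "bridge_closeness",
)


def expected_influence(network: IsingNetwork) -> pd.Series:
    """One-step expected influence: signed sum of each node's incident weights."""
    return pd.Series(
        network.weights.sum(axis=1), index=network.item_labels, name="expected_influence"
    )


def _distance_graph(network: IsingNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.item_labels)
    for i in range(network.p):
        for j in range(i + 1, network.p):
            w = network.weights[i, j]
            if w != 0.0:
                g.add_edge(
                    network.item_labels[i],
                    network.item_labels[j],
                    weight=w,
                    length=1.0 / abs(w),
                )
    return g


def _resolve_partition(network: IsingNetwork, partition) -> dict[str, str]:
    part = dict(partition) if partition is not None else dict(network.community)
    missing = [lab for lab in network.item_labels if lab not in part]
    if missing:
        raise KeyError(f"items without a community assignment: {missing}")
    if len(set(part[lab] for lab in network.item_labels)) < 2:
        raise ValueError("bridge centrality requires at least two communities")
    return part


def _zscore(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=1) if col.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(col, dtype=float)
    return (col - col.mean()) / sd


def bridge_indices(
    network: IsingNetwork, partition: dict[str, str] | None = None
) -> pd.DataFrame:
    """All four bridge indices plus one-step EI, raw and z-standardized.

    Betweenness counts each unordered cross-community pair once; when a
    pair has several equal-length shortest paths, the unit count is
    split equally among them (so interior nodes earn fractional
    credit).
    """
    part = _resolve_partition(network, partition)
    labels = network.item_labels
    w = network.weights
    comms = np.array([part[lab] for lab in labels])
    cross = comms[:, None] != comms[None, :]

    strength = np.abs(w * cross).sum(axis=1)
    bridge_ei = (w * cross).sum(axis=1)

    g = _distance_graph(network)
    betweenness = dict.fromkeys(labels, 0.0)
    for i in range(network.p):
        for j in range(i + 1, network.p):
            if not cross[i, j]:
                continue
            s, t = labels[i], labels[j]
            try:
                paths = list(nx.all_shortest_paths(g, s, t, weight="length"))
            except nx.NetworkXNoPath:
                continue
            share = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    betweenness[v] += share

    closeness = np.zeros(network.p)
    for i, lab in enumerate(labels):
        dists = nx.single_source_dijkstra_path_length(g, lab, weight="length")
        outside = [labels[j] for j in range(network.p) if cross[i, j]]
        d = [dists.get(o, math.inf) for o in outside]
        mean_d = float(np.mean(d))
        closeness[i] = 0.0 if not math.isfinite(mean_d) or mean_d == 0 else 1.0 / mean_d

    result = pd.DataFrame(
        {
            "expected_influence": expected_influence(network).to_numpy(),
            "bridge_strength": strength,
            "bridge_expected_influence": bridge_ei,
            "bridge_betweenness": np.array([betweenness[lab] for lab in labels]),
            "bridge_closeness": closeness,
        },
        index=pd.Index(labels, name="Item"),
    )
    for col in list(result.columns):
        result[f"z_{col}"] = _zscore(result[col].to_numpy())
    return result


@dataclass
class StabilityResult:
    """Case-dropping bootstrap correlations for one centrality index."""

    index: str
    drop_proportions: np.ndarray
    #: tidy table: proportion, replicate, correlation (NaN when failed), failed
    records: pd.DataFrame
    n_failed: int = field(default=0)

    def correlations(self, proportion: float) -> np.ndarray:
        rows = self.records[
            np.isclose(self.records["proportion"], proportion)
            & ~self.records["failed"]
        ]
        return rows["correlation"].to_numpy()


def _index_values(
    binary: BinaryDataset, index: str, partition, estimator_config: dict
) -> pd.Series:
    net = estimate_network(binary, **estimator_config)
    if index == "expected_influence":
        return expected_influence(net)
    if index in BRIDGE_INDEX_NAMES:
        return bridge_indices(net, partition)[index]
    raise ValueError(f"unknown centrality index: {index!r}")


def case_drop_bootstrap(
    binary: BinaryDataset,
    index: str = "bridge_expected_influence",
    partition: dict[str, str] | None = None,
    drop_proportions=None,
    B: int = 500,
    seed: int = 0,
    estimator_config: dict | None = None,
) -> StabilityResult:
    """Stability of a centrality index under person subsampling.

    For each drop proportion q and replicate, ceil((1-q) n) persons are
    subsampled without replacement, the network is re-estimated from
    scratch, and the index's Spearman correlation with the full-sample
    index is recorded.  Replicates where estimation fails (degenerate
    column) or the correlation is undefined (constant index) are
    recorded as failed, counted, and excluded from summaries.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if drop_proportions is None:
        drop_proportions = np.round(np.arange(0.05, 0.751, 0.05), 2)
    drop_proportions = np.asarray(drop_proportions, dtype=float)
    if np.any((drop_proportions <= 0) | (drop_proportions >= 1)):
        raise ValueError("drop proportions must lie in (0, 1)")
    config = dict(estimator_config or {})

    full = _index_values(binary, index, partition, config)
    n = binary.n_persons
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for q in drop_proportions:
        m = math.ceil((1.0 - q) * n)
        for b in range(B):
            keep = rng.choice(n, size=m, replace=False)
            sub = BinaryDataset(
                values=binary.values[keep],
                item_labels=list(binary.item_labels),
                community=dict(binary.community),
            )
            try:
                vals = _index_values(sub, index, partition, config)
                with warnings.catch_warnings():
                    # constant index -> undefined correlation -> failed replicate
                    warnings.simplefilter("ignore")
                    rho = spearmanr(full.to_numpy(), vals.to_numpy()).statistic
                failed = not np.isfinite(rho)
            except DegenerateItemError:
                rho, failed = np.nan, True
            if failed:
                n_failed += 1
                rho = np.nan
            rows.append((q, b, rho, failed))
    records = pd.DataFrame(
        rows, columns=["proportion", "replicate", "correlation", "failed"]
    )
    return StabilityResult(
        index=index,
        drop_proportions=drop_proportions,
        records=records,
        n_failed=n_failed,
    )


def cs_coefficient(
    stability: StabilityResult, cor_threshold: float = 0.7, prob: float = 0.95
) -> float:
    """Correlation-stability coefficient.

    The largest tested drop proportion q such that, at every tested
    proportion <= q, the fraction of successful replicates correlating
    >= ``cor_threshold`` with the full-sample index is >= ``prob``.
    Returns 0 when no proportion qualifies.  A proportion with no
    successful replicates does not qualify.
    """
    cs = 0.0
    for q in np.sort(stability.drop_proportions):
        cors = stability.correlations(q)
        if cors.size == 0:
            break
        if np.mean(cors >= cor_threshold) >= prob:
            cs = float(q)
        else:
            break
    return cs
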
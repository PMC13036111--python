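"""Simulated network interventions by threshold perturbation.

Each candidate symptom is "treated" by shifting its activation
threshold down (alleviating) or up (aggravating) by a multiple —
two, by convention — of the standard deviation of the network's
threshold vector.  Large samples are then simulated from the original
and each perturbed network, a sum score over a designated outcome item
set summarizes each simulated observation, and candidates are ranked by
the absolute change in mean sum score.  Welch t-tests with
Benjamini-Hochberg FDR correction (within direction) attach
significance to each projected effect.

This is a computational prediction about network structure: it ranks
targets by projected leverage, it does not evaluate any concrete
clinical technique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distribution import (
    ENUMERATION_CAP,
    SampleSet,
    sample_exact,
    sample_gibbs,
    spawn_seeds,
    sum_scores,
)
from .network import IsingNetwork

DIRECTIONS = ("alleviating", "aggravating")


@dataclass
class InterventionScenario:
    """One perturbed network: a target symptom and a direction."""

    target: str
    direction: str
    sd_multiplier: float
    perturbed_network: IsingNetwork


def perturb_threshold(
    network: IsingNetwork,
    target: str,
    direction: str,
    sd_multiplier: float = 2.0,
) -> InterventionScenario:
    """Shift one symptom's threshold by +/- sd_multiplier * SD(tau).

    The SD is the sample standard deviation (denominator p - 1) of the
    full threshold vector across nodes — the scale on which thresholds
    vary in this network.  Only the target's threshold changes.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if network.p < 2:
        raise ValueError("threshold SD undefined for p < 2")
    j = network.index(target)
    sd = float(network.thresholds.std(ddof=1))
    perturbed = network.copy()
    sign = -1.0 if direction == "alleviating" else 1.0
    perturbed.thresholds[j] += sign * sd_multiplier * sd
    return InterventionScenario(
        target=target,
        direction=direction,
        sd_multiplier=sd_multiplier,
        perturbed_network=perturbed,
    )


def _simulate(network: IsingNetwork, n_sim: int, seed: int) -> SampleSet:
    if network.p <= ENUMERATION_CAP:
        return sample_exact(network, n_sim, seed)
    return sample_gibbs(network, n_sim, seed)


def simulate_scenario(
    scenario: InterventionScenario,
    outcome_items,
    n_sim: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Sum scores of n_sim observations drawn from the perturbed network."""
    samples = _simulate(scenario.perturbed_network, n_sim, seed)
    return sum_scores(samples, outcome_items)


def _welch(perturbed: np.ndarray, baseline: np.ndarray):
    """Welch t on perturbed vs baseline; (t, p, ci_low, ci_high).

    When both samples have zero variance the statistic is undefined; by
    policy t = NaN and p = 1 (no evidence of an effect), with a
    degenerate CI at the mean difference.
    """
    if perturbed.std() == 0.0 and baseline.std() == 0.0:
        d = float(perturbed.mean() - baseline.mean())
        return np.nan, 1.0, d, d
    res = stats.ttest_ind(perturbed, baseline, equal_var=False)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(res.pvalue), float(ci.low), float(ci.high)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment of a p-value vector."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def compare_scenarios(
    baseline: np.ndarray, results: dict[tuple[str, str], np.ndarray]
) -> pd.DataFrame:
    """Test and rank scenarios against the shared baseline sum scores.

    BH adjustment is applied across candidate targets within each
    direction; ranks order |mean difference| (1 = largest) within each
    direction, ties broken by table order.
    """
    baseline = np.asarray(baseline, dtype=float)
    rows = []
    for (target, direction), sums in results.items():
        sums = np.asarray(sums, dtype=float)
        t, p, lo, hi = _welch(sums, baseline)
        rows.append(
            {
                "target": target,
                "direction": direction,
                "baseline_mean": baseline.mean(),
                "perturbed_mean": sums.mean(),
                "mean_difference": sums.mean() - baseline.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    table["rank"] = 0
    for direction in table["direction"].unique():
        mask = table["direction"] == direction
        table.loc[mask, "p_adjusted"] = bh_adjust(table.loc[mask, "p"].to_numpy())
        order = np.argsort(
            -np.abs(table.loc[mask, "mean_difference"].to_numpy()), kind="stable"
        )
        ranks = np.empty(order.size, dtype=int)
        ranks[order] = np.arange(1, order.size + 1)
        table.loc[mask, "rank"] = ranks
    return table


def run_nira(
    network: IsingNetwork,
    candidate_items,
    outcome_items,
    directions=DIRECTIONS,
    n_sim: int = 5000,
    master_seed: int = 0,
    sd_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Full intervention screen: baseline plus one scenario per (target, direction).

    The baseline is simulated once and shared across all comparisons.
    Each simulation gets an independent sub-seed derived from
    ``master_seed`` by a counter scheme, so the whole run is
    reproducible while scenarios stay independent.
    """
    candidate_items = list(candidate_items)
    outcome_items = list(outcome_items)
    if not candidate_items or not outcome_items:
        raise ValueError("candidate_items and outcome_items must be nonempty")
    scenarios = [
        (target, direction) for direction in directions for target in candidate_items
    ]
    seeds = spawn_seeds(master_seed, len(scenarios) + 1)
    baseline = sum_scores(_simulate(network, n_sim, seeds[0]), outcome_items)
    results = {}
    for k, (target, direction) in enumerate(scenarios):
        scenario = perturb_threshold(network, target, direction, sd_multiplier)
        results[(target, direction)] = simulate_scenario(
            scenario, outcome_items, n_sim=n_sim, seed=seeds[k + 1]
        )
    return compare_scenarios(baseline, results)
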
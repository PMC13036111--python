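"""The Ising probability model over binary symptom states.

For a network with thresholds tau and weights omega, a state
x in {0,1}^p has probability

    P(x) = exp( sum_i tau_i x_i + sum_{i<j} omega_ij x_i x_j ) / Z.

For p up to an enumeration cap (default 20, i.e. ~10^6 states) the
distribution is tabulated exactly and sampled by inversion; beyond the
cap a single-site Gibbs sampler with a fixed ascending scan provides
draws.  Both routes are seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .network import IsingNetwork

ENUMERATION_CAP = 20


class EnumerationCapError(ValueError):
    """p exceeds the exact-enumeration cap; use the Gibbs sampler instead."""


@dataclass
class StateDistribution:
    """Exact tabulated distribution over all 2^p states.

    ``states`` row k holds the binary vector whose bit i equals
    ``(k >> i) & 1``, so state index and bit pattern correspond.
    """

    p: int
    states: np.ndarray          # (2^p, p) in {0, 1}
    probabilities: np.ndarray   # (2^p,), sums to 1
    log_partition: float
    item_labels: list[str]

    def prob(self, state) -> float:
        """Probability of one state given as a 0/1 sequence."""
        x = np.asarray(state, dtype=int)
        if x.shape != (self.p,) or not np.isin(x, (0, 1)).all():
            raise ValueError("state must be a 0/1 vector of length p")
        k = int((x << np.arange(self.p)).sum())
        return float(self.probabilities[k])

    def marginals(self) -> np.ndarray:
        """P(x_i = 1) for each item."""
        return self.probabilities @ self.states

    def as_mapping(self) -> dict[tuple[int, ...], float]:
        return {
            tuple(int(b) for b in row): float(pr)
            for row, pr in zip(self.states, self.probabilities)
        }


@dataclass
class SampleSet:
    """Seeded draws from an Ising network, one simulated observation per row."""

    draws: np.ndarray
    item_labels: list[str]
    seed: int
    method: str                 # "exact" or "gibbs"
    burn_in: int | None = None
    thin: int | None = None

    @property
    def n(self) -> int:
        return self.draws.shape[0]


def _state_table(p: int) -> np.ndarray:
    idx = np.arange(2**p, dtype=np.int64)
    return ((idx[:, None] >> np.arange(p)) & 1).astype(np.int8)


def exact_distribution(
    network: IsingNetwork, cap: int = ENUMERATION_CAP
) -> StateDistribution:
    """Enumerate all 2^p states with normalized probabilities and log Z."""
    p = network.p
    if p > cap:
        raise EnumerationCapError(
            f"p = {p} exceeds the enumeration cap ({cap}); use sample_gibbs"
        )
    states = _state_table(p)
    s = states.astype(float)
    # energy(x) = tau.x + 0.5 * x' omega x  (omega symmetric, zero diagonal)
    energies = s @ network.thresholds + 0.5 * np.einsum(
        "ij,ij->i", s @ network.weights, s
    )
    log_z = float(logsumexp(energies))
    probs = np.exp(energies - log_z)
    return StateDistribution(
        p=p,
        states=states,
        probabilities=probs,
        log_partition=log_z,
        item_labels=list(network.item_labels),
    )


def sample_exact(
    network: IsingNetwork, n: int, seed: int, cap: int = ENUMERATION_CAP
) -> SampleSet:
    """Draw n i.i.d. observations from the enumerated distribution."""
    if n < 0:
        raise ValueError("n must be >= 0")
    dist = exact_distribution(network, cap=cap)
    rng = np.random.default_rng(seed)
    if n == 0:
        draws = np.empty((0, network.p), dtype=np.int8)
    else:
        idx = rng.choice(dist.probabilities.size, size=n, p=dist.probabilities)
        draws = dist.states[idx]
    return SampleSet(
        draws=draws, item_labels=list(network.item_labels), seed=seed, method="exact"
    )


@njit(cache=False)
def _gibbs_chain(tau, omega, n, burn_in, thin, uniforms):  # pragma: no cover
    p = tau.shape[0]
    x = np.zeros(p, dtype=np.int8)
    out = np.empty((n, p), dtype=np.int8)
    total = burn_in + n * thin
    for sweep in range(total):
        for j in range(p):
            field = tau[j]
            for k in range(p):
                field += omega[j, k] * x[k]
            prob = 1.0 / (1.0 + np.exp(-field))
            x[j] = 1 if uniforms[sweep, j] < prob else 0
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            out[(sweep - burn_in) // thin] = x
    return out


def sample_gibbs(
    network: IsingNetwork,
    n: int,
    seed: int,
    burn_in: int = 1000,
    thin: int = 1,
) -> SampleSet:
    """Single-site Gibbs draws with fixed ascending scan order.

    The full conditional is P(x_j = 1 | rest) =
    logistic(tau_j + sum_k omega_jk x_k).  The chain starts from the
    all-zero state; ``burn_in`` sweeps are discarded and every
    ``thin``-th subsequent sweep is retained.
    """
    if n < 0 or burn_in < 0:
        raise ValueError("n and burn_in must be >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = np.random.default_rng(seed)
    total = burn_in + n * thin
    uniforms = rng.random((max(total, 1), network.p))
    if n == 0:
        draws = np.empty((0, network.p), dtype=np.int8)
    else:
        draws = _gibbs_chain(
            network.thresholds, network.weights, n, burn_in, thin, uniforms
        )
    return SampleSet(
        draws=draws,
        item_labels=list(network.item_labels),
        seed=seed,
        method="gibbs",
        burn_in=burn_in,
        thin=thin,
    )


def sum_scores(samples: SampleSet, outcome_items) -> np.ndarray:
    """Per draw, the count of active symptoms among ``outcome_items``."""
    outcome_items = list(outcome_items)
    if not outcome_items:
        raise ValueError("outcome_items must be nonempty")
    known = {lab: j for j, lab in enumerate(samples.item_labels)}
    try:
        idx = [known[lab] for lab in outcome_items]
    except KeyError as exc:
        raise KeyError(f"unknown item label: {exc.args[0]!r}") from None
    return samples.draws[:, idx].sum(axis=1).astype(int)


def expected_sum_score(
    network: IsingNetwork, outcome_items, cap: int = ENUMERATION_CAP
) -> float:
    """Exact expected sum score over ``outcome_items`` (no sampling noise)."""
    dist = exact_distribution(network, cap=cap)
    idx = [network.index(lab) for lab in outcome_items]
    if not idx:
        raise ValueError("outcome_items must be nonempty")
    return float(dist.marginals()[idx].sum())


def spawn_seeds(master_seed: int, count: int) -> list[int]:
    """Derive ``count`` independent sub-seeds from a master seed.

    Uses a SeedSequence counter scheme (spawn key = index) so each
    scenario in a run gets an independent stream while the whole run is
    reproducible from the single master seed.
    """
    return [
        int(np.random.SeedSequence(master_seed, spawn_key=(k,)).generate_state(1)[0])
        % (2**31)
        for k in range(count)
    ]
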
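"""The Ising network container and its on-disk representation.

An Ising network over p binary symptoms is parameterized by a threshold
vector ``tau`` (per-symptom activation tendency, log-odds scale) and a
symmetric zero-diagonal weight matrix ``omega`` (pairwise conditional
associations).  States are coded {0, 1} (symptom absent / present), not
the {-1, +1} convention common in statistical physics; thresholds and
weights are *not* interchangeable between the two conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class NetworkValidationError(ValueError):
    """Raised when threshold/weight data violate the network invariants."""


class NetworkSchemaError(ValueError):
    """Raised when a serialized network file is malformed."""


@dataclass
class IsingNetwork:
    """Thresholds and pairwise weights of a binary (0/1) Ising model.

    Parameters
    ----------
    item_labels
        Ordered, unique symptom labels; index order matches ``thresholds``
        and the rows/columns of ``weights``.
    thresholds
        Length-p vector tau on the log-odds scale.
    weights
        p x p symmetric matrix omega with a zero diagonal.
    community
        Mapping from item label to community identifier (e.g. "MW",
        "PSVU").  May be empty when no partition is relevant.
    """

    item_labels: list[str]
    thresholds: np.ndarray
    weights: np.ndarray
    community: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.item_labels = list(self.item_labels)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.item_labels)
        if p == 0:
            raise NetworkValidationError("empty network (p = 0) is not allowed")
        if len(set(self.item_labels)) != p:
            raise NetworkValidationError("item labels must be unique")
        if self.thresholds.shape != (p,):
            raise NetworkValidationError(
                f"thresholds shape {self.thresholds.shape} != ({p},)"
            )
        if self.weights.shape != (p, p):
            raise NetworkValidationError(
                f"weights shape {self.weights.shape} != ({p}, {p})"
            )
        if not np.all(np.isfinite(self.thresholds)):
            raise NetworkValidationError("thresholds must be finite")
        if not np.all(np.isfinite(self.weights)):
            raise NetworkValidationError("weights must be finite")
        if not np.array_equal(self.weights, self.weights.T):
            raise NetworkValidationError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0.0):
            raise NetworkValidationError("weight matrix diagonal must be zero")
        unknown = [l for l in self.community if l not in set(self.item_labels)]
        if unknown:
            raise NetworkValidationError(f"community map has unknown items: {unknown}")

    @property
    def p(self) -> int:
        return len(self.item_labels)

    def index(self, label: str) -> int:
        try:
            return self.item_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown item label: {label!r}") from None

    def copy(self) -> "IsingNetwork":
        return IsingNetwork(
            item_labels=list(self.item_labels),
            thresholds=self.thresholds.copy(),
            weights=self.weights.copy(),
            community=dict(self.community),
        )

    def permute(self, order: list[int]) -> "IsingNetwork":
        """Return the network with items reordered by ``order`` (relabeling)."""
        idx = np.asarray(order)
        return IsingNetwork(
            item_labels=[self.item_labels[i] for i in order],
            thresholds=self.thresholds[idx],
            weights=self.weights[np.ix_(idx, idx)],
            community=dict(self.community),
        )

    def equals(self, other: "IsingNetwork") -> bool:
        return (
            self.item_labels == other.item_labels
            and np.array_equal(self.thresholds, other.thresholds)
            and np.array_equal(self.weights, other.weights)
            and self.community == other.community
        )


def save_network(network: IsingNetwork, path) -> None:
    """Serialize a network to keyed JSON text at full float precision.

    Python's ``json`` writes floats with ``repr``, which round-trips IEEE
    doubles exactly, so ``load_network(save_network(net)) == net``.
    """
    payload = {
        "item_labels": network.item_labels,
        "thresholds": network.thresholds.tolist(),
        "weights": network.weights.tolist(),
        "community": network.community,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_network(path) -> IsingNetwork:
    """Read a network written by :func:`save_network`, validating invariants."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise NetworkSchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise NetworkSchemaError("top-level JSON value must be an object")
    missing = {"item_labels", "thresholds", "weights"} - set(payload)
    if missing:
        raise NetworkSchemaError(f"missing required keys: {sorted(missing)}")
    try:
        return IsingNetwork(
            item_labels=payload["item_labels"],
            thresholds=np.asarray(payload["thresholds"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            community=dict(payload.get("community", {})),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, NetworkValidationError):
            raise
        raise NetworkSchemaError(f"malformed network fields: {exc}") from exc
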
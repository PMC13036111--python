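"""Ising network estimation by regularized nodewise logistic regression.

Each symptom is regressed on all other symptoms with an L1 penalty along
a descending lambda path; per node, the penalty level is selected by the
extended BIC

    EBIC(lambda) = -2 l + k log n + 2 gamma k log(p - 1)

where l is the logistic log-likelihood at the penalized fit and k the
number of nonzero neighborhood coefficients.  Directed coefficients are
symmetrized into a single weight matrix with an AND rule (edge kept only
when both regressions retain it) or an OR rule.  This is the standard
pseudo-likelihood ("eLasso") approach for binary symptom networks.

The source literature sometimes describes the resulting edges as
"partial correlations"; they are conditional log-odds weights and are
reported on that scale, without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .datasets import BinaryDataset
from .network import IsingNetwork

#: Coefficients below this magnitude count as exactly zero (liblinear
#: produces exact zeros; the guard absorbs solver noise only).
ZERO_TOL = 1e-10


class DegenerateItemError(ValueError):
    """An item is constant (all 0 or all 1) and cannot enter the regression."""

    def __init__(self, items):
        self.items = list(items)
        super().__init__(f"constant (degenerate) items: {self.items}")


@dataclass
class NodewiseFit:
    """L1 logistic path for one node regressed on all other items."""

    node: str
    predictor_labels: list[str]
    lambdas: np.ndarray          # descending
    intercepts: np.ndarray       # (n_lambda,)
    coefs: np.ndarray            # (n_lambda, p - 1)
    n_nonzero: np.ndarray        # (n_lambda,)
    loglik: np.ndarray           # (n_lambda,)
    selected: int | None = field(default=None)


def lambda_grid(X: np.ndarray, y: np.ndarray, size: int = 100,
                min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced descending path from lambda_max (all-zero solution).

    lambda_max = max_j |x_j' (y - ybar)| / n is the smallest penalty at
    which the KKT conditions admit the intercept-only model.
    """
    n = y.shape[0]
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / n
    if lam_max <= 0:
        lam_max = 1.0  # response independent of predictors; any path works
    return np.geomspace(lam_max, min_ratio * lam_max, size)


def _logistic_loglik(X, y, intercept, coef) -> float:
    eta = intercept + X @ coef
    # log-likelihood of the logistic model: sum y*eta - log(1 + e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def nodewise_logistic_path(
    binary: BinaryDataset,
    node: str,
    lambdas: np.ndarray | None = None,
    grid_size: int = 100,
    min_ratio: float = 1e-3,
) -> NodewiseFit:
    """Fit the L1 logistic path of one node on all remaining items.

    Predictors are standardized internally before the penalty is
    applied (the glmnet convention, so items with different endorsement
    rates face comparable penalties); coefficients and intercepts are
    returned on the original 0/1 scale.  The intercept is unpenalized
    (implemented with a large ``intercept_scaling`` so its penalty
    contribution is negligible).  Deterministic given the data and the
    grid.
    """
    j = binary.item_labels.index(node) if node in binary.item_labels else None
    if j is None:
        raise KeyError(f"unknown item label: {node!r}")
    y = binary.values[:, j].astype(float)
    mask = np.arange(binary.n_items) != j
    X = binary.values[:, mask].astype(float)
    predictor_labels = [lab for k, lab in enumerate(binary.item_labels) if k != j]

    degenerate = []
    if y.min() == y.max():
        degenerate.append(node)
    for k, lab in enumerate(predictor_labels):
        if X[:, k].min() == X[:, k].max():
            degenerate.append(lab)
    if degenerate:
        raise DegenerateItemError(degenerate)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xs = (X - mu) / sd

    if lambdas is None:
        lambdas = lambda_grid(Xs, y, size=grid_size, min_ratio=min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be nonempty")

    n = y.shape[0]
    n_lam = lambdas.size
    intercepts = np.empty(n_lam)
    coefs = np.empty((n_lam, X.shape[1]))
    n_nonzero = np.empty(n_lam, dtype=int)
    loglik = np.empty(n_lam)
    for i, lam in enumerate(lambdas):
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (n * lam),
            solver="liblinear",
            fit_intercept=True,
            intercept_scaling=1000.0,
            tol=1e-6,
            max_iter=5000,
            random_state=0,
        )
        clf.fit(Xs, y)
        ws = clf.coef_.ravel()
        ws = np.where(np.abs(ws) > ZERO_TOL, ws, 0.0)
        w = ws / sd
        b = float(clf.intercept_[0]) - float((ws * mu / sd).sum())
        intercepts[i] = b
        coefs[i] = w
        n_nonzero[i] = int(np.count_nonzero(ws))
        loglik[i] = _logistic_loglik(X, y, b, w)

    return NodewiseFit(
        node=node,
        predictor_labels=predictor_labels,
        lambdas=lambdas,
        intercepts=intercepts,
        coefs=coefs,
        n_nonzero=n_nonzero,
        loglik=loglik,
    )


def ebic_score(loglik, k, n, p, gamma) -> np.ndarray:
    return -2.0 * np.asarray(loglik) + np.asarray(k) * np.log(n) \
        + 2.0 * gamma * np.asarray(k) * np.log(max(p - 1, 1))


def ebic_select(fit: NodewiseFit, gamma: float, n: int, p: int) -> int:
    """Index of the EBIC-minimizing path point; ties go to larger lambda.

    Because the path is stored in descending lambda order, the tie-break
    is "first index attaining the minimum".  gamma = 0 reduces the
    criterion to the ordinary BIC.
    """
    if fit.lambdas.size == 0:
        raise ValueError("empty lambda grid")
    scores = ebic_score(fit.loglik, fit.n_nonzero, n, p, gamma)
    selected = int(np.argmin(scores))  # argmin returns the first minimizer
    fit.selected = selected
    return selected


def estimate_network(
    binary: BinaryDataset,
    gamma: float = 0.25,
    rule: str = "AND",
    grid_size: int = 100,
    min_ratio: float = 1e-3,
) -> IsingNetwork:
    """Estimate thresholds and symmetrized weights from binary data.

    Parameters
    ----------
    gamma
        EBIC sparsity hyperparameter; 0.25 is the common eLasso default.
    rule
        "AND": keep an edge only when both nodewise regressions retain
        it (conservative default); "OR": keep it when at least one does.
        Either way the weight is the mean of the two directed
        coefficients, with an absent coefficient counted as 0.
    """
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    p = binary.n_items
    n = binary.n_persons
    constant = [
        lab
        for k, lab in enumerate(binary.item_labels)
        if binary.values[:, k].min() == binary.values[:, k].max()
    ]
    if constant:
        raise DegenerateItemError(constant)

    tau = np.zeros(p)
    directed = np.zeros((p, p))  # directed[j, i] = coefficient of item i in node j's fit
    for j, node in enumerate(binary.item_labels):
        fit = nodewise_logistic_path(
            binary, node, grid_size=grid_size, min_ratio=min_ratio
        )
        sel = ebic_select(fit, gamma=gamma, n=n, p=p)
        tau[j] = fit.intercepts[sel]
        cols = [k for k in range(p) if k != j]
        directed[j, cols] = fit.coefs[sel]

    present = np.abs(directed) > 0
    if rule == "AND":
        keep = present & present.T
    else:
        keep = present | present.T
    omega = np.where(keep, 0.5 * (directed + directed.T), 0.0)
    np.fill_diagonal(omega, 0.0)
    return IsingNetwork(
        item_labels=list(binary.item_labels),
        thresholds=tau,
        weights=omega,
        community=dict(binary.community),
    )


def edge_list(network: IsingNetwork, min_abs_weight: float = 0.0):
    """Upper-triangle edges as (item_a, item_b, weight) rows, optionally filtered."""
    import pandas as pd

    rows = []
    for i in range(network.p):
        for j in range(i + 1, network.p):
            w = network.weights[i, j]
            if w != 0.0 and abs(w) > min_abs_weight:
                rows.append((network.item_labels[i], network.item_labels[j], w))
    return pd.DataFrame(rows, columns=["item_a", "item_b", "weight"])
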
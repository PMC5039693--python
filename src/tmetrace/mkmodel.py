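"""Two-state Mk (continuous-time Markov) model on a rooted tree.

The character takes states 0 (absent) and 1 (present) and evolves with
gain rate ``q01`` (0 -> 1) and loss rate ``q10`` (1 -> 0) per unit branch
length. The transition probability matrix has the closed form

    P(t) = Pi + exp(-(q01+q10) t) (I - Pi),   Pi = rows of (pi0, pi1),

with stationary distribution pi = (q10, q01) / (q01 + q10); for
q01 + q10 = 0, P(t) = I. Tip-data likelihoods are computed by the pruning
(post-order) algorithm with per-node scaling, marginal ancestral state
probabilities by combining tipward and rootward partial likelihoods, and
rates are fitted by bounded maximum likelihood on the log-rate scale from
a deterministic multistart grid.

Supported model families: ER (q01 = q10, one free rate), ARD (two free
rates), and Dollo (q01 = 0 exactly — regain impossible — with the loss
rate free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import minimize

from .treeio import Phylogeny

__all__ = [
    "RateMatrix2",
    "RootPrior",
    "FitResult",
    "transition_matrix",
    "loglik",
    "fit",
    "compare_aic",
    "marginal_ancestral",
]


@dataclass(frozen=True)
class RateMatrix2:
    """Gain (q01: absent->present) and loss (q10: present->absent) rates."""

    q01: float
    q10: float

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def is_er(self) -> bool:
        return self.q01 == self.q10

    @property
    def is_dollo(self) -> bool:
        return self.q01 == 0.0

    def stationary(self) -> np.ndarray:
        s = self.q01 + self.q10
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / s, self.q01 / s])


@dataclass(frozen=True)
class RootPrior:
    """Distribution over the root state: flat, stationary, or fixed."""

    kind: Literal["flat", "stationary", "fixed"] = "flat"
    fixed_state: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed" and self.fixed_state not in (0, 1):
            raise ValueError("fixed root prior requires fixed_state in {0, 1}")

    def vector(self, q: RateMatrix2) -> np.ndarray:
        if self.kind == "flat":
            return np.array([0.5, 0.5])
        if self.kind == "stationary":
            return q.stationary()
        v = np.zeros(2)
        v[self.fixed_state] = 1.0
        return v


def transition_matrix(q: RateMatrix2, t: float) -> np.ndarray:
    """P(t) for the two-state chain; identity at t = 0 or zero total rate."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    s = q.q01 + q.q10
    if s == 0 or t == 0:
        return np.eye(2)
    pi = q.stationary()
    e = math.exp(-s * t)
    P = np.empty((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            P[i, j] = pi[j] + e * ((i == j) - pi[j])
    return P


def _tip_partial(state: object) -> np.ndarray:
    if state == 0:
        return np.array([1.0, 0.0])
    if state == 1:
        return np.array([0.0, 1.0])
    if state in ("?", None):
        return np.array([1.0, 1.0])
    raise ValueError(f"tip state must be 0, 1 or '?', got {state!r}")


def _edge_matrices(tree: Phylogeny, q: RateMatrix2) -> dict[int, np.ndarray]:
    tree.require_branch_lengths()
    return {
        n.id: transition_matrix(q, n.branch_length)
        for n in tree.nodes.values()
        if n.parent is not None
    }


def _down_partials(
    tree: Phylogeny, tips: Mapping[str, object], P: dict[int, np.ndarray]
) -> tuple[dict[int, np.ndarray], dict[int, float]]:
    """Scaled conditional likelihoods of each subtree; returns (partials, log-scales)."""
    part: dict[int, np.ndarray] = {}
    logscale: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            L = _tip_partial(tips.get(node.label, "?"))
            ls = 0.0
        else:
            L = np.ones(2)
            ls = 0.0
            for cid in node.children:
                L = L * (P[cid] @ part[cid])
                ls += logscale[cid]
        m = L.max()
        if m == 0:
            raise ValueError("data have zero likelihood under the model")
        part[node.id] = L / m
        logscale[node.id] = ls + math.log(m)
    return part, logscale


def loglik(
    tree: Phylogeny, tips: Mapping[str, object], q: RateMatrix2, prior: RootPrior
) -> float:
    """Log-likelihood of the tip data by the pruning algorithm.

    Unknown ('?') and unscored tips contribute the partial likelihood
    (1, 1). Returns ``-inf`` when the data are impossible under the model
    (e.g. a Dollo chain from a root fixed at absent with a present tip).
    """
    P = _edge_matrices(tree, q)
    try:
        part, logscale = _down_partials(tree, tips, P)
    except ValueError:
        return -math.inf
    root_vec = prior.vector(q)
    lik = float(root_vec @ part[tree.root])
    if lik <= 0:
        return -math.inf
    return math.log(lik) + logscale[tree.root]


def marginal_ancestral(
    tree: Phylogeny, tips: Mapping[str, object], q: RateMatrix2, prior: RootPrior
) -> dict[int, float]:
    """Per-node marginal posterior probability of state 1 (present).

    Standard two-pass computation: tipward partials from the pruning pass
    are combined with rootward messages, giving P(node = s | data) at every
    node; at leaves with known state this is exactly 0 or 1.
    """
    P = _edge_matrices(tree, q)
    part, _ = _down_partials(tree, tips, P)

    up: dict[int, np.ndarray] = {tree.root: prior.vector(q).astype(float)}
    post: dict[int, float] = {}
    for node in tree.preorder():
        u = up[node.id]
        joint = u * part[node.id]
        tot = joint.sum()
        if tot <= 0:
            raise ValueError("data have zero likelihood under the model")
        post[node.id] = float(joint[1] / tot)
        if not node.children:
            continue
        # rootward message to each child: exclude that child's subtree
        for cid in node.children:
            msg = u.copy()
            for oid in node.children:
                if oid != cid:
                    msg = msg * (P[oid] @ part[oid])
            down_msg = msg @ P[cid]
            m = down_msg.max()
            up[cid] = down_msg / m if m > 0 else down_msg
    return post


@dataclass
class FitResult:
    rates: RateMatrix2
    loglik: float
    n_params: int
    aic: float = field(init=False)
    model: str = "ER"
    converged: bool = True
    boundary: bool = False  # optimum at the zero-rate boundary (e.g. constant data)

    def __post_init__(self) -> None:
        self.aic = 2 * self.n_params - 2 * self.loglik


_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1)
_LOG_BOUNDS = (math.log(1e-9), math.log(1e4))


def fit(
    tree: Phylogeny,
    tips: Mapping[str, object],
    model: Literal["ER", "ARD", "dollo"] = "ER",
    prior: RootPrior = RootPrior("flat"),
) -> FitResult:
    """Maximum-likelihood rate estimation for ER, ARD or Dollo.

    Optimization runs on the log-rate scale from a fixed multistart grid
    scaled by the inverse tree height, so fits are deterministic. A
    constant character drives the rate to the zero boundary; the result is
    flagged via ``boundary`` rather than raising.
    """
    tree.require_branch_lengths()
    height = tree.height()
    if height <= 0:
        raise ValueError("tree height must be positive to fit rates")
    starts = [g / height for g in _GRID]

    observed = {tips[l] for l in tree.leaf_labels() if tips.get(l, "?") in (0, 1)}
    constant = len(observed) < 2

    def q_of(x: np.ndarray) -> RateMatrix2:
        if model == "ER":
            r = math.exp(x[0])
            return RateMatrix2(r, r)
        if model == "ARD":
            return RateMatrix2(math.exp(x[0]), math.exp(x[1]))
        return RateMatrix2(0.0, math.exp(x[0]))  # dollo

    def nll(x: np.ndarray) -> float:
        ll = loglik(tree, tips, q_of(np.atleast_1d(x)), prior)
        return -ll if math.isfinite(ll) else 1e300

    ndim = 2 if model == "ARD" else 1
    best_x, best_val = None, math.inf
    for s0 in starts:
        x0 = np.full(ndim, math.log(s0))
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=[_LOG_BOUNDS] * ndim,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.fun < best_val:
            best_x, best_val = res.x, float(res.fun)
    if best_x is None or not math.isfinite(best_val):
        raise RuntimeError(f"rate optimization failed to converge for model {model}")

    rates = q_of(best_x)
    n_params = {"ER": 1, "ARD": 2, "dollo": 1}[model]
    at_floor = bool(np.any(np.isclose(best_x, _LOG_BOUNDS[0], atol=1.0)))
    return FitResult(
        rates=rates,
        loglik=-best_val,
        n_params=n_params,
        model=model,
        converged=True,
        boundary=constant or at_floor,
    )


def compare_aic(fits: list[FitResult]) -> list[dict[str, object]]:
    """Rank fits by AIC (ascending); ties broken toward fewer parameters.

    Returns one record per fit with its delta-AIC to the best model.
    """
    if not fits:
        raise ValueError("no fits to compare")
    order = sorted(fits, key=lambda f: (f.aic, f.n_params))
    best = order[0].aic
    return [
        {
            "model": f.model,
            "aic": f.aic,
            "delta_aic": f.aic - best,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "rates": {"q01": f.rates.q01, "q10": f.rates.q10},
        }
        for f in order
    ]
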
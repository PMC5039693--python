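"""Stochastic character mapping for a binary trait.

A stochastic map is one full character history — states through time along
every branch — drawn from the posterior of histories given the tip data
and a rate model. Sampling follows the standard two-stage scheme:

1. joint ancestral node states are drawn exactly, by a tipward pruning
   pass followed by rootward sampling from each node's conditional
   distribution given its parent's sampled state and the data below;
2. the path along each branch is drawn conditional on its endpoint states
   by *uniformization* (the jump chain of the subordinated Poisson
   process), which terminates by construction — no rejection sampling, so
   long branches with unlikely endpoint pairs cannot stall.

Many maps are summarized into per-node posteriors (the fraction of maps in
the "present" state) and change counts. Two counts are reported: the mean
per-map numbers of gains and losses, and threshold counts that apply a
node-calling rule — a node is called for a state only when its posterior
strictly exceeds the support threshold (default 0.5), and a change is
counted on an edge whose parent and child are called for opposite states.
Edges touching an uncalled node are not counted.

Three analysis scenarios are provided: equal-rates unconstrained,
equal-rates with the root constrained to "present" (eared ancestor), and a
Dollo model (gain rate exactly zero — a complex structure, once lost,
cannot be regained) with the loss rate refitted under that constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .mkmodel import (
    FitResult,
    RateMatrix2,
    RootPrior,
    _down_partials,
    _edge_matrices,
    fit,
    loglik,
    transition_matrix,
)
from .treeio import Phylogeny

__all__ = [
    "ScenarioConfig",
    "CharacterHistory",
    "MapSummary",
    "ImpossibleDataError",
    "sample_history",
    "sample_node_states",
    "summarize",
    "run_scenario",
]

ScenarioName = Literal["er_unconstrained", "er_root_eared", "dollo"]


class ImpossibleDataError(ValueError):
    """Tip data have probability zero under the requested model/constraints."""


@dataclass(frozen=True)
class ScenarioConfig:
    name: ScenarioName
    n_sims: int = 10_000
    threshold: float = 0.5
    seed: int = 0
    refit_rate: bool = False  # scenario 2: refit ER rate under the root constraint

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly between 0 and 1")


@dataclass
class CharacterHistory:
    """One sampled history: node states plus per-edge timed change events.

    ``events[child_id]`` lists ``(time_from_parent, new_state)`` in
    increasing time order along the edge leading to ``child_id``.
    """

    node_states: dict[int, int]
    events: dict[int, list[tuple[float, int]]] = field(default_factory=dict)

    def counts(self) -> tuple[int, int]:
        """(gains, losses) summed over all edges."""
        gains = losses = 0
        for evs in self.events.values():
            for _, new in evs:
                if new == 1:
                    gains += 1
                else:
                    losses += 1
        return gains, losses


@dataclass
class MapSummary:
    node_posterior: dict[int, float]  # fraction of maps in state 1
    mean_gains: float
    mean_losses: float
    threshold_gains: int
    threshold_losses: int
    threshold_changes: list[tuple[int, str]] = field(default_factory=list)
    n_maps: int = 0
    threshold: float = 0.5
    rates: RateMatrix2 | None = None
    scenario: str | None = None


# -- joint node-state sampling ----------------------------------------


def _conditional_partials(
    tree: Phylogeny, tips: Mapping[str, object], q: RateMatrix2, prior: RootPrior
):
    P = _edge_matrices(tree, q)
    try:
        part, _ = _down_partials(tree, tips, P)
    except ValueError as exc:
        raise ImpossibleDataError(str(exc)) from exc
    root = prior.vector(q) * part[tree.root]
    tot = root.sum()
    if tot <= 0:
        raise ImpossibleDataError(
            "tip data impossible under the given rates and root prior"
        )
    return P, part, root / tot


def sample_node_states(
    tree: Phylogeny,
    tips: Mapping[str, object],
    q: RateMatrix2,
    prior: RootPrior,
    rng: np.random.Generator,
    n: int = 1,
) -> tuple[list[int], np.ndarray]:
    """Draw ``n`` joint ancestral state vectors from the exact conditional.

    Returns the node ids in preorder and an (n_nodes, n) int8 array of
    sampled states. Sampling is vectorized across draws, so large numbers
    of maps are cheap.
    """
    P, part, root_dist = _conditional_partials(tree, tips, q, prior)
    order = [node.id for node in tree.preorder()]
    states = np.empty((len(order), n), dtype=np.int8)
    pos = {nid: i for i, nid in enumerate(order)}

    states[0] = rng.random(n) < root_dist[1]
    for node in tree.preorder():
        s_par = states[pos[node.id]]
        for cid in node.children:
            # P(child=1 | parent, data below child), for parent 0 and 1;
            # a parent state impossible given the data yields 0/0 here but
            # is never sampled, so the invalid division is inert
            w = P[cid] * part[cid][None, :]  # (parent, child)
            with np.errstate(invalid="ignore", divide="ignore"):
                p1 = w[:, 1] / w.sum(axis=1)
            states[pos[cid]] = rng.random(n) < p1[s_par]
    return order, states


# -- endpoint-conditioned path sampling (uniformization) ---------------


def _uniformization_path(
    q: RateMatrix2, t: float, a: int, b: int, rng: np.random.Generator
) -> list[tuple[float, int]]:
    """Timed state changes on a branch of length ``t`` from state a to b."""
    if t == 0:
        if a != b:
            raise ImpossibleDataError("state change across a zero-length branch")
        return []
    rates = (q.q01, q.q10)
    omega = max(rates)
    if omega == 0:
        if a != b:
            raise ImpossibleDataError("state change with zero rates")
        return []
    # jump chain R = I + Q/omega of the subordinating Poisson(omega) process
    R = np.array(
        [
            [1 - q.q01 / omega, q.q01 / omega],
            [q.q10 / omega, 1 - q.q10 / omega],
        ]
    )
    # sample the number of uniformized jumps N | endpoints
    lam = omega * t
    pab = transition_matrix(q, t)[a, b]
    Rpow = [np.eye(2)]
    probs = []
    n = 0
    log_lam = math.log(lam)
    logpois = -lam  # log Pois(0)
    total = 0.0
    while True:
        probs.append(math.exp(logpois) * Rpow[n][a, b])
        total += probs[-1]
        if total >= pab * (1 - 1e-12) and n >= 1:
            break
        n += 1
        Rpow.append(Rpow[-1] @ R)
        logpois += log_lam - math.log(n)
        if n > 100000:  # pragma: no cover - defensive
            break
    probs = np.array(probs)
    if probs.sum() <= 0:
        raise ImpossibleDataError("endpoint pair impossible on this branch")
    N = int(rng.choice(len(probs), p=probs / probs.sum()))
    if N == 0:
        return []
    # jump states by backward conditioning on reaching b in the remaining jumps
    while len(Rpow) <= N:
        Rpow.append(Rpow[-1] @ R)
    times = np.sort(rng.random(N)) * t
    path = []
    s = a
    for i in range(1, N + 1):
        w = R[s, :] * Rpow[N - i][:, b]
        p1 = w[1] / w.sum()
        s_new = int(rng.random() < p1)
        if s_new != s:
            path.append((float(times[i - 1]), s_new))
        s = s_new
    assert s == b
    return path


def sample_history(
    tree: Phylogeny,
    tips: Mapping[str, object],
    q: RateMatrix2,
    prior: RootPrior,
    rng: np.random.Generator,
) -> CharacterHistory:
    """Draw one full character history conditional on the tip data."""
    order, states = sample_node_states(tree, tips, q, prior, rng, n=1)
    node_states = {nid: int(states[i, 0]) for i, nid in enumerate(order)}
    events: dict[int, list[tuple[float, int]]] = {}
    for node in tree.preorder():
        for cid in node.children:
            t = tree.nodes[cid].branch_length
            events[cid] = _uniformization_path(
                q, t, node_states[node.id], node_states[cid], rng
            )
    return CharacterHistory(node_states, events)


# -- change-count sampling for batches of maps -------------------------


def _sample_change_counts(
    tree: Phylogeny,
    q: RateMatrix2,
    order: Sequence[int],
    states: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-map total (gains, losses) given sampled endpoint states.

    For equal rates the change process is Poisson along each branch, so the
    conditional number of changes is a parity-restricted Poisson draw,
    vectorized across maps. Under Dollo the count is determined by the
    endpoints. Other rate matrices fall back to per-map uniformization.
    """
    n = states.shape[1]
    pos = {nid: i for i, nid in enumerate(order)}
    gains = np.zeros(n, dtype=np.int64)
    losses = np.zeros(n, dtype=np.int64)

    def add_counts(par_state: np.ndarray, c: np.ndarray) -> None:
        # changes alternate direction starting from the parent state
        gains[:] += (c + (par_state == 0)) // 2
        losses[:] += (c + (par_state == 1)) // 2

    er = q.q01 == q.q10
    for node in tree.preorder():
        for cid in node.children:
            t = tree.nodes[cid].branch_length
            a = states[pos[node.id]].astype(np.int64)
            b = states[pos[cid]].astype(np.int64)
            if er:
                lam = q.q01 * t
                c = _parity_poisson(lam, (a != b).astype(np.int64), rng)
            elif q.is_dollo:
                c = ((a == 1) & (b == 0)).astype(np.int64)
                if np.any((a == 0) & (b == 1)):
                    raise ImpossibleDataError("gain sampled under a Dollo model")
            else:
                c = np.empty(n, dtype=np.int64)
                for k in range(n):
                    path = _uniformization_path(q, t, int(a[k]), int(b[k]), rng)
                    c[k] = len(path)
            add_counts(a, c)
    return gains, losses


def _parity_poisson(lam: float, parity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam) draws conditioned on even (parity 0) or odd (parity 1) count."""
    n = len(parity)
    out = np.zeros(n, dtype=np.int64)
    if lam == 0:
        if np.any(parity == 1):
            raise ImpossibleDataError("state change with zero rate")
        return out
    # pmf table to negligible tail
    kmax = max(10, int(lam + 12 * math.sqrt(lam) + 12))
    k = np.arange(kmax + 1)
    logpmf = k * math.log(lam) - lam - np.cumsum(np.concatenate(([0.0], np.log(k[1:]))))
    pmf = np.exp(logpmf)
    for par in (0, 1):
        mask = parity == par
        if not np.any(mask):
            continue
        sub = pmf.copy()
        sub[k % 2 != par] = 0.0
        tot = sub.sum()
        if tot <= 0:
            raise ImpossibleDataError("endpoint parity impossible on this branch")
        cdf = np.cumsum(sub / tot)
        out[mask] = np.searchsorted(cdf, rng.random(int(mask.sum())), side="right")
    return out


# -- summaries and scenarios -------------------------------------------


def _threshold_calls(posterior: Mapping[int, float], threshold: float) -> dict[int, int | None]:
    """Called state per node: 1 or 0 when that state's support strictly
    exceeds the threshold, else None (uncalled)."""
    calls: dict[int, int | None] = {}
    for nid, p in posterior.items():
        if p > threshold:
            calls[nid] = 1
        elif (1.0 - p) > threshold:
            calls[nid] = 0
        else:
            calls[nid] = None
    return calls


def _threshold_counts(
    tree: Phylogeny, posterior: Mapping[int, float], threshold: float
) -> tuple[int, int, list[tuple[int, str]]]:
    calls = _threshold_calls(posterior, threshold)
    gains = losses = 0
    changes: list[tuple[int, str]] = []
    for node in tree.preorder():
        for cid in node.children:
            p, c = calls[node.id], calls[cid]
            if p is None or c is None or p == c:
                continue
            if p == 0 and c == 1:
                gains += 1
                changes.append((cid, "gain"))
            else:
                losses += 1
                changes.append((cid, "loss"))
    return gains, losses, changes


def summarize(
    tree: Phylogeny, maps: Sequence[CharacterHistory], threshold: float = 0.5
) -> MapSummary:
    """Summarize a list of sampled histories on a common tree."""
    if not maps:
        raise ValueError("need at least one map")
    node_ids = set(maps[0].node_states)
    if node_ids != set(tree.nodes):
        raise ValueError("maps do not match the given tree")
    for m in maps[1:]:
        if set(m.node_states) != node_ids:
            raise ValueError("maps were sampled on different trees")

    n = len(maps)
    posterior = {
        nid: sum(m.node_states[nid] for m in maps) / n for nid in node_ids
    }
    counts = [m.counts() for m in maps]
    mean_gains = sum(g for g, _ in counts) / n
    mean_losses = sum(l for _, l in counts) / n
    tg, tl, changes = _threshold_counts(tree, posterior, threshold)
    return MapSummary(
        node_posterior=posterior,
        mean_gains=mean_gains,
        mean_losses=mean_losses,
        threshold_gains=tg,
        threshold_losses=tl,
        threshold_changes=changes,
        n_maps=n,
        threshold=threshold,
    )


def _summary_from_batch(
    tree: Phylogeny,
    order: Sequence[int],
    states: np.ndarray,
    gains: np.ndarray,
    losses: np.ndarray,
    threshold: float,
) -> MapSummary:
    n = states.shape[1]
    posterior = {nid: float(states[i].mean()) for i, nid in enumerate(order)}
    tg, tl, changes = _threshold_counts(tree, posterior, threshold)
    return MapSummary(
        node_posterior=posterior,
        mean_gains=float(gains.mean()),
        mean_losses=float(losses.mean()),
        threshold_gains=tg,
        threshold_losses=tl,
        threshold_changes=changes,
        n_maps=n,
        threshold=threshold,
    )


def run_scenario(
    tree: Phylogeny,
    tips: Mapping[str, object],
    cfg: ScenarioConfig,
    er_fit: FitResult | None = None,
) -> MapSummary:
    """Sample ``cfg.n_sims`` stochastic maps under one analysis scenario.

    * ``er_unconstrained`` — ER rate fitted by ML (flat root prior), maps
      sampled with that rate and a flat root prior.
    * ``er_root_eared`` — the same ER rate (refit under the constraint only
      if ``cfg.refit_rate``), root fixed to state 1.
    * ``dollo`` — gain rate exactly 0, loss rate fitted by ML with the
      root fixed eared.

    A precomputed unconstrained ER fit can be passed to avoid refitting.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.name == "er_unconstrained":
        f = er_fit or fit(tree, tips, model="ER", prior=RootPrior("flat"))
        q, prior = f.rates, RootPrior("flat")
    elif cfg.name == "er_root_eared":
        prior = RootPrior("fixed", fixed_state=1)
        if cfg.refit_rate:
            f = fit(tree, tips, model="ER", prior=prior)
        else:
            f = er_fit or fit(tree, tips, model="ER", prior=RootPrior("flat"))
        q = f.rates
    elif cfg.name == "dollo":
        prior = RootPrior("fixed", fixed_state=1)
        f = fit(tree, tips, model="dollo", prior=prior)
        q = f.rates
        if not math.isfinite(loglik(tree, tips, q, prior)):
            raise ImpossibleDataError("tip data impossible under the Dollo scenario")
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario {cfg.name!r}")

    order, states = sample_node_states(tree, tips, q, prior, rng, n=cfg.n_sims)
    gains, losses = _sample_change_counts(tree, q, order, states, rng)
    summary = _summary_from_batch(tree, order, states, gains, losses, cfg.threshold)
    summary.rates = q
    summary.scenario = cfg.name
    return summary
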
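"""Independent brute-force oracles for small trees.

Everything here enumerates ancestral assignments exhaustively and is kept
deliberately separate from the package's dynamic-programming / pruning
implementations so the two can be compared.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from tmetrace.mkmodel import RateMatrix2, RootPrior, transition_matrix
from tmetrace.treeio import Node, Phylogeny


def build_random_tree(rng: np.random.Generator, n_leaves: int, p_polytomy: float = 0.25) -> Phylogeny:
    """Random rooted tree (with occasional polytomies) and random branch lengths."""
    counter = [0]

    def new_id() -> int:
        counter[0] += 1
        return counter[0] - 1

    nodes: dict[int, Node] = {}

    def make(labels: list[str], parent: int | None) -> int:
        nid = new_id()
        bl = None if parent is None else float(rng.uniform(0.05, 2.0))
        nodes[nid] = Node(nid, None, parent, [], bl)
        if len(labels) == 1:
            nodes[nid].label = labels[0]
            return nid
        k = 3 if len(labels) >= 3 and rng.random() < p_polytomy else 2
        cuts = sorted(rng.choice(range(1, len(labels)), size=k - 1, replace=False))
        parts, prev = [], 0
        for c in list(cuts) + [len(labels)]:
            parts.append(labels[prev:c])
            prev = c
        for part in parts:
            cid = make(part, nid)
            nodes[nid].children.append(cid)
        return nid

    labels = [f"L{i}" for i in range(n_leaves)]
    root = make(labels, None)
    return Phylogeny(nodes, root)


def random_tips(rng: np.random.Generator, tree: Phylogeny, p_unknown: float = 0.15) -> dict:
    tips = {}
    for label in tree.leaf_labels():
        u = rng.random()
        tips[label] = "?" if u < p_unknown else int(rng.random() < 0.5)
    return tips


def _assignments(tree: Phylogeny, tips: dict):
    """All full node-state assignments consistent with the tip data."""
    order = [n.id for n in tree.postorder()]
    choices = []
    for nid in order:
        node = tree.nodes[nid]
        if node.is_leaf:
            s = tips.get(node.label, "?")
            choices.append((0, 1) if s == "?" else (s,))
        else:
            choices.append((0, 1))
    for combo in itertools.product(*choices):
        yield dict(zip(order, combo))


def brute_parsimony(tree: Phylogeny, tips: dict):
    """(length, per-node MPR state sets, min/max gains, min/max losses)."""
    edges = [(n.parent, n.id) for n in tree.nodes.values() if n.parent is not None]
    best = math.inf
    records = []
    for assign in _assignments(tree, tips):
        changes = gains = 0
        for p, c in edges:
            if assign[p] != assign[c]:
                changes += 1
                if assign[p] == 0:
                    gains += 1
        records.append((changes, gains, assign))
        best = min(best, changes)
    sets = {nid: set() for nid in tree.nodes}
    gmin, gmax = math.inf, -math.inf
    for changes, gains, assign in records:
        if changes == best:
            for nid, s in assign.items():
                sets[nid].add(s)
            gmin, gmax = min(gmin, gains), max(gmax, gains)
    losses = (int(best - gmax), int(best - gmin))
    return int(best), {k: frozenset(v) for k, v in sets.items()}, (int(gmin), int(gmax)), losses


def brute_likelihood(tree: Phylogeny, tips: dict, q: RateMatrix2, prior: RootPrior) -> float:
    """Exact likelihood by summation over all ancestral assignments."""
    P = {
        n.id: transition_matrix(q, n.branch_length)
        for n in tree.nodes.values()
        if n.parent is not None
    }
    pi = prior.vector(q)
    total = 0.0
    for assign in _assignments(tree, tips):
        p = pi[assign[tree.root]]
        for node in tree.nodes.values():
            if node.parent is not None:
                p *= P[node.id][assign[node.parent], assign[node.id]]
        total += p
    return total


def brute_marginal(tree: Phylogeny, tips: dict, q: RateMatrix2, prior: RootPrior) -> dict:
    """P(node = 1 | data) for every node, by enumeration."""
    P = {
        n.id: transition_matrix(q, n.branch_length)
        for n in tree.nodes.values()
        if n.parent is not None
    }
    pi = prior.vector(q)
    tot = 0.0
    mass1 = {nid: 0.0 for nid in tree.nodes}
    for assign in _assignments(tree, tips):
        p = pi[assign[tree.root]]
        for node in tree.nodes.values():
            if node.parent is not None:
                p *= P[node.id][assign[node.parent], assign[node.id]]
        tot += p
        for nid, s in assign.items():
            if s == 1:
                mass1[nid] += p
    return {nid: mass1[nid] / tot for nid in tree.nodes}
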
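"""Unordered parsimony for a binary character on a rooted tree.

The minimum number of state changes and per-node most-parsimonious-
reconstruction (MPR) state sets are computed with the Sankoff dynamic
program under unit costs, which handles multifurcations natively (the
Fitch pass is the binary special case). Because a binary character on a
rooted tree admits many MPRs that trade gains (0->1) for losses (1->0),
directional counts are reported as ranges over all MPRs:

* the minimum loss count over MPRs is obtained by minimizing the
  lexicographic cost (total changes, losses) — an exact integer version of
  breaking ties with an infinitesimally more expensive loss;
* the minimum gain count symmetrically; the maxima follow from
  gains + losses = length in every MPR.

Unknown ('?') tips enter the DP with the full state set {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from .treeio import Phylogeny

__all__ = [
    "ParsimonyResult",
    "fitch_length",
    "mpr_summary",
    "count_directed_changes",
    "resolve_mpr",
]

_INF = float("inf")

TipStates = Mapping[str, object]  # taxon -> 0 | 1 | '?'


def _leaf_allowed(state: object) -> tuple[bool, bool]:
    """(state-0 allowed, state-1 allowed) for a tip scoring."""
    if state == 0:
        return (True, False)
    if state == 1:
        return (False, True)
    if state in ("?", None):
        return (True, True)
    raise ValueError(f"tip state must be 0, 1 or '?', got {state!r}")


def _down_costs(
    tree: Phylogeny, tips: TipStates, secondary: Literal["none", "losses", "gains"], strict: bool
) -> dict[int, tuple]:
    """Sankoff down-pass.

    Costs are pairs (changes, secondary-count) compared lexicographically,
    with the secondary component tracking losses or gains, so a single pass
    yields both the parsimony length and the extreme directional count.
    """

    def edge_cost(parent_state: int, child_state: int) -> tuple[int, int]:
        change = int(parent_state != child_state)
        if secondary == "losses":
            sec = int(parent_state == 1 and child_state == 0)
        elif secondary == "gains":
            sec = int(parent_state == 0 and child_state == 1)
        else:
            sec = 0
        return (change, sec)

    costs: dict[int, tuple] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in tips:
                if strict:
                    raise KeyError(f"leaf {node.label!r} missing from tip states")
                allowed = (True, True)
            else:
                allowed = _leaf_allowed(tips[node.label])
            costs[node.id] = tuple((0, 0) if ok else (_INF, _INF) for ok in allowed)
        else:
            acc = [(0, 0), (0, 0)]
            for cid in node.children:
                child = costs[cid]
                for s in (0, 1):
                    best = None
                    for t in (0, 1):
                        ec = edge_cost(s, t)
                        cand = (child[t][0] + ec[0], child[t][1] + ec[1])
                        if best is None or cand < best:
                            best = cand
                    acc[s] = (acc[s][0] + best[0], acc[s][1] + best[1])
            costs[node.id] = tuple(acc)
    return costs


def fitch_length(tree: Phylogeny, tips: TipStates, strict: bool = True) -> int:
    """Minimum number of state changes over all ancestral assignments."""
    costs = _down_costs(tree, tips, "none", strict)
    root = min(costs[tree.root])
    if root[0] == _INF:
        raise ValueError("character has no valid assignment (all tip states excluded)")
    return int(root[0])


def _up_costs(tree: Phylogeny, down: dict[int, tuple]) -> dict[int, tuple[float, float]]:
    """Min cost of the rest of the tree given each node's state (unit costs)."""
    up: dict[int, tuple[float, float]] = {tree.root: (0.0, 0.0)}
    for node in tree.preorder():
        for cid in node.children:
            res = [0.0, 0.0]
            for t in (0, 1):
                best = _INF
                for s in (0, 1):
                    # cost of parent state s seen from outside + siblings + edge
                    sib = 0.0
                    for oid in node.children:
                        if oid == cid:
                            continue
                        sib += min(down[oid][u][0] + (s != u) for u in (0, 1))
                    cand = up[node.id][s] + sib + (s != t)
                    if cand < best:
                        best = cand
                res[t] = best
            up[cid] = (res[0], res[1])
    return up


@dataclass
class ParsimonyResult:
    length: int
    node_state_sets: dict[int, frozenset[int]]
    gains_range: tuple[int, int]
    losses_range: tuple[int, int]
    unambiguous_changes: list[tuple[int, str]]  # (edge child id, "gain"|"loss")


def mpr_summary(tree: Phylogeny, tips: TipStates, strict: bool = True) -> ParsimonyResult:
    """Summary over all most-parsimonious reconstructions.

    ``node_state_sets[v]`` is the set of states node ``v`` takes in at least
    one MPR, computed by combining down-pass (subtree) and up-pass
    (rest-of-tree) costs rather than by enumeration. An edge whose parent
    and child sets are disjoint singletons carries the same change in every
    MPR and is listed in ``unambiguous_changes``.
    """
    down = _down_costs(tree, tips, "none", strict)
    length = fitch_length(tree, tips, strict)
    up = _up_costs(tree, {k: v for k, v in down.items()})

    sets: dict[int, frozenset[int]] = {}
    for node in tree.postorder():
        states = frozenset(
            s for s in (0, 1) if down[node.id][s][0] + up[node.id][s] == length
        )
        assert states, "every node takes some state in an MPR"
        sets[node.id] = states

    # lexicographic optima at the root
    loss_costs = _down_costs(tree, tips, "losses", strict)[tree.root]
    gain_costs = _down_costs(tree, tips, "gains", strict)[tree.root]
    min_losses = int(min(loss_costs)[1])
    min_gains = int(min(gain_costs)[1])
    gains_range = (min_gains, length - min_losses)
    losses_range = (min_losses, length - min_gains)

    unambiguous: list[tuple[int, str]] = []
    for node in tree.preorder():
        for cid in node.children:
            ps, cs = sets[node.id], sets[cid]
            if len(ps) == 1 and len(cs) == 1 and ps != cs:
                direction = "gain" if ps == frozenset({0}) else "loss"
                unambiguous.append((cid, direction))

    return ParsimonyResult(length, sets, gains_range, losses_range, unambiguous)


def count_directed_changes(
    result: ParsimonyResult,
    resolution: Literal["min_gains", "min_losses", "unambiguous_only"],
) -> tuple[int, int]:
    """(gains, losses) tally under an MPR resolution rule.

    ``min_gains`` / ``min_losses`` pick the MPR extreme for that direction
    (the complementary count follows from gains + losses = length);
    ``unambiguous_only`` counts only changes shared by every MPR.
    """
    if resolution == "min_gains":
        g = result.gains_range[0]
        return g, result.length - g
    if resolution == "min_losses":
        l = result.losses_range[0]
        return result.length - l, l
    if resolution == "unambiguous_only":
        g = sum(1 for _, d in result.unambiguous_changes if d == "gain")
        l = sum(1 for _, d in result.unambiguous_changes if d == "loss")
        return g, l
    raise ValueError(f"unknown resolution {resolution!r}")


def resolve_mpr(
    tree: Phylogeny,
    tips: TipStates,
    minimize: Literal["losses", "gains"] = "losses",
    strict: bool = True,
) -> tuple[dict[int, int], list[tuple[int, str]]]:
    """One concrete MPR extremizing the chosen direction, with its changes.

    Returns per-node states and the list of (edge child id, direction).
    Tie-breaks are deterministic (lower state index preferred), so the same
    input always yields the same reconstruction.
    """
    down = _down_costs(tree, tips, minimize, strict)

    def edge_cost(s: int, t: int) -> tuple[int, int]:
        change = int(s != t)
        if minimize == "losses":
            sec = int(s == 1 and t == 0)
        else:
            sec = int(s == 0 and t == 1)
        return (change, sec)

    states: dict[int, int] = {}
    states[tree.root] = min((down[tree.root][s], s) for s in (0, 1))[1]
    for node in tree.preorder():
        s = states[node.id]
        for cid in node.children:
            best = None
            for t in (0, 1):
                ec = edge_cost(s, t)
                cand = ((down[cid][t][0] + ec[0], down[cid][t][1] + ec[1]), t)
                if best is None or cand < best:
                    best = cand
            states[cid] = best[1]

    changes = []
    for node in tree.preorder():
        for cid in node.children:
            if states[node.id] != states[cid]:
                changes.append((cid, "gain" if states[node.id] == 0 else "loss"))
    return states, changes
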
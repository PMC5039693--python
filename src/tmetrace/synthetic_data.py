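"""Synthetic trees, traits and dependent character triples.

Every pipeline stage can be exercised without external data: Yule
(pure-birth) trees, binary traits evolved forward under a known 2-state
Markov chain with the true change history recorded, and TM/TA/CO triples
that obey the lateral-medial dependency by construction.

The triple generator uses a *gating* scheme rather than a joint
multi-state chain: the columella evolves under its own rates, each lateral
structure evolves under independent rates, and a lateral structure is
masked to absent wherever its medial gate is absent (TA requires CO, TM
requires observed TA). The generated matrix therefore passes the coding
rules unchanged.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from dendropy.model import birthdeath

from .characters import ABSENT, PRESENT, CharacterMatrix, StructureTriple
from .mkmodel import RateMatrix2
from .simmap import CharacterHistory
from .treeio import Phylogeny, read_newick, write_newick

__all__ = [
    "SimulationRecord",
    "yule_tree",
    "simulate_mk",
    "simulate_dependent_triple",
    "write_fixture_bundle",
]


@dataclass
class SimulationRecord:
    """A simulated trait with its generating model and full true history."""

    tree: Phylogeny
    truth: CharacterHistory
    tips: dict[str, int]
    q_true: RateMatrix2
    seed: int


def yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Rooted binary ultrametric tree from a pure-birth (Yule) process.

    Leaves are relabelled ``t1`` .. ``tN`` so fixtures can be mixed without
    name collisions. Identical seeds give identical Newick output.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    text = dtree.as_string(schema="newick", suppress_rooting=True)
    return read_newick(text)


def simulate_mk(
    tree: Phylogeny, q: RateMatrix2, root_state: int = 1, seed: int = 0
) -> SimulationRecord:
    """Forward simulation of a binary trait along every branch.

    Waiting times between changes are exponential with the current state's
    exit rate; the full event history (times measured from the parent node)
    is recorded per edge.
    """
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    tree.require_branch_lengths()
    rng = np.random.default_rng(seed)
    rates = (q.q01, q.q10)

    node_states: dict[int, int] = {tree.root: root_state}
    events: dict[int, list[tuple[float, int]]] = {}
    for node in tree.preorder():
        for cid in node.children:
            s = node_states[node.id]
            t_total = tree.nodes[cid].branch_length
            t = 0.0
            evs: list[tuple[float, int]] = []
            while True:
                rate = rates[s]
                if rate == 0:
                    break
                t += rng.exponential(1.0 / rate)
                if t >= t_total:
                    break
                s = 1 - s
                evs.append((t, s))
            events[cid] = evs
            node_states[cid] = s

    tips = {tree.nodes[n.id].label: node_states[n.id] for n in tree.leaves()}
    return SimulationRecord(tree, CharacterHistory(node_states, events), tips, q, seed)


def simulate_dependent_triple(
    tree: Phylogeny,
    q_co: RateMatrix2,
    q_lateral: RateMatrix2,
    seed: int = 0,
    root_state: int = 1,
) -> tuple[CharacterMatrix, dict[str, SimulationRecord]]:
    """TM/TA/CO tip scorings respecting the lateral-medial dependency.

    CO evolves under ``q_co``; TA and TM each evolve latent presence under
    ``q_lateral`` and are expressed only where the medial gate is present.
    Returns the character matrix plus the three latent true histories.
    """
    rec_co = simulate_mk(tree, q_co, root_state=root_state, seed=seed)
    rec_ta = simulate_mk(tree, q_lateral, root_state=root_state, seed=seed + 1)
    rec_tm = simulate_mk(tree, q_lateral, root_state=root_state, seed=seed + 2)

    rows = []
    for taxon in sorted(rec_co.tips, key=lambda s: int(s[1:]) if s[1:].isdigit() else 0):
        co = rec_co.tips[taxon]
        ta = rec_ta.tips[taxon] if co == 1 else 0
        tm = rec_tm.tips[taxon] if ta == 1 else 0
        state = {1: PRESENT, 0: ABSENT}
        rows.append(StructureTriple(taxon, state[tm], state[ta], state[co]))
    matrix = CharacterMatrix(rows, provenance={r.taxon: "simulated" for r in rows})
    return matrix, {"CO": rec_co, "TA": rec_ta, "TM": rec_tm}


def write_fixture_bundle(
    out_dir: str | Path,
    n_tips: int = 50,
    q_co: RateMatrix2 | None = None,
    q_lateral: RateMatrix2 | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a Newick tree + character TSV + truth JSON fixture bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    q_co = q_co or RateMatrix2(0.1, 0.5)
    q_lateral = q_lateral or RateMatrix2(0.2, 0.6)
    tree = yule_tree(n_tips, seed=seed)
    matrix, truths = simulate_dependent_triple(tree, q_co, q_lateral, seed=seed)

    tree_path = out / "tree.nwk"
    tree_path.write_text(write_newick(tree) + "\n")
    table_path = out / "characters.tsv"
    code = {PRESENT: "1", ABSENT: "0"}
    lines = ["taxon\tTM\tTA\tCO"]
    for r in matrix.rows:
        lines.append(f"{r.taxon}\t{code[r.tm]}\t{code[r.ta]}\t{code[r.co]}")
    table_path.write_text("\n".join(lines) + "\n")
    truth_path = out / "truth.json"
    truth = {
        name: {
            "q01": rec.q_true.q01,
            "q10": rec.q_true.q10,
            "seed": rec.seed,
            "tips": rec.tips,
            "n_true_gains": rec.truth.counts()[0],
            "n_true_losses": rec.truth.counts()[1],
        }
        for name, rec in truths.items()
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return {"tree": tree_path, "characters": table_path, "truth": truth_path}
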
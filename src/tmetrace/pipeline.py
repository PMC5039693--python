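"""End-to-end analysis: tree + character table -> gains/losses report.

The pipeline mirrors a standard comparative workflow for the tympanic
middle ear: complete the TM/TA/CO scorings under the dependency rules,
reconcile taxa between tree and matrix, optionally restrict to a focal
clade (named by the MRCA of anchor taxa), run parsimony reconstruction per
structure, compare ER vs ARD transition-rate models by AIC, and run the
three stochastic-mapping scenarios on complete-TME presence/absence.

Every reported count is traceable to a module output stored alongside the
report: per-node state sets and posteriors as TSV, annotated trees as
NHX-commented Newick, and a consolidated ``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .characters import CharacterMatrix, extract_binary, read_character_table
from .mkmodel import RootPrior, compare_aic, fit
from .parsimony import ParsimonyResult, mpr_summary, resolve_mpr
from .simmap import MapSummary, ScenarioConfig, run_scenario
from .treeio import Phylogeny, prune_to_taxa, read_newick, write_annotated

__all__ = ["AnalysisReport", "run_full_analysis", "count_independent_losses"]

log = logging.getLogger("tmetrace")

STRUCTURES = ("TM", "TA", "CO")
SCENARIOS = ("er_unconstrained", "er_root_eared", "dollo")

DEFAULT_CONFIG: dict[str, Any] = {
    "scope": {"anchors": None},  # list of taxa whose MRCA bounds the analysis
    "parsimony": {"resolutions": ["min_losses", "min_gains", "unambiguous_only"]},
    "mk": {"root_prior": "flat"},
    "simmap": {"n_sims": 10_000, "threshold": 0.5, "seed": 0, "refit_rate": False},
}


@dataclass
class AnalysisReport:
    parsimony: dict[str, dict[str, Any]] = field(default_factory=dict)
    independent_losses: dict[str, Any] = field(default_factory=dict)
    model_comparison: list[dict[str, Any]] = field(default_factory=list)
    scenarios: dict[str, dict[str, Any]] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "parsimony": self.parsimony,
            "independent_losses": self.independent_losses,
            "model_comparison": self.model_comparison,
            "scenarios": self.scenarios,
            "provenance": self.provenance,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if config is None:
        return cfg
    if isinstance(config, Mapping):
        user = dict(config)
    else:
        with open(config, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section in cfg and isinstance(values, Mapping):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def count_independent_losses(
    tree: Phylogeny, tips: Mapping[str, object]
) -> tuple[int, list[int]]:
    """Lower bound on independent losses of a structure across the tree.

    The bound is the minimum number of present->absent transitions over all
    most-parsimonious reconstructions (an "at least N times" statement);
    the contributing edges of the corresponding loss-minimal MPR are
    returned by edge child id. Nested loss clades count once.
    """
    _, changes = resolve_mpr(tree, tips, minimize="losses")
    loss_edges = [cid for cid, d in changes if d == "loss"]
    return len(loss_edges), loss_edges


def _parsimony_section(result: ParsimonyResult) -> dict[str, Any]:
    from .parsimony import count_directed_changes

    out: dict[str, Any] = {
        "length": result.length,
        "gains_range": list(result.gains_range),
        "losses_range": list(result.losses_range),
        "unambiguous_changes": [
            {"edge": cid, "direction": d} for cid, d in result.unambiguous_changes
        ],
    }
    for res in ("min_losses", "min_gains", "unambiguous_only"):
        g, l = count_directed_changes(result, res)
        out[res] = {"gains": g, "losses": l}
    return out


def _summary_section(s: MapSummary) -> dict[str, Any]:
    return {
        "scenario": s.scenario,
        "n_maps": s.n_maps,
        "threshold": s.threshold,
        "rates": {"q01": s.rates.q01, "q10": s.rates.q10} if s.rates else None,
        "mean_gains": s.mean_gains,
        "mean_losses": s.mean_losses,
        "threshold_gains": s.threshold_gains,
        "threshold_losses": s.threshold_losses,
        "threshold_changes": [
            {"edge": cid, "direction": d} for cid, d in s.threshold_changes
        ],
    }


def run_full_analysis(
    tree_path: str | Path,
    matrix_path: str | Path,
    config: str | Path | Mapping[str, Any] | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run coding -> parsimony -> model selection -> stochastic mapping.

    Taxa scored but absent from the tree are dropped with a warning; tree
    taxa without a scoring are treated as unknown ('?'). The stochastic-
    mapping scenarios run on complete-TME presence (TM present implies the
    full TM+TA+CO chain under the dependency rules).
    """
    t0 = time.time()
    tree_path, matrix_path = Path(tree_path), Path(matrix_path)
    for p in (tree_path, matrix_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    cfg = _load_config(config)

    tree = read_newick(tree_path.read_text())
    matrix, altered, inconsistent = read_character_table(str(matrix_path))
    log.info("loaded tree (%d leaves) and matrix (%d rows)", tree.n_leaves, len(matrix))

    # clade scoping by MRCA of anchor taxa
    anchors = cfg["scope"].get("anchors")
    if anchors:
        mrca = tree.mrca(anchors)
        tree = tree.subtree(mrca)
        log.info("restricted to MRCA clade of %s: %d leaves", anchors, tree.n_leaves)

    # taxon reconciliation
    tree_taxa = set(tree.leaf_labels())
    matrix_taxa = set(matrix.taxa())
    extra = sorted(matrix_taxa - tree_taxa)
    if extra:
        warnings.warn(f"{len(extra)} scored taxa absent from the tree were dropped")
        matrix = CharacterMatrix([r for r in matrix.rows if r.taxon in tree_taxa])
    unscored = sorted(tree_taxa - matrix_taxa)
    if unscored:
        warnings.warn(f"{len(unscored)} tree taxa are unscored; treated as '?'")

    report = AnalysisReport()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # parsimony per structure
    for structure in STRUCTURES:
        tips = extract_binary(matrix, structure)
        result = mpr_summary(tree, tips, strict=False)
        report.parsimony[structure] = _parsimony_section(result)
        if out is not None:
            lines = ["node_id\tstate_set\tis_leaf"]
            for node in tree.preorder():
                ss = ",".join(map(str, sorted(result.node_state_sets[node.id])))
                lines.append(f"{node.id}\t{{{ss}}}\t{int(node.is_leaf)}")
            (out / f"node_states_{structure}.tsv").write_text("\n".join(lines) + "\n")

    # independent complete-TME losses, read from the columella
    co_tips = extract_binary(matrix, "CO")
    n_losses, loss_edges = count_independent_losses(tree, co_tips)
    report.independent_losses = {
        "structure": "CO",
        "count": n_losses,
        "edges": loss_edges,
    }

    # ER vs ARD model comparison on complete-TME presence
    ear_tips = extract_binary(matrix, "TM")
    prior = RootPrior(cfg["mk"]["root_prior"])
    er = fit(tree, ear_tips, model="ER", prior=prior)
    ard = fit(tree, ear_tips, model="ARD", prior=prior)
    report.model_comparison = compare_aic([er, ard])

    # stochastic-mapping scenarios
    sm = cfg["simmap"]
    for i, name in enumerate(SCENARIOS):
        scen = ScenarioConfig(
            name=name,
            n_sims=int(sm["n_sims"]),
            threshold=float(sm["threshold"]),
            seed=int(sm["seed"]) + i,
            refit_rate=bool(sm.get("refit_rate", False)),
        )
        summary = run_scenario(tree, ear_tips, scen, er_fit=er)
        report.scenarios[name] = _summary_section(summary)
        report.scenarios[name]["seed"] = scen.seed
        if out is not None:
            lines = ["node_id\tposterior_present"]
            for node in tree.preorder():
                lines.append(f"{node.id}\t{summary.node_posterior[node.id]:.6f}")
            (out / f"posterior_{name}.tsv").write_text("\n".join(lines) + "\n")
            ann = {
                nid: {"p1": f"{p:.4f}"} for nid, p in summary.node_posterior.items()
            }
            (out / f"annotated_{name}.tre").write_text(write_annotated(tree, ann) + "\n")
        log.info("scenario %s done in %.1fs", name, time.time() - t0)

    report.provenance = {
        "tool": "tmetrace",
        "version": __version__,
        "tree_sha256": _sha256(tree_path),
        "matrix_sha256": _sha256(matrix_path),
        "config": cfg,
        "n_tree_leaves": tree.n_leaves,
        "n_matrix_rows": len(matrix),
        "rows_altered_by_completion": len(altered),
        "rows_rejected_inconsistent": len(inconsistent),
        "dropped_taxa_not_in_tree": extra,
        "unscored_tree_taxa": unscored,
    }

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return report
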
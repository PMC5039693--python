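"""Rooted phylogenies with stable node addressing.

Trees are read from Newick (parsing is delegated to dendropy, which handles
quoted labels and dialect quirks) into a light :class:`Phylogeny` structure
whose integer node ids are *stable*: pruning never renumbers surviving nodes,
so per-node results from different analysis stages can be joined safely.

Edges are identified by their child node, oriented rootward.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import dendropy

__all__ = ["Node", "Phylogeny", "TreeError", "read_newick", "write_newick", "write_annotated"]


class TreeError(ValueError):
    """Raised for malformed Newick input or contract violations."""


@dataclass
class Node:
    id: int
    label: str | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    branch_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with (possibly multifurcating) internal nodes.

    Invariants: exactly one root (parent is None); leaf labels unique and
    nonempty; branch lengths, where present, are nonnegative.
    """

    def __init__(self, nodes: dict[int, Node], root: int):
        self.nodes = nodes
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        roots = [n.id for n in self.nodes.values() if n.parent is None]
        if roots != [self.root]:
            raise TreeError(f"expected exactly one root {self.root}, found {roots}")
        labels = [n.label for n in self.nodes.values() if n.is_leaf]
        if any(not lab for lab in labels):
            raise TreeError("every leaf must carry a nonempty label")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dups}")
        for n in self.nodes.values():
            if n.branch_length is not None and n.branch_length < 0:
                raise TreeError(f"negative branch length on node {n.id}")

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            nid, done = stack.pop()
            if done:
                yield self.nodes[nid]
            else:
                stack.append((nid, True))
                for c in reversed(self.nodes[nid].children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_leaf)

    def has_branch_lengths(self) -> bool:
        return all(
            n.branch_length is not None for n in self.nodes.values() if n.parent is not None
        )

    def require_branch_lengths(self) -> None:
        if not self.has_branch_lengths():
            raise TreeError("branch lengths required for this operation")

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths (missing lengths treated as an error)."""
        self.require_branch_lengths()
        out = {self.root: 0.0}
        for n in self.preorder():
            if n.parent is not None:
                out[n.id] = out[n.parent] + n.branch_length
        return out

    def height(self) -> float:
        d = self.depths()
        return max(d[n.id] for n in self.leaves())

    def total_length(self) -> float:
        self.require_branch_lengths()
        return sum(n.branch_length for n in self.nodes.values() if n.parent is not None)

    def mrca(self, taxa: Iterable[str]) -> int:
        """Node id of the most recent common ancestor of the named leaves."""
        by_label = {n.label: n.id for n in self.leaves()}
        ids = []
        for t in taxa:
            if t not in by_label:
                raise TreeError(f"taxon {t!r} not in tree")
            ids.append(by_label[t])
        if not ids:
            raise TreeError("mrca of empty taxon set")
        paths = []
        for nid in ids:
            path = []
            while nid is not None:
                path.append(nid)
                nid = self.nodes[nid].parent
            paths.append(set(path))
        common = set.intersection(*paths)
        # deepest common ancestor = the common node with the longest root path
        nid = ids[0]
        while nid not in common or not all(nid in p for p in paths):
            nid = self.nodes[nid].parent
        return nid

    def subtree(self, node_id: int) -> "Phylogeny":
        """The clade rooted at ``node_id``, ids preserved."""
        keep: dict[int, Node] = {}
        stack = [node_id]
        while stack:
            nid = stack.pop()
            n = self.nodes[nid]
            keep[nid] = Node(nid, n.label, n.parent, list(n.children), n.branch_length)
            stack.extend(n.children)
        keep[node_id].parent = None
        keep[node_id].branch_length = None
        return Phylogeny(keep, node_id)

    def copy(self) -> "Phylogeny":
        nodes = {
            i: Node(n.id, n.label, n.parent, list(n.children), n.branch_length)
            for i, n in self.nodes.items()
        }
        return Phylogeny(nodes, self.root)


# -- Newick I/O --------------------------------------------------------


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Labels may be quoted; underscores in unquoted labels are preserved
    verbatim (no space substitution). Missing branch lengths are recorded
    as absent and only rejected by operations that need them.
    """
    if not text or not text.strip():
        raise TreeError("empty Newick input")
    if text.count("(") != text.count(")"):
        raise TreeError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"Newick parse error: {exc}") from exc

    nodes: dict[int, Node] = {}
    next_id = 0
    index: dict[dendropy.Node, int] = {}
    for dnode in dtree.preorder_node_iter():
        nid = next_id
        next_id += 1
        index[dnode] = nid
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        parent = index[dnode.parent_node] if dnode.parent_node is not None else None
        bl = dnode.edge.length
        nodes[nid] = Node(nid, label, parent, [], None if bl is None else float(bl))
        if parent is not None:
            nodes[parent].children.append(nid)
    tree = Phylogeny(nodes, 0)
    root = tree.nodes[tree.root]
    if len(root.children) == 1:
        warnings.warn("root has a single child (degree-1 root accepted)", stacklevel=2)
    return tree


_UNQUOTED_OK = re.compile(r"^[^\s()\[\]{}:;,'\"]+$")


def _format_label(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(
    tree: Phylogeny,
    annotations: Mapping[int, Mapping[str, object]] | None = None,
) -> str:
    """Serialize to Newick; with ``annotations``, NHX comments are attached.

    Annotations map node id -> {key: value}; they are emitted as
    ``[&&NHX:key=value]`` after the branch length, which dendropy and most
    tree viewers read back without disturbing topology or lengths.
    """
    ann = annotations or {}
    for nid in ann:
        if nid not in tree.nodes:
            raise TreeError(f"annotation on unknown node id {nid}")

    out = io.StringIO()

    def comment(nid: int) -> str:
        if nid not in ann or not ann[nid]:
            return ""
        items = ":".join(f"{k}={v}" for k, v in ann[nid].items())
        return f"[&&NHX:{items}]"

    def rec(nid: int) -> None:
        node = tree.nodes[nid]
        if node.children:
            out.write("(")
            for i, c in enumerate(node.children):
                if i:
                    out.write(",")
                rec(c)
            out.write(")")
            if node.label:
                out.write(_format_label(node.label))
        else:
            out.write(_format_label(node.label))
        if node.branch_length is not None:
            out.write(f":{node.branch_length!r}")
        out.write(comment(nid))

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(tree.nodes) + 100))
    try:
        rec(tree.root)
    finally:
        sys.setrecursionlimit(old)
    out.write(";")
    return out.getvalue()


def write_annotated(tree: Phylogeny, annotations: Mapping[int, Mapping[str, object]]) -> str:
    """Newick with per-node NHX comments (machine-readable annotated tree)."""
    return write_newick(tree, annotations)


# -- pruning -----------------------------------------------------------


def prune_to_taxa(tree: Phylogeny, keep: set[str]) -> tuple[Phylogeny, list[str]]:
    """Restrict the tree to the leaves named in ``keep``.

    Degree-2 internal nodes created by the pruning are suppressed with
    their branch lengths summed, so all pairwise path lengths among kept
    leaves are preserved. Node ids of surviving nodes are unchanged.

    Returns the pruned tree and the sorted list of dropped taxon names.
    """
    leaf_labels = set(tree.leaf_labels())
    kept_labels = keep & leaf_labels
    if not kept_labels:
        raise TreeError("no requested taxa are present in the tree")
    dropped = sorted(leaf_labels - kept_labels)

    tree = tree.copy()
    # mark nodes on a root-to-kept-leaf path
    alive: set[int] = set()
    for n in tree.postorder():
        if n.is_leaf:
            if n.label in kept_labels:
                alive.add(n.id)
        elif any(c in alive for c in n.children):
            alive.add(n.id)

    nodes = {i: n for i, n in tree.nodes.items() if i in alive}
    for n in nodes.values():
        n.children = [c for c in n.children if c in alive]

    root = tree.root  # the root is an ancestor of every kept leaf, hence alive

    # suppress degree-2 internal nodes (not the root, not leaves)
    def suppress(nid: int) -> None:
        node = nodes[nid]
        (child_id,) = node.children
        child = nodes[child_id]
        if child.branch_length is not None and node.branch_length is not None:
            child.branch_length += node.branch_length
        elif node.branch_length is not None and child.branch_length is None:
            child.branch_length = node.branch_length
        child.parent = node.parent
        parent = nodes[node.parent]
        parent.children[parent.children.index(nid)] = child_id
        del nodes[nid]

    for nid in [n.id for n in nodes.values()]:
        node = nodes.get(nid)
        if node is None or node.parent is None:
            continue
        if len(node.children) == 1:
            suppress(nid)

    pruned = Phylogeny(nodes, root)
    return pruned, dropped
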
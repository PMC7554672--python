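"""Rooted phylogenetic trees: Newick I/O, traversals, pruning.

The tree is the shared scaffold of both reconstruction tracks: the
nonhomogeneous 16S model and the gene-family birth-death model both walk
the same rooted topology and read branch lengths in substitutions/site
from it.  The data model is deliberately small: integer node ids, an
optional label per node, parent/children links and one branch length per
non-root node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Node",
    "Tree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "branch_table",
    "assign_internal_labels",
    "read_node_label_map",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


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


class Tree:
    """Rooted tree with unique leaf labels and non-negative branch lengths.

    Polytomies are allowed; all algorithms in this package are written for
    arbitrary out-degree.  The root carries no (or an ignored) branch length.
    """

    def __init__(self, nodes: list[Node], root: int):
        self.nodes = nodes
        self.root = root
        self.validate()

    # -- construction helpers -------------------------------------------------

    def validate(self) -> None:
        roots = [n.id for n in self.nodes if n.parent is None]
        if roots != [self.root] and set(roots) != {self.root}:
            raise NewickError(f"expected exactly one root, found {roots}")
        seen: set[str] = set()
        reached = 0
        for nid in self.postorder():
            reached += 1
            node = self.nodes[nid]
            if node.is_leaf:
                if not node.label:
                    raise NewickError(f"leaf node {nid} has an empty label")
                if node.label in seen:
                    raise NewickError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            if node.parent is not None:
                bl = node.branch_length
                if bl is not None and bl < 0:
                    raise NewickError(
                        f"negative branch length {bl} on node {node.label or nid}"
                    )
        if reached != len(self.nodes):
            raise NewickError("tree is not fully connected")

    # -- traversals -----------------------------------------------------------

    def postorder(self) -> Iterator[int]:
        """Yield node ids, every child strictly before its parent."""
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            nid, expanded = stack.pop()
            if expanded:
                yield nid
            else:
                stack.append((nid, True))
                for c in reversed(self.nodes[nid].children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self.nodes[nid].children))

    # -- queries --------------------------------------------------------------

    def leaves(self) -> list[int]:
        return [n.id for n in self.nodes if n.is_leaf]

    def internals(self) -> list[int]:
        return [n.id for n in self.nodes if not n.is_leaf]

    def leaf_labels(self) -> list[str]:
        """Leaf labels in the left-to-right order of the Newick input."""
        out = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            if node.is_leaf:
                out.append(node.label)
            else:
                stack.extend(reversed(node.children))
        return out

    def node_by_label(self, label: str) -> Node:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def root_to_node_length(self, nid: int) -> float:
        total = 0.0
        while self.nodes[nid].parent is not None:
            bl = self.nodes[nid].branch_length
            total += 0.0 if bl is None else bl
            nid = self.nodes[nid].parent
        return total

    def leaf_set_below(self, nid: int) -> frozenset[str]:
        labels = []
        stack = [nid]
        while stack:
            cur = stack.pop()
            node = self.nodes[cur]
            if node.is_leaf:
                labels.append(node.label)
            stack.extend(node.children)
        return frozenset(labels)

    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    def copy(self) -> "Tree":
        nodes = [
            Node(n.id, n.label, n.parent, list(n.children), n.branch_length)
            for n in self.nodes
        ]
        return Tree(nodes, self.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_leaves={self.n_leaves()}, n_nodes={len(self.nodes)})"


# -- Newick parsing -----------------------------------------------------------

_SPECIAL = set("(),:;")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in _SPECIAL:
            tokens.append(ch)
            i += 1
        elif ch in "'\"":
            raise NewickError(f"quoted labels are not supported (at {text[i:i+15]!r})")
        else:
            j = i
            while j < n and text[j] not in _SPECIAL and not text[j].isspace():
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def parse_newick(text: str, *, missing_length_zero: bool = False) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    Branch lengths are required on every non-root node unless
    ``missing_length_zero`` is set, in which case absent lengths become 0.
    Unquoted labels only; internal (support-style) labels are kept.
    """
    tokens = _tokenize(text)
    if not tokens or tokens[-1] != ";":
        raise NewickError("Newick string must end with ';'")
    pos = 0
    nodes: list[Node] = []

    def new_node() -> Node:
        node = Node(id=len(nodes))
        nodes.append(node)
        return node

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_clade() -> Node:
        nonlocal pos
        node = new_node()
        if peek() == "(":
            pos += 1
            while True:
                child = parse_clade()
                child.parent = node.id
                node.children.append(child.id)
                if peek() == ",":
                    pos += 1
                    continue
                if peek() == ")":
                    pos += 1
                    break
                raise NewickError(f"unbalanced parentheses near token {pos}")
        tok = peek()
        if tok is not None and tok not in _SPECIAL:
            node.label = tok
            pos += 1
        if peek() == ":":
            pos += 1
            tok = peek()
            try:
                node.branch_length = float(tok)
            except (TypeError, ValueError):
                raise NewickError(f"invalid branch length token {tok!r}") from None
            if node.branch_length < 0:
                raise NewickError(f"negative branch length token {tok!r}")
            pos += 1
        return node

    root = parse_clade()
    if peek() != ";":
        raise NewickError(f"trailing tokens after tree: {tokens[pos:]}")
    for node in nodes:
        if node.parent is not None and node.branch_length is None:
            if missing_length_zero:
                node.branch_length = 0.0
            else:
                raise NewickError(
                    f"missing branch length on node {node.label or node.id}"
                )
    return Tree(nodes, root.id)


def _format_length(x: float, precision: int | None) -> str:
    if precision is None:
        return repr(float(x))
    return f"{x:.{precision}g}"


def write_newick(tree: Tree, *, precision: int | None = None) -> str:
    """Serialize a tree; with ``precision=None`` lengths round-trip exactly."""

    def render(nid: int) -> str:
        node = tree.nodes[nid]
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label:
                s += node.label
        if node.branch_length is not None:
            s += ":" + _format_length(node.branch_length, precision)
        return s

    return render(tree.root) + ";"


# -- pruning ------------------------------------------------------------------


def prune_to_taxa(tree: Tree, keep: Iterable[str]) -> Tree:
    """Restrict a tree to a subset of its leaves.

    Unary internal nodes created by the removal are suppressed with their
    branch lengths summed, so every kept leaf retains its exact root-to-leaf
    path length.  If all kept leaves fall in one root subtree the root is
    retained as a unary node (suppressing it would shorten the paths).
    """
    keep = set(keep)
    labels = set(tree.leaf_labels())
    unknown = keep - labels
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 leaves to keep")

    kept_below: dict[int, bool] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            kept_below[nid] = node.label in keep
        else:
            kept_below[nid] = any(kept_below[c] for c in node.children)

    new_nodes: list[Node] = []

    def build(nid: int, extra_length: float, parent_new: int | None) -> None:
        node = tree.nodes[nid]
        live = [c for c in node.children if kept_below[c]]
        bl = node.branch_length or 0.0
        if not node.is_leaf and len(live) == 1 and parent_new is not None:
            # unary, non-root: splice out, pushing length onto the child
            build(live[0], extra_length + bl, parent_new)
            return
        new = Node(id=len(new_nodes), label=node.label, parent=parent_new)
        if parent_new is not None:
            new.branch_length = bl + extra_length
            new_nodes.append(new)
            new_nodes[parent_new].children.append(new.id)
        else:
            new_nodes.append(new)
        for c in live:
            build(c, 0.0, new.id)

    build(tree.root, 0.0, None)
    return Tree(new_nodes, 0)


# -- tabular views and labelling ----------------------------------------------


def branch_table(tree: Tree) -> pd.DataFrame:
    """One row per non-root node: (parent_id, child_id, branch_length, child_is_leaf)."""
    rows = [
        (n.parent, n.id, n.branch_length, n.is_leaf)
        for n in tree.nodes
        if n.parent is not None
    ]
    return pd.DataFrame(
        rows, columns=["parent_id", "child_id", "branch_length", "child_is_leaf"]
    )


def assign_internal_labels(
    tree: Tree, label_map: Mapping[frozenset[str], str] | None = None
) -> dict[int, str]:
    """Name internal nodes.

    ``label_map`` keys are the leaf sets descending from a node (how named
    ancestors are pinned down); unlabeled internals get
    stable ids N1..Nk in postorder.  Existing labels from the Newick input are
    kept unless the map overrides them.  Returns {node id: label} and writes
    the labels onto the tree.
    """
    label_map = dict(label_map or {})
    out: dict[int, str] = {}
    counter = 0
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            continue
        counter += 1
        clade = tree.leaf_set_below(nid)
        if clade in label_map:
            node.label = label_map[clade]
        elif not node.label:
            node.label = f"N{counter}"
        out[nid] = node.label
    return out


def read_node_label_map(path) -> dict[frozenset[str], str]:
    """Two-column TSV: comma-separated leaf set, label."""
    out: dict[frozenset[str], str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            out[frozenset(parts[0].split(","))] = parts[1]
    return out
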
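"""Unrooted phylogenetic trees with branch lengths and bootstrap supports.

The tree model is deliberately small: labelled leaves, unlabelled (or
support-labelled) internal nodes, non-negative branch lengths.  Newick
text is parsed through :mod:`dendropy` and converted into this light
node structure; numeric internal-node labels are interpreted as
bootstrap support percentages (the convention used by MEGA and
FastTree).

All path queries treat the tree as *unrooted*: any degree-2 vertex
(e.g. an artificial root) is suppressed before distances and
internal-node counts are measured, so a rooted and an unrooted
serialisation of the same topology give identical metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = ["Tree", "TreeNode", "read_newick", "write_newick", "PathMetrics"]


@dataclass(eq=False)
class TreeNode:
    """A node of a (rooted representation of a) phylogenetic tree."""

    label: str | None = None
    length: float = 0.0          # length of the edge to the parent
    support: float | None = None  # bootstrap % in [0, 100] on the edge to the parent
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, len={self.length}, n_children={len(self.children)})"


@dataclass(frozen=True)
class PathMetrics:
    """Path summary between two leaves on the unrooted tree.

    ``internal_node_count`` is the number of internal vertices strictly
    between the two leaves on their unique path; ``branch_length_sum``
    is the total length of the edges on that path.
    """

    leaf_a: str
    leaf_b: str
    internal_node_count: int
    branch_length_sum: float


class Tree:
    """An unrooted phylogeny stored as a rooted node structure."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.label for n in self.iter_leaves()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if any(lbl is None or lbl == "" for lbl in labels):
            raise ValueError("every leaf must carry a non-empty label")

    # ------------------------------------------------------------------
    # basic traversal
    # ------------------------------------------------------------------
    def iter_nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def iter_leaves(self) -> Iterator[TreeNode]:
        return (n for n in self.iter_nodes() if n.is_leaf)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(n.label for n in self.iter_leaves())

    def n_leaves(self) -> int:
        return sum(1 for _ in self.iter_leaves())

    def n_internal_nodes(self) -> int:
        """Internal vertices of the unrooted tree (degree-2 root suppressed)."""
        adj = self._adjacency()
        return sum(1 for n, nbrs in adj.items() if len(nbrs) > 1)

    # ------------------------------------------------------------------
    # unrooted adjacency view
    # ------------------------------------------------------------------
    def _adjacency(self) -> dict[TreeNode, list[tuple[TreeNode, float]]]:
        """Adjacency map of the unrooted tree.

        Degree-2 vertices (artificial roots, serialisation artefacts)
        are suppressed by merging their two incident edges.
        """
        adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}
        for node in self.iter_nodes():
            adj.setdefault(node, [])
            for child in node.children:
                adj[node].append((child, child.length))
                adj.setdefault(child, []).append((node, child.length))
        changed = True
        while changed:
            changed = False
            for node, nbrs in list(adj.items()):
                if len(nbrs) == 2 and not node.is_leaf:
                    (u, lu), (v, lv) = nbrs
                    adj[u] = [(w, l) for w, l in adj[u] if w is not node] + [(v, lu + lv)]
                    adj[v] = [(w, l) for w, l in adj[v] if w is not node] + [(u, lu + lv)]
                    del adj[node]
                    changed = True
                    break
        return adj

    def _leaf(self, label: str) -> TreeNode:
        for n in self.iter_leaves():
            if n.label == label:
                return n
        raise KeyError(f"leaf {label!r} not present in tree")

    # ------------------------------------------------------------------
    # path metrics
    # ------------------------------------------------------------------
    def path_metrics(self, leaf_a: str, leaf_b: str) -> PathMetrics:
        """Internal-node count and branch-length sum between two leaves."""
        if leaf_a == leaf_b:
            return PathMetrics(leaf_a, leaf_b, 0, 0.0)
        a, b = self._leaf(leaf_a), self._leaf(leaf_b)
        adj = self._adjacency()
        # breadth-first search from a to b on the unrooted adjacency
        prev: dict[TreeNode, tuple[TreeNode, float]] = {}
        queue = [a]
        seen = {a}
        while queue:
            node = queue.pop(0)
            if node is b:
                break
            for nbr, length in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    prev[nbr] = (node, length)
                    queue.append(nbr)
        if b not in prev:
            raise ValueError(f"no path between {leaf_a!r} and {leaf_b!r}")
        total = 0.0
        count = -1  # the walk below visits b..a inclusive; exclude both leaves
        node = b
        while node is not a:
            parent, length = prev[node]
            total += length
            count += 1
            node = parent
        return PathMetrics(leaf_a, leaf_b, count, total)

    # ------------------------------------------------------------------
    # bipartitions / bootstrap support
    # ------------------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted tree.

        Each split is canonicalised as the frozen set of leaf labels on
        the side *not* containing the lexicographically smallest leaf.
        """
        all_leaves = set(self.leaf_labels)
        ref = min(all_leaves)
        adj = self._adjacency()
        splits: set[frozenset[str]] = set()
        seen_edges: set[frozenset[int]] = set()
        for node, nbrs in adj.items():
            for nbr, _ in nbrs:
                key = frozenset({id(node), id(nbr)})
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                side = self._component_leaves(adj, node, nbr)
                if ref in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(frozenset(side))
        return splits

    @staticmethod
    def _component_leaves(adj, start: TreeNode, blocked: TreeNode) -> set[str]:
        leaves: set[str] = set()
        stack, seen = [start], {start, blocked}
        while stack:
            node = stack.pop()
            if node.is_leaf:
                leaves.add(node.label)
            for nbr, _ in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return leaves

    def annotate_support(self, replicates: list["Tree"]) -> None:
        """Set internal-edge supports to bipartition frequencies (percent)."""
        if not replicates:
            raise ValueError("at least one replicate tree required")
        counts: dict[frozenset[str], int] = {}
        for rep in replicates:
            for split in rep.bipartitions():
                counts[split] = counts.get(split, 0) + 1
        all_leaves = set(self.leaf_labels)
        ref = min(all_leaves)
        for node in self.iter_nodes():
            if node.is_leaf or node.parent is None:
                continue
            side = {leaf.label for leaf in self._subtree_leaves(node)}
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                node.support = 100.0 * counts.get(frozenset(side), 0) / len(replicates)

    def _subtree_leaves(self, node: TreeNode) -> Iterator[TreeNode]:
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                yield n
            stack.extend(n.children)

    # ------------------------------------------------------------------
    # serialisation
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree(n_leaves={self.n_leaves()})"


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------
def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at character {offset}")
    if depth != 0:
        raise ValueError(f"unbalanced '(': {depth} unclosed at end of text")


def read_newick(text: str) -> Tree:
    """Parse one Newick tree.

    Branch lengths default to 0 when absent.  Internal-node labels that
    parse as numbers in [0, 100] are stored as bootstrap supports.
    """
    text = text.strip()
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else None
        support = None
        if dnode.is_internal() and dnode.label is not None:
            try:
                value = float(dnode.label)
            except ValueError:
                value = None
            if value is not None and 0.0 <= value <= 100.0:
                support = value
            else:
                label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if length < 0:
            raise ValueError(f"negative branch length {length} on edge to {label!r}")
        node = TreeNode(label=label, length=float(length), support=support)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return Tree(convert(dtree.seed_node))


def _fmt_length(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _fmt_support(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def write_newick(tree: Tree) -> str:
    """Serialise with supports as internal-node labels, lengths to 6 dp."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.label
        else:
            inner = ",".join(render(c) for c in node.children)
            label = _fmt_support(node.support) if node.support is not None else (node.label or "")
            body = f"({inner}){label}"
        if node.parent is None:
            return body
        return f"{body}:{_fmt_length(node.length)}"

    return render(tree.root) + ";"


def read_newick_list(text: str) -> list[Tree]:
    """Parse a multi-tree Newick file (one tree per ';')."""
    trees = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(read_newick(chunk + ";"))
    return trees


def write_newick_list(trees: list[Tree]) -> str:
    return "\n".join(write_newick(t) for t in trees) + "\n"
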
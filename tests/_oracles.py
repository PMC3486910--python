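"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, independently of the
package's implementations: affine-gap alignment by explicit three-state
dynamic programming, tree path metrics by networkx shortest paths on a
graph built during tree *generation* (never parsed back from the
package's own objects), synteny chains by exhaustive depth-first
enumeration, and the HGT screen rule by direct evaluation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float(-1e18)


# ----------------------------------------------------------------------
# affine-gap alignment scores (three-state DP)
# ----------------------------------------------------------------------
def dp_align_score(a: str, b: str, local: bool, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal BLOSUM62 alignment score; first gap residue costs
    gap_open + gap_extend, each further residue gap_extend."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (a residue vs gap)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            Ix[i, 0] = -(first + (i - 1) * gap_extend)
        for j in range(1, m + 1):
            Iy[0, j] = -(first + (j - 1) * gap_extend)
    best_local = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if local:
                diag = max(diag, 0.0)
            M[i, j] = diag + s
            Ix[i, j] = max(M[i - 1, j] - first, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - first, Iy[i, j - 1] - gap_extend)
            if local and M[i, j] > best_local:
                best_local = M[i, j]
    if local:
        return best_local
    return max(M[n, m], Ix[n, m], Iy[n, m])


# ----------------------------------------------------------------------
# random trees: newick text + an independent networkx graph
# ----------------------------------------------------------------------
def random_tree(rng: np.random.Generator, n_leaves: int):
    """A random unrooted binary tree.

    Returns (newick, graph, leaf_labels); the graph is built directly
    during generation with edge attribute ``length``, so path queries
    on it do not involve the package's tree code at all.
    """
    assert n_leaves >= 3
    graph = nx.Graph()
    items: list[tuple[str, str]] = []  # (newick fragment, graph node id)
    for i in range(n_leaves):
        name = f"L{i}"
        graph.add_node(name)
        items.append((name, name))
    counter = 0

    def join(children: list[tuple[str, str]], top: bool) -> tuple[str, str]:
        nonlocal counter
        node_id = f"I{counter}"
        counter += 1
        graph.add_node(node_id)
        parts = []
        for frag, child in children:
            length = round(float(rng.uniform(0.05, 2.0)), 4)
            graph.add_edge(node_id, child, length=length)
            parts.append(f"{frag}:{length}")
        return "(" + ",".join(parts) + ")", node_id

    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = join([items[i], items[j]], top=False)
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    frag, _ = join(items, top=True)
    return frag + ";", graph, [f"L{i}" for i in range(n_leaves)]


def graph_path_metrics(graph: nx.Graph, a: str, b: str) -> tuple[int, float]:
    """(internal node count, branch length sum) via networkx."""
    path = nx.shortest_path(graph, a, b)
    internal = sum(1 for v in path[1:-1])
    total = sum(graph[u][v]["length"] for u, v in zip(path, path[1:]))
    return internal, total


def additive_matrix(graph: nx.Graph, leaves: list[str]):
    """Leaf-to-leaf path-length matrix of a generated tree."""
    n = len(leaves)
    d = np.zeros((n, n))
    lengths = dict(nx.all_pairs_dijkstra_path_length(graph, weight="length"))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = lengths[leaves[i]][leaves[j]]
    return d


# ----------------------------------------------------------------------
# synteny chains by exhaustive enumeration
# ----------------------------------------------------------------------
def _ok(p, q, direction: int, max_gap: int) -> bool:
    da = q.a_index - p.a_index
    db = q.b_index - p.b_index
    return 0 < da <= max_gap + 1 and direction * db > 0 and abs(db) <= max_gap + 1


def _all_chains(pairs, direction, max_gap):
    """Every right-maximal chain, by depth-first extension."""
    pairs = sorted(pairs, key=lambda p: p.a_index)
    chains = []

    def extend(chain):
        last = chain[-1]
        succs = [q for q in pairs if _ok(last, q, direction, max_gap)]
        if not succs:
            chains.append(list(chain))
            return
        for q in succs:
            extend(chain + [q])

    for p in pairs:
        extend([p])
    return chains


def oracle_syntons(pairs, min_genes: int, max_gap: int):
    """Greedy longest-chain-first assignment, fully enumerated.

    Returns a list of (tuple of a_locus, orientation).
    """
    pool = sorted(pairs, key=lambda p: p.a_index)
    out = []
    while pool:
        candidates = []
        for direction, name in ((1, "conserved"), (-1, "inverted")):
            for chain in _all_chains(pool, direction, max_gap):
                dir_pref = 0 if name == "conserved" else 1
                candidates.append(
                    (
                        -len(chain),
                        chain[0].a_index,
                        dir_pref,
                        tuple(p.a_index for p in chain),
                        chain,
                        name,
                    )
                )
        if not candidates:
            break
        best = min(candidates)
        chain, name = best[4], best[5]
        if len(chain) < min_genes:
            break
        if len(chain) == 1:
            name = "conserved"
        out.append((tuple(p.a_locus for p in chain), name))
        used = {id(p) for p in chain}
        pool = [p for p in pool if id(p) not in used]
    out.sort(key=lambda c: c[0])
    return out


# ----------------------------------------------------------------------
# HGT screen rule, evaluated directly
# ----------------------------------------------------------------------
def oracle_candidate(phyla: list[str], self_phylum: str, k: int, lenient: bool) -> bool:
    """Direct evaluation of the top-k outside-phylum rule on a list of
    hit phyla ordered by rank (no exclusions)."""
    top = phyla[:k]
    if not top:
        return False
    if len(top) < k and not lenient:
        return False
    return all(p != self_phylum for p in top)
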
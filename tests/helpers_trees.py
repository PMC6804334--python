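"""Test-side tree utilities kept independent of the package internals:
a random-tree generator and a graph-based brute-force weighted
Robinson-Foulds oracle."""

import io
import itertools

import networkx as nx
import numpy as np
from skbio import TreeNode


def random_binary_newick(names, rng, length_range=(0.05, 1.0)) -> str:
    """Random binary topology over ``names`` with uniform branch lengths."""
    lo, hi = length_range

    def bl():
        return rng.uniform(lo, hi)

    nodes = [f"{n}:{bl():.6f}" for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl():.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def _tree_to_graph(tree: TreeNode) -> tuple[nx.Graph, dict]:
    g = nx.Graph()
    ids = {}
    for i, node in enumerate(tree.traverse(include_self=True)):
        ids[id(node)] = i
        g.add_node(i, name=node.name if node.is_tip() else None)
    for node in tree.traverse(include_self=False):
        g.add_edge(
            ids[id(node.parent)], ids[id(node)], weight=float(node.length or 0.0)
        )
    return g, ids


def brute_force_split_weights(tree: TreeNode) -> dict:
    """Enumerate nontrivial bipartitions by deleting each edge of the
    tree graph and reading off the connected components."""
    g, _ = _tree_to_graph(tree)
    leaves = sorted(n for n, d in g.nodes(data=True) if d["name"] is not None)
    names = {n: g.nodes[n]["name"] for n in leaves}
    anchor = min(names.values())
    all_names = frozenset(names.values())
    weights = {}
    for u, v, data in list(g.edges(data=True)):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(names[n] for n in comp if n in names)
        g.add_edge(u, v, weight=data["weight"])
        if len(side) < 2 or len(side) > len(all_names) - 2:
            continue
        if anchor in side:
            side = all_names - side
        weights[side] = weights.get(side, 0.0) + data["weight"]
    return weights


def brute_force_wrfd(t1: TreeNode, t2: TreeNode) -> float:
    w1 = brute_force_split_weights(t1)
    w2 = brute_force_split_weights(t2)
    return sum(abs(w1.get(k, 0.0) - w2.get(k, 0.0)) for k in set(w1) | set(w2))


def random_ultrametric_matrix(n, rng):
    """Ultrametric distances from a random agglomeration with strictly
    increasing merge heights.  Returns (matrix, ids)."""
    ids = [f"L{i}" for i in range(n)]
    clusters = [{i} for i in range(n)]
    height = 0.0
    d = np.zeros((n, n))
    while len(clusters) > 1:
        height += rng.uniform(0.2, 1.0)
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2 * height
        clusters[i] |= clusters[j]
        del clusters[j]
    return d, ids
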
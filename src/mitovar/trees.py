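"""Distance matrices, dendrograms, and weighted Robinson-Foulds comparison.

Four per-sample characteristics of an intratumor sampling design are
turned into pairwise distance matrices — physical sampling coordinates
(Euclidean distance in mm), heteroplasmy minor-allele-fraction profiles
(norm of the per-site MAF difference vector, absent sites as 0), scalar
copy-number values (absolute difference), and a precomputed nuclear SNV
matrix.  Each matrix is min-max normalized over its off-diagonal
entries, a dendrogram is built (neighbor joining by default, UPGMA as
an option), and pairs of dendrograms are compared by the weighted
Robinson-Foulds distance (wRFD):

    wRFD(T1, T2) = sum over the union of nontrivial bipartitions s of
                   |w1(s) - w2(s)|

where ``w(s)`` is the length of the branch inducing split ``s`` and a
split absent from a tree has weight 0 (unrooted semantics; the two
edges of a rooted-binary root induce the same split and their lengths
are summed).  Significance is assessed by uniformly permuting the leaf
labels of one tree and recomputing the wRFD, with the add-one p-value
convention ``p = (1 + #{null <= observed}) / (1 + n_permutations)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj
from skbio.tree import upgma as _skbio_upgma

__all__ = [
    "SampleCoordinate",
    "TreeComparison",
    "coordinate_matrix",
    "het_matrix",
    "scalar_matrix",
    "normalize",
    "build_tree",
    "split_weights",
    "wrfd",
    "permutation_test",
    "compare_all",
]


@dataclass(frozen=True)
class SampleCoordinate:
    """2D Cartesian sampling position in mm."""

    sample_id: str
    x: float
    y: float


@dataclass(frozen=True)
class TreeComparison:
    id_a: str
    id_b: str
    wrfd: float
    p_value: float
    n_permutations: int


def _as_distance_matrix(
    data: np.ndarray, ids: Sequence[str]
) -> DistanceMatrix:
    data = np.asarray(data, dtype=float)
    return DistanceMatrix(data, ids=list(ids))


def coordinate_matrix(
    coords: Union[Sequence[SampleCoordinate], pd.DataFrame]
) -> DistanceMatrix:
    """Pairwise Euclidean distances between sampling coordinates."""
    if isinstance(coords, pd.DataFrame):
        ids = coords["sample_id"].astype(str).tolist()
        xy = coords[["x", "y"]].to_numpy(dtype=float)
    else:
        ids = [c.sample_id for c in coords]
        xy = np.array([[c.x, c.y] for c in coords], dtype=float)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    return _as_distance_matrix(squareform(pdist(xy, metric="euclidean")), ids)


def het_matrix(
    maf_table: pd.DataFrame, metric: str = "euclidean"
) -> DistanceMatrix:
    """Distances between per-sample heteroplasmy MAF profiles.

    ``maf_table`` is samples x sites; missing entries (a site not
    detected in a sample) are treated as MAF 0.  ``metric`` is
    "euclidean" (default) or "manhattan".
    """
    if metric not in ("euclidean", "manhattan"):
        raise ValueError("metric must be 'euclidean' or 'manhattan'")
    filled = maf_table.fillna(0.0)
    vals = filled.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 0.5)).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    scipy_metric = "cityblock" if metric == "manhattan" else "euclidean"
    ids = [str(i) for i in filled.index]
    return _as_distance_matrix(squareform(pdist(vals, metric=scipy_metric)), ids)


def scalar_matrix(values: Union[pd.Series, Mapping[str, float]]) -> DistanceMatrix:
    """Absolute differences between per-sample scalar values (e.g. mtCN)."""
    series = pd.Series(values, dtype=float)
    v = series.to_numpy()[:, None]
    return _as_distance_matrix(np.abs(v - v.T), [str(i) for i in series.index])


def normalize(m: DistanceMatrix, method: str = "minmax") -> DistanceMatrix:
    """Scale off-diagonal entries into [0, 1].

    "minmax" (default) maps d -> (d - min) / (max - min) over the
    off-diagonal values; "maxdiv" divides by the maximum.  A constant
    matrix maps to all zeros; the diagonal always stays 0.
    """
    if method not in ("minmax", "maxdiv"):
        raise ValueError("method must be 'minmax' or 'maxdiv'")
    data = m.data.copy()
    n = data.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = data[off]
    if vals.size == 0:
        return _as_distance_matrix(data, m.ids)
    lo, hi = vals.min(), vals.max()
    if method == "minmax":
        data[off] = 0.0 if hi == lo else (vals - lo) / (hi - lo)
    else:
        data[off] = 0.0 if hi == 0 else vals / hi
    np.fill_diagonal(data, 0.0)
    return _as_distance_matrix(data, m.ids)


def build_tree(
    m: DistanceMatrix,
    method: str = "nj",
    root_id: Optional[str] = None,
) -> TreeNode:
    """Dendrogram from a distance matrix.

    ``method`` is "nj" (neighbor joining, negative branch lengths
    clamped to 0) or "upgma".  When ``root_id`` names a leaf, the tree
    is rooted on that leaf's pendant edge (the leaf becomes the
    outgroup).
    """
    if len(m.ids) < 3:
        raise ValueError("need at least 3 samples to build a tree")
    if method == "nj":
        tree = _skbio_nj(m, neg_as_zero=True)
    elif method == "upgma":
        tree = _skbio_upgma(m)
    else:
        raise ValueError("method must be 'nj' or 'upgma'")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if root_id is not None:
        if root_id not in set(m.ids):
            raise ValueError(f"root id {root_id!r} is not a leaf")
        tree = tree.root_by_outgroup([root_id])
    return tree


def _leaf_names(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def split_weights(tree: TreeNode) -> dict[frozenset, float]:
    """Nontrivial bipartitions of an (un)rooted tree with branch weights.

    Each split is canonicalized to the side *not* containing the
    lexicographically smallest leaf; weights of edges inducing the same
    split (e.g. the two root edges of a rooted binary tree) are summed.
    """
    leaves = sorted(_leaf_names(tree))
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names")
    full = frozenset(leaves)
    anchor = leaves[0]
    out: dict[frozenset, float] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        below = frozenset(t.name for t in node.tips())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        side = full - below if anchor in below else below
        out[side] = out.get(side, 0.0) + float(node.length or 0.0)
    return out


def _wrfd_from_splits(
    s1: Mapping[frozenset, float], s2: Mapping[frozenset, float]
) -> float:
    total = 0.0
    for k in s1.keys() | s2.keys():
        total += abs(s1.get(k, 0.0) - s2.get(k, 0.0))
    return total


def wrfd(t1: TreeNode, t2: TreeNode) -> float:
    """Weighted Robinson-Foulds distance between trees on the same leaves."""
    l1, l2 = set(_leaf_names(t1)), set(_leaf_names(t2))
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    return _wrfd_from_splits(split_weights(t1), split_weights(t2))


def _permute_splits(
    splits: Mapping[frozenset, float],
    mapping: Mapping[str, str],
    leaves: Sequence[str],
) -> dict[frozenset, float]:
    anchor = min(leaves)
    full = frozenset(leaves)
    out: dict[frozenset, float] = {}
    for side, w in splits.items():
        new = frozenset(mapping[x] for x in side)
        if anchor in new:
            new = full - new
        out[new] = out.get(new, 0.0) + w
    return out


def permutation_test(
    t1: TreeNode,
    t2: TreeNode,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    id_a: str = "tree1",
    id_b: str = "tree2",
) -> TreeComparison:
    """Leaf-label permutation test of tree similarity.

    The null distribution is ``wrfd(t1, t2')`` where ``t2'`` carries a
    uniformly random permutation of t2's leaf labels.  Small observed
    distances (similar trees) give small p-values:
    ``p = (1 + #{null <= observed}) / (1 + n_permutations)``.
    """
    rng = np.random.default_rng(seed)
    s1 = split_weights(t1)
    s2 = split_weights(t2)
    observed = _wrfd_from_splits(s1, s2)
    leaves = sorted(_leaf_names(t1))
    if set(leaves) != set(_leaf_names(t2)):
        raise ValueError("leaf sets differ")
    count = 0
    names = np.array(leaves)
    for _ in range(n_permutations):
        perm = rng.permutation(len(names))
        mapping = dict(zip(names, names[perm]))
        null = _wrfd_from_splits(s1, _permute_splits(s2, mapping, leaves))
        if null <= observed:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return TreeComparison(
        id_a=id_a, id_b=id_b, wrfd=observed, p_value=p,
        n_permutations=n_permutations,
    )


def compare_all(
    trees: Mapping[str, TreeNode],
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    tree_method: str = "nj",
) -> tuple[pd.DataFrame, pd.DataFrame, TreeNode]:
    """All-pairs wRFD matrix, permutation p-values, and the second-level
    dendrogram built from the wRFD matrix itself."""
    names = list(trees)
    k = len(names)
    dists = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    pvals = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, k):
            b = names[j]
            cmp_ = permutation_test(
                trees[a], trees[b], n_permutations=n_permutations,
                seed=None if seed is None else seed + 997 * (i * k + j),
                id_a=a, id_b=b,
            )
            dists.loc[a, b] = dists.loc[b, a] = cmp_.wrfd
            pvals.loc[a, b] = pvals.loc[b, a] = cmp_.p_value
    meta_dm = _as_distance_matrix(dists.to_numpy(), names)
    meta_tree = build_tree(meta_dm, method=tree_method)
    return dists, pvals, meta_tree


def significance_stars(p: float) -> str:
    """Conventional significance annotation for wRFD tables."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def read_newick(path_or_str: Union[str, io.TextIOBase]) -> TreeNode:
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(path_or_str))
    return TreeNode.read(path_or_str)
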
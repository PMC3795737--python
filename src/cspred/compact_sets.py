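"""Compact-set enumeration over a distance matrix.

A subset ``C`` of items is a *compact set* when its smallest external
distance strictly exceeds its largest internal distance:

    min{ D(i, k) : i in C, k not in C }  >  max{ D(i, j) : i, j in C }.

The whole item set ``V`` and every singleton are trivially compact.  All
nontrivial compact sets are found in two steps:

1. build the Kruskal merging-order tree (the *merge tree*): process edges in
   non-decreasing weight order with a union-find; every edge that joins
   two components creates an internal node over them carrying that
   edge's weight.  Its merge heights coincide with single-linkage
   clustering, and every compact set appears as the leaf set of one of
   its internal nodes (the candidate property).
2. verify each candidate: an internal node's leaf set is compact iff
   its largest internal distance is smaller than its parent's merge
   weight (which equals the set's minimum external distance).  Failed
   candidates are contracted into their parent, leaving the laminar,
   possibly non-binary compact-set tree.

Construction is O(M log N) in the number of edges M and items N; a
2^N brute-force enumerator is provided as an independent oracle.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with item identifiers."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.ids)
        if n < 2:
            raise ValueError("a distance matrix needs at least 2 items")
        if values.shape != (n, n):
            raise ValueError("distance matrix shape does not match its ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate item ids in distance matrix")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(values < 0):
            raise ValueError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, item: str) -> int:
        try:
            return self.ids.index(item)
        except ValueError:
            raise KeyError(f"unknown item id {item!r}") from None

    @classmethod
    def from_points(cls, points: np.ndarray, ids: Sequence[str] | None = None) -> "DistanceMatrix":
        """Euclidean distance matrix of row-vector coordinates."""
        from scipy.spatial.distance import pdist, squareform

        points = np.asarray(points, dtype=float)
        if ids is None:
            ids = [f"item{i}" for i in range(points.shape[0])]
        return cls(tuple(ids), squareform(pdist(points)))

    def write_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column ids differ")
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# the merge tree
# ---------------------------------------------------------------------------

@dataclass
class MergeNode:
    """Node of the Kruskal merging-order tree.

    Leaves carry ``weight = None``; an internal node's weight is the
    weight of the edge whose processing merged its two children, which
    equals the minimum external distance of both merged groups.
    """

    index: int
    leaves: frozenset[int]
    weight: float | None = None
    children: tuple["MergeNode", ...] = ()
    parent: "MergeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return self.weight is None


@dataclass
class MergeTree:
    """Kruskal merging-order tree: the candidate compact-set hierarchy."""

    ids: tuple[str, ...]
    root: MergeNode
    internal_nodes: list[MergeNode]  # in merge (non-decreasing weight) order

    def members(self, node: MergeNode) -> frozenset[str]:
        return frozenset(self.ids[i] for i in node.leaves)


def _sorted_edges(D: DistanceMatrix) -> list[tuple[float, int, int]]:
    n = D.n
    return sorted(
        (float(D.values[i, j]), i, j) for i in range(n) for j in range(i + 1, n)
    )


def build_kruskal_tree(
    D: DistanceMatrix,
    edge_order: Sequence[tuple[float, int, int]] | None = None,
) -> MergeTree:
    """Build the merge tree by Kruskal-style edge merging with union-find.

    Edges are processed in non-decreasing weight, ties broken by the
    lexicographic item-index pair for reproducibility (``edge_order``
    overrides the ordering, for tie-invariance experiments).  Each edge
    joining two components creates an internal node over their current
    trees, annotated with the edge weight.
    """
    n = D.n
    edges = list(edge_order) if edge_order is not None else _sorted_edges(D)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    trees: dict[int, MergeNode] = {
        i: MergeNode(index=i, leaves=frozenset([i])) for i in range(n)
    }
    internal: list[MergeNode] = []
    next_index = n
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        node = MergeNode(
            index=next_index,
            leaves=trees[ri].leaves | trees[rj].leaves,
            weight=w,
            children=(trees[ri], trees[rj]),
        )
        trees[ri].parent = node
        trees[rj].parent = node
        next_index += 1
        internal.append(node)
        parent[ri] = rj
        trees[rj] = node
        del trees[ri]
        if len(node.leaves) == n:
            break
    root = internal[-1]
    assert len(internal) == n - 1 and len(root.leaves) == n
    return MergeTree(ids=D.ids, root=root, internal_nodes=internal)


def extract_candidates(tree: MergeTree) -> list[frozenset[str]]:
    """Leaf sets of all non-root internal nodes: the candidate compact sets."""
    return [tree.members(nd) for nd in tree.internal_nodes if nd is not tree.root]


# ---------------------------------------------------------------------------
# the compact-set predicate
# ---------------------------------------------------------------------------

def is_compact(C: Iterable[str], D: DistanceMatrix) -> bool:
    """Strict compact-set predicate for an arbitrary subset.

    ``V`` itself is compact by definition.  For a singleton the internal
    maximum is the empty-set convention 0 and the external minimum is
    compared strictly.  Ties (min external == max internal) fail.
    """
    members = set(C)
    if not members:
        raise ValueError("compact-set predicate is undefined for the empty set")
    idx = np.array(sorted(D.index_of(m) for m in members))
    if len(idx) == D.n:
        return True
    out = np.setdiff1d(np.arange(D.n), idx)
    max_internal = float(D.values[np.ix_(idx, idx)].max()) if len(idx) > 1 else 0.0
    min_external = float(D.values[np.ix_(idx, out)].min())
    return min_external > max_internal


def compact_sets_bruteforce(D: DistanceMatrix, max_items: int = 15) -> set[frozenset[str]]:
    """All nontrivial compact sets by direct 2^N enumeration (test oracle)."""
    if D.n > max_items:
        raise ValueError(f"brute force limited to {max_items} items (got {D.n})")
    found: set[frozenset[str]] = set()
    indices = range(D.n)
    for size in range(2, D.n):
        for combo in itertools.combinations(indices, size):
            idx = np.array(combo)
            out = np.setdiff1d(np.arange(D.n), idx)
            if D.values[np.ix_(idx, out)].min() > D.values[np.ix_(idx, idx)].max():
                found.add(frozenset(D.ids[i] for i in combo))
    return found


# ---------------------------------------------------------------------------
# verification: the compact-set tree
# ---------------------------------------------------------------------------

@dataclass
class CompactSetNode:
    """Node of the verified compact-set tree."""

    members: frozenset[str]
    max_internal: float
    min_external: float | None  # None for the root (V has no exterior)
    children: list["CompactSetNode"] = field(default_factory=list)

    @property
    def is_trivial(self) -> bool:
        return len(self.members) <= 1


@dataclass
class CompactSetTree:
    """Laminar, possibly non-binary hierarchy of verified compact sets."""

    ids: tuple[str, ...]
    root: CompactSetNode

    def nontrivial_sets(self) -> set[frozenset[str]]:
        """All verified nontrivial compact sets (excludes singletons and V)."""
        out: set[frozenset[str]] = set()

        def walk(node: CompactSetNode) -> None:
            if node is not self.root and len(node.members) >= 2:
                out.add(node.members)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def sets_containing(self, item: str) -> list[frozenset[str]]:
        """Nontrivial compact sets containing ``item``, largest first.

        Laminarity makes these totally ordered by inclusion.
        """
        hits = [s for s in self.nontrivial_sets() if item in s]
        return sorted(hits, key=len, reverse=True)


def _max_internal_bottom_up(tree: MergeTree, D: DistanceMatrix) -> dict[int, float]:
    """Largest internal distance per internal node, by cross-child scan."""
    out: dict[int, float] = {}

    def visit(node: MergeNode) -> float:
        if node.is_leaf:
            return 0.0
        best = 0.0
        for ch in node.children:
            best = max(best, visit(ch))
        a, b = node.children
        ia = np.fromiter(a.leaves, dtype=int)
        ib = np.fromiter(b.leaves, dtype=int)
        best = max(best, float(D.values[np.ix_(ia, ib)].max()))
        out[node.index] = best
        return best

    visit(tree.root)
    return out


def _max_internal_lca(tree: MergeTree, D: DistanceMatrix) -> dict[int, float]:
    """Same quantity via the least-common-ancestor formulation.

    Every item pair's distance is charged to the LCA of the two leaves in
    the merge tree; a node's largest internal distance is then the maximum
    charge in its subtree.  Kept as the documented algorithm; must agree
    with the cross-child scan.
    """
    # map leaf index -> path of ancestor node indices via parent pointers
    leaf_nodes: dict[int, MergeNode] = {}

    def collect(node: MergeNode) -> None:
        if node.is_leaf:
            leaf_nodes[node.index] = node
        for ch in node.children:
            collect(ch)

    collect(tree.root)

    depth: dict[int, int] = {}

    def set_depth(node: MergeNode, d: int) -> None:
        depth[node.index] = d
        for ch in node.children:
            set_depth(ch, d + 1)

    set_depth(tree.root, 0)

    def lca(u: MergeNode, v: MergeNode) -> MergeNode:
        while u is not v:
            if depth[u.index] >= depth[v.index]:
                u = u.parent  # type: ignore[assignment]
            else:
                v = v.parent  # type: ignore[assignment]
        return u

    charge: dict[int, float] = {}
    n = D.n
    for i in range(n):
        for j in range(i + 1, n):
            anc = lca(leaf_nodes[i], leaf_nodes[j])
            w = float(D.values[i, j])
            if charge.get(anc.index, -np.inf) < w:
                charge[anc.index] = w

    out: dict[int, float] = {}

    def visit(node: MergeNode) -> float:
        best = charge.get(node.index, 0.0)
        for ch in node.children:
            best = max(best, visit(ch))
        if not node.is_leaf:
            out[node.index] = best
        return best

    visit(tree.root)
    return out


def verify_compact_sets(
    tree: MergeTree,
    D: DistanceMatrix,
    method: str = "scan",
) -> CompactSetTree:
    """Verify merge-tree candidates and contract failures into the compact-set tree.

    A non-root internal node is a compact set iff its largest internal
    distance is strictly below its parent's merge weight (the set's
    minimum external distance).  Children of a failed candidate are
    re-parented to the nearest verified (or root) ancestor, so the verified
    tree may be non-binary.
    """
    if tree.ids != D.ids:
        raise ValueError("merge tree and distance matrix carry different items")
    if method == "scan":
        max_internal = _max_internal_bottom_up(tree, D)
    elif method == "lca":
        max_internal = _max_internal_lca(tree, D)
    else:
        raise ValueError(f"unknown verification method {method!r}")

    def convert(node: MergeNode) -> CompactSetNode:
        kept_children: list[CompactSetNode] = []

        def gather(child: MergeNode) -> None:
            if child.is_leaf:
                kept_children.append(
                    CompactSetNode(
                        members=frozenset([tree.ids[next(iter(child.leaves))]]),
                        max_internal=0.0,
                        min_external=node_weight_above(child),
                    )
                )
                return
            if max_internal[child.index] < child.parent.weight:  # type: ignore[union-attr]
                kept_children.append(convert(child))
            else:
                # contraction: splice the failed candidate's children up
                for gc in child.children:
                    gather(gc)

        def node_weight_above(child: MergeNode) -> float:
            return float(child.parent.weight)  # type: ignore[union-attr]

        for ch in node.children:
            gather(ch)
        return CompactSetNode(
            members=tree.members(node),
            max_internal=max_internal[node.index],
            min_external=(
                float(node.parent.weight) if node.parent is not None else None
            ),
            children=kept_children,
        )

    return CompactSetTree(ids=tree.ids, root=convert(tree.root))


def nontrivial_compact_sets(D: DistanceMatrix) -> set[frozenset[str]]:
    """Convenience: build, verify, and list the nontrivial compact sets."""
    return verify_compact_sets(build_kruskal_tree(D), D).nontrivial_sets()


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def merge_tree_to_newick(tree: MergeTree) -> str:
    """Newick string of the merge tree, merge weights as internal labels."""

    def fmt(node: MergeNode) -> str:
        if node.is_leaf:
            return tree.ids[next(iter(node.leaves))]
        inner = ",".join(fmt(ch) for ch in node.children)
        return f"({inner}){node.weight:g}"

    return fmt(tree.root) + ";"


def compact_tree_to_newick(tree: CompactSetTree) -> str:
    """Newick string of the compact-set tree (non-binary nodes allowed)."""

    def fmt(node: CompactSetNode) -> str:
        if len(node.members) == 1:
            return next(iter(node.members))
        inner = ",".join(fmt(ch) for ch in node.children)
        label = f"{node.max_internal:g}"
        return f"({inner}){label}"

    return fmt(tree.root) + ";"


def merge_tree_to_dict(tree: MergeTree) -> dict:
    """JSON-serializable nested representation of the merge tree."""

    def conv(node: MergeNode) -> dict:
        if node.is_leaf:
            return {"leaf": tree.ids[next(iter(node.leaves))]}
        return {
            "weight": node.weight,
            "members": sorted(tree.ids[i] for i in node.leaves),
            "children": [conv(ch) for ch in node.children],
        }

    return conv(tree.root)


def compact_tree_to_dict(tree: CompactSetTree) -> dict:
    """JSON-serializable nested representation of the compact-set tree."""

    def conv(node: CompactSetNode) -> dict:
        return {
            "members": sorted(node.members),
            "max_internal": node.max_internal,
            "min_external": node.min_external,
            "children": [conv(ch) for ch in node.children],
        }

    return conv(tree.root)


def write_compact_sets_tsv(tree: CompactSetTree, path: Union[str, Path]) -> None:
    """One verified nontrivial set per line: members, max-internal, min-external."""
    rows = []

    def walk(node: CompactSetNode) -> None:
        if node is not tree.root and len(node.members) >= 2:
            rows.append(
                {
                    "members": ",".join(sorted(node.members)),
                    "size": len(node.members),
                    "max_internal": node.max_internal,
                    "min_external": node.min_external,
                }
            )
        for ch in node.children:
            walk(ch)

    walk(tree.root)
    pd.DataFrame(rows, columns=["members", "size", "max_internal", "min_external"]).to_csv(
        path, sep="\t", index=False
    )


def write_compact_tree_json(tree: CompactSetTree, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(compact_tree_to_dict(tree), indent=1))
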
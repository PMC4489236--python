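"""Distance estimation, neighbor joining, column bootstrap and Newick I/O.

This is the guide-tree-uncertainty component: bootstrap the columns of an
alignment, re-estimate pairwise distances, and build a fresh NJ guide tree
for every ensemble member.  Trees are rooted (midpoint) and binary, with a
deterministic child order so that the progressive merge schedule — and hence
the head/tail orientation indexing — is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import dendropy
import numpy as np

from alnconf.msa import GAP_CODE, Msa, msa_from_encoded

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances over named taxa."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


class TreeNode:
    """Node of a rooted binary tree.

    ``length`` is the branch length to the parent (0.0 at the root).
    Children are kept ordered by the smallest leaf label under each child,
    which fixes a deterministic merge schedule.
    """

    __slots__ = ("name", "children", "length", "_min_leaf")

    def __init__(
        self,
        name: str | None = None,
        children: list["TreeNode"] | None = None,
        length: float = 0.0,
    ) -> None:
        self.name = name
        self.children: list[TreeNode] = children or []
        self.length = float(length)
        self._min_leaf: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def min_leaf(self) -> str:
        if self._min_leaf is None:
            if self.is_leaf:
                self._min_leaf = self.name or ""
            else:
                self._min_leaf = min(c.min_leaf() for c in self.children)
        return self._min_leaf


@dataclass
class Tree:
    """Rooted binary tree with branch lengths and ordered children."""

    root: TreeNode

    def __post_init__(self) -> None:
        self._normalize(self.root)
        names = [leaf.name for leaf in self.leaves()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels in tree")
        for node in self.postorder():
            if not node.is_leaf and len(node.children) != 2:
                raise ValueError("tree is not binary")

    def _normalize(self, node: TreeNode) -> None:
        for c in node.children:
            self._normalize(c)
        node.children.sort(key=lambda c: c.min_leaf())

    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        """Internal nodes in postorder — the deterministic merge schedule."""
        return [n for n in self.postorder() if not n.is_leaf]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def p_distance(msa: Msa) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion of gap sites.

    ``d[i, j]`` = mismatches / sites where both i and j have residues.  Pairs
    sharing zero ungapped sites get distance 1 by convention (logged).
    """
    if msa.n_sequences < 2:
        raise ValueError("p_distance requires at least 2 sequences")
    enc = msa.encoded().astype(np.int16)
    res = enc != GAP_CODE
    n = msa.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = res[i] & res[j]
            ns = int(shared.sum())
            if ns == 0:
                logger.warning(
                    "no shared ungapped sites between %s and %s; distance set to 1",
                    msa.ids[i],
                    msa.ids[j],
                )
                d[i, j] = d[j, i] = 1.0
            else:
                mism = int(np.count_nonzero(enc[i, shared] != enc[j, shared]))
                d[i, j] = d[j, i] = mism / ns
    return DistanceMatrix(msa.ids, d)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj(dm: DistanceMatrix) -> Tree:
    """Neighbor joining (Q-criterion) followed by midpoint rooting.

    Ties in the Q minimization are broken toward the lowest (i, j) index
    pair; negative branch-length estimates are clamped to zero.  The
    unrooted NJ tree is rooted at the midpoint of its longest leaf-to-leaf
    path, and children are ordered by smallest contained leaf label.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("nj requires at least 2 taxa")
    if n == 2:
        a, b = dm.labels
        half = dm.d[0, 1] / 2.0
        return Tree(TreeNode(children=[TreeNode(a, length=half), TreeNode(b, length=half)]))

    # Work on an unrooted tree represented as an adjacency map.
    next_id = [0]

    def fresh() -> str:
        next_id[0] += 1
        return f"@{next_id[0]}"

    nodes = list(dm.labels)
    adj: dict[str, dict[str, float]] = {u: {} for u in nodes}
    d = dm.d.copy()
    active = list(range(n))
    names = {i: dm.labels[i] for i in range(n)}

    def join(i: int, j: int, li: float, lj: float) -> int:
        u = fresh()
        adj[u] = {}
        _add_edge(adj, u, names[i], max(li, 0.0))
        _add_edge(adj, u, names[j], max(lj, 0.0))
        k = len(names)
        names[k] = u
        return k

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minimizers, in active-index order
        flat = np.argmin(q)
        bi, bj = divmod(int(flat), m)
        best = q[bi, bj]
        tie = np.argwhere(np.isclose(q, best, rtol=0, atol=1e-12))
        bi, bj = min((min(a, b), max(a, b)) for a, b in tie)
        i, j = active[bi], active[bj]
        dij = d[i, j]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        k = join(i, j, li, lj)
        # distances from the new node to the remaining taxa
        newd = np.zeros(k)
        for bx in range(m):
            x = active[bx]
            if x in (i, j):
                continue
            newd[x] = 0.5 * (d[i, x] + d[j, x] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, :k] = newd
        d[:k, k] = newd
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    _add_edge(adj, names[i], names[j], max(d[i, j], 0.0))

    return _midpoint_root(adj, set(dm.labels))


def _add_edge(adj: dict[str, dict[str, float]], u: str, v: str, w: float) -> None:
    adj.setdefault(u, {})[v] = w
    adj.setdefault(v, {})[u] = w


def _farthest(adj: dict[str, dict[str, float]], start: str, leaves: set[str]):
    """(leaf, distance, path) of the farthest leaf from ``start``."""
    best = (start, -1.0, [start])
    stack = [(start, None, 0.0, [start])]
    while stack:
        u, parent, dist, path = stack.pop()
        if u in leaves and dist > best[1]:
            best = (u, dist, path)
        for v, w in adj[u].items():
            if v != parent:
                stack.append((v, u, dist + w, path + [v]))
    return best


def _midpoint_root(adj: dict[str, dict[str, float]], leaves: set[str]) -> Tree:
    start = next(iter(leaves))
    a, _, _ = _farthest(adj, start, leaves)
    b, diam, path = _farthest(adj, a, leaves)
    half = diam / 2.0
    # walk the a->b path to find the edge containing the midpoint
    acc = 0.0
    for idx in range(len(path) - 1):
        u, v = path[idx], path[idx + 1]
        w = adj[u][v]
        if acc + w >= half - 1e-12:
            du = half - acc  # distance from u to the root along this edge
            du = min(max(du, 0.0), w)
            return _orient(adj, u, v, du, w - du)
        acc += w
    # degenerate (zero diameter): root on any edge adjacent to a
    u = a
    v = next(iter(adj[a]))
    return _orient(adj, u, v, 0.0, adj[u][v])


def _orient(
    adj: dict[str, dict[str, float]], u: str, v: str, du: float, dv: float
) -> Tree:
    """Root on the edge (u, v), ``du`` from u, and build the rooted tree."""

    def build(node: str, parent: str | None, length: float) -> TreeNode:
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            return TreeNode(node, length=length)
        if len(kids) == 1 and not node.startswith("@"):
            # labelled internal node (should not occur for NJ output)
            child = build(kids[0], node, adj[node][kids[0]])
            return TreeNode(node, children=[child], length=length)
        children = [build(x, node, adj[node][x]) for x in kids]
        if len(children) == 1:
            # suppress unifurcation created by removing the old root edge
            child = children[0]
            child.length += length
            return child
        return TreeNode(children=children, length=length)

    left = build(u, v, du)
    right = build(v, u, dv)
    return Tree(TreeNode(children=[left, right]))


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_msa(msa: Msa, rng: np.random.Generator) -> Msa:
    """Resample alignment columns uniformly with replacement.

    The result is used only for distance and tree estimation; it is never an
    alignment of the data.  All-gap columns never arise because every sampled
    column is a column of the input.
    """
    idx = rng.integers(0, msa.length, size=msa.length)
    enc = msa.encoded()[:, idx]
    return msa_from_encoded(msa.ids, enc)


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(path: str | Path) -> Tree:
    """Read a rooted tree from a Newick file.

    Missing branch lengths default to 0.  Trees whose root has more than two
    children are rejected (guide trees must be binary after rooting).
    """
    dt = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(node: dendropy.Node) -> TreeNode:
        length = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if not label:
                raise ValueError("leaf without a label in Newick input")
            return TreeNode(label.replace(" ", "_"), length=length)
        return TreeNode(
            children=[convert(c) for c in node.child_nodes()], length=length
        )

    return Tree(convert(dt.seed_node))


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def leaf_depths(tree: Tree) -> dict[str, float]:
    """Root-to-leaf path lengths."""
    out: dict[str, float] = {}

    def walk(node: TreeNode, depth: float) -> None:
        if node.is_leaf:
            out[node.name] = depth
        for c in node.children:
            walk(c, depth + c.length)

    walk(tree.root, 0.0)
    return out


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric difference of splits)."""
    taxa = frozenset(t1.leaf_names())
    if taxa != frozenset(t2.leaf_names()):
        raise ValueError("trees are over different taxon sets")

    def splits(t: Tree) -> set[frozenset[str]]:
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in t.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if 1 < len(s) < len(taxa) - 1:
                    side = min(s, taxa - s, key=lambda x: (len(x), sorted(x)))
                    out.add(frozenset(side))
        return out

    return len(splits(t1) ^ splits(t2))
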
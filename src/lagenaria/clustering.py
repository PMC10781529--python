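"""UPGMA dendrograms, Newick export, cophenetic distances, tree cuts.

Clustering operates on the complement distance d = 1 - s of a
similarity matrix. UPGMA proper (unweighted pair-group method with
arithmetic mean) merges, at every step, the pair of clusters with the
smallest average inter-cluster distance, the average taken over all
leaf pairs (i.e. size-weighted when updating), and is exact on
ultrametric inputs.

Determinism: when several cluster pairs tie for the minimal distance,
the pair whose smallest member label sorts lexicographically first is
merged (ties broken further by the other cluster's smallest label).
Newick children are ordered with the subtree containing the
lexicographically smallest leaf first. Both rules exist so identical
inputs always yield byte-identical trees.

Merge heights are recorded as the full average pair distance; branch
lengths in Newick follow the ultrametric convention that a leaf sits
at depth height/2 below a merge at that height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["Merge", "Dendrogram", "upgma", "to_newick", "cophenetic", "cut"]


@dataclass(frozen=True)
class Merge:
    """One agglomeration: node ids of the two children and the average
    leaf-pair distance at which they join. Leaves are ids 0..n-1 in
    input order; merge k creates node n+k."""

    left: int
    right: int
    height: float


@dataclass
class Dendrogram:
    """Rooted ultrametric tree as an ordered merge list."""

    leaves: list[str]
    merges: list[Merge]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [m.height for m in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError(f"merge heights must be non-decreasing: {heights}")

    @property
    def n(self) -> int:
        return len(self.leaves)

    def members(self, node: int) -> frozenset[str]:
        """Leaf labels under a node id."""
        if node < self.n:
            return frozenset((self.leaves[node],))
        m = self.merges[node - self.n]
        return self.members(m.left) | self.members(m.right)

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n else self.merges[node - self.n].height

    def clades(self) -> set[frozenset[str]]:
        """All non-singleton clades (for topology comparison)."""
        return {self.members(self.n + k) for k in range(len(self.merges))}


def _min_leaf(labels: frozenset[str]) -> str:
    return min(labels)


def upgma(s: SimilarityMatrix) -> Dendrogram:
    """Build the UPGMA tree of a similarity matrix on d = 1 - s."""
    if s.n < 2:
        raise ValueError("UPGMA requires at least 2 genotypes")
    n = s.n
    labels = s.genotypes
    dist = {}  # frozen pair of active node ids -> average distance
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> leaf count
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    d0 = s.distance()
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = d0[i, j]

    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        # minimal average distance; lexicographic tie-break on the
        # sorted pair of each side's smallest leaf label
        best = None
        for pair, d in dist.items():
            i, j = sorted(pair)
            key = (d, *sorted((minlab[i], minlab[j])))
            if best is None or key < best[0]:
                best = (key, i, j, d)
        _, i, j, d = best
        ni, nj = active[i], active[j]
        merges.append(Merge(i, j, d))
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            dk = (ni * dist[frozenset((i, k))] + nj * dist[frozenset((j, k))]) / (
                ni + nj
            )
            dist[frozenset((new, k))] = dk
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        del active[i], active[j]
        active[new] = ni + nj
        minlab[new] = min(minlab[i], minlab[j])
    return Dendrogram(list(labels), merges)


def to_newick(tree: Dendrogram, ndigits: int = 6) -> str:
    """Serialize with ultrametric branch lengths (leaf depth = height/2).

    Child order: the subtree holding the lexicographically smallest
    leaf comes first, making the output deterministic.
    """

    def depth(node: int) -> float:
        return tree.node_height(node) / 2.0

    def fmt(x: float) -> str:
        return f"{round(x, ndigits):g}"

    def render(node: int, parent_depth: float) -> str:
        bl = fmt(parent_depth - depth(node))
        if node < tree.n:
            return f"{tree.leaves[node]}:{bl}"
        m = tree.merges[node - tree.n]
        kids = sorted(
            (m.left, m.right), key=lambda c: _min_leaf(tree.members(c))
        )
        inner = ",".join(render(c, depth(node)) for c in kids)
        return f"({inner}):{bl}"

    root = tree.n + len(tree.merges) - 1
    m = tree.merges[-1]
    kids = sorted((m.left, m.right), key=lambda c: _min_leaf(tree.members(c)))
    inner = ",".join(render(c, depth(root)) for c in kids)
    return f"({inner});"


def cophenetic(tree: Dendrogram) -> tuple[list[str], np.ndarray]:
    """Distance at which each leaf pair first co-clusters.

    Returns (labels, matrix); the matrix is ultrametric: for any three
    leaves the maximum pairwise value is attained at least twice.
    """
    n = tree.n
    index = {lab: i for i, lab in enumerate(tree.leaves)}
    out = np.zeros((n, n))
    for k, m in enumerate(tree.merges):
        left = tree.members(m.left)
        right = tree.members(m.right)
        for x in left:
            for y in right:
                out[index[x], index[y]] = out[index[y], index[x]] = m.height
    return list(tree.leaves), out


def cut(tree: Dendrogram, k: int) -> list[set[str]]:
    """Partition the leaves into k clusters by removing the k-1 highest
    (i.e. last) merges. Clusters are ordered by smallest member label."""
    if not (1 <= k <= tree.n):
        raise ValueError(f"k must be in 1..{tree.n}, got {k}")
    parent: dict[str, str] = {lab: lab for lab in tree.leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in tree.merges[: tree.n - k]:
        left = _min_leaf(tree.members(m.left))
        right = _min_leaf(tree.members(m.right))
        parent[find(right)] = find(left)
    groups: dict[str, set[str]] = {}
    for lab in tree.leaves:
        groups.setdefault(find(lab), set()).add(lab)
    return sorted(groups.values(), key=_min_leaf)
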
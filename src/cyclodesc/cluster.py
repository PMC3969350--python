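"""Ward hierarchical clustering of descriptor space.

Peptides are clustered on the four descriptors (E_M, E_S, L_M, L_S*) after
per-column min-max normalization to [0, 1], using Ward's minimum-variance
criterion via the reciprocal-nearest-neighbour (RNN) chain algorithm with
the Lance–Williams update.  Heights follow the same convention as classic
Ward linkage (initial inter-point distance = Euclidean distance), so the
merge sequence is directly comparable to any standard Ward implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterTree",
    "normalize_descriptors",
    "ward_cluster",
    "cut",
    "make_leaf_labels",
]


def normalize_descriptors(matrix) -> np.ndarray:
    """Per-column min-max scaling to [0, 1]; constant columns map to 0."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if np.isnan(X).any():
        bad = sorted(set(np.where(np.isnan(X))[0]))
        raise ValueError(f"missing values in rows: {bad}")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = np.zeros_like(X)
    const = span == 0
    if const.any():
        warnings.warn(f"constant descriptor column(s) {np.where(const)[0].tolist()} set to 0")
    nz = ~const
    out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return out


@dataclass
class ClusterTree:
    """Merge sequence in linkage-matrix form plus leaf labels.

    ``linkage`` rows are (left, right, height, size) with cluster ids
    0..n-1 for leaves and n+t for the cluster created at merge t; merges
    are sorted by non-decreasing height.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> list[tuple[frozenset, float]]:
        """(member-set, height) per merge, in merge order."""
        n = self.n_leaves
        members = {i: frozenset([i]) for i in range(n)}
        out = []
        for t, (a, b, h, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + t] = merged
            out.append((merged, float(h)))
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge-height differences."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i].replace(" ", "_") for i in range(n)}
        for t, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + t] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + t] = h
        return node[n + len(self.linkage) - 1] + ";"


def _ward_update(d_ik: float, d_jk: float, d_ij: float,
                 si: int, sj: int, sk: int) -> float:
    """Lance–Williams Ward recurrence on distances (scipy convention)."""
    s = si + sj + sk
    return np.sqrt(
        ((si + sk) * d_ik ** 2 + (sj + sk) * d_jk ** 2 - sk * d_ij ** 2) / s
    )


def ward_cluster(matrix, labels: list[str] | None = None) -> ClusterTree:
    """Ward clustering by the reciprocal-nearest-neighbour chain algorithm.

    A chain of nearest neighbours is grown until two clusters are mutual
    nearest neighbours; those are merged and the chain rewinds.  Ward's
    reducibility guarantees the resulting dendrogram equals the one found
    by always merging the globally closest pair.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    if labels is None:
        labels = [str(i) for i in range(n)]

    # full distance matrix, updated in place; inactive rows masked with inf
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(D, np.inf)
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    pos = {i: i for i in range(n)}     # cluster id -> row in D
    merges = []                        # (id_a, id_b, height, new_id)
    next_id = n
    chain: list[int] = []
    while len(active) > 1:
        if not chain:
            chain.append(next(iter(active)))
        while True:
            c = chain[-1]
            row = D[pos[c]]
            j_pos = int(np.argmin(row))
            d = row[j_pos]
            nn = next(k for k in active if pos[k] == j_pos)
            if len(chain) >= 2 and nn == chain[-2]:
                break
            chain.append(nn)
        b = chain.pop()
        a = chain.pop()
        h = D[pos[a], pos[b]]
        # merge b into a's row
        ra, rb = pos[a], pos[b]
        for k in active:
            if k in (a, b):
                continue
            rk = pos[k]
            D[ra, rk] = D[rk, ra] = _ward_update(
                D[ra, rk], D[rb, rk], h, size[a], size[b], size[k]
            )
        D[rb, :] = np.inf
        D[:, rb] = np.inf
        D[ra, ra] = np.inf
        new = next_id
        next_id += 1
        merges.append((a, b, float(h), new))
        active.discard(a)
        active.discard(b)
        active.add(new)
        size[new] = size[a] + size[b]
        pos[new] = ra

    # sort merges by height and relabel to the standard linkage convention
    order = sorted(range(len(merges)), key=lambda t: merges[t][2])
    relabel = {i: i for i in range(n)}
    Z = np.zeros((n - 1, 4))
    for new_t, t in enumerate(order):
        a, b, h, old_id = merges[t]
        ia, ib = relabel[a], relabel[b]
        if ib < ia:
            ia, ib = ib, ia
        Z[new_t] = (ia, ib, h, 0)
        relabel[old_id] = n + new_t
    # sizes
    sizes = np.ones(2 * n - 1)
    for t in range(n - 1):
        sizes[n + t] = sizes[int(Z[t, 0])] + sizes[int(Z[t, 1])]
        Z[t, 3] = sizes[n + t]
    return ClusterTree(linkage=Z, labels=list(labels))


def cut(tree: ClusterTree, k: int) -> np.ndarray:
    """Group assignment (1..k) from cutting the dendrogram into k clusters.

    Groups are numbered by order of first appearance along the leaves.
    """
    n = tree.n_leaves
    if k > n or k < 1:
        raise ValueError(f"k must be in 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(tree.linkage[t, 0]), int(tree.linkage[t, 1])
        parent[find(a)] = parent[find(b)] = n + t
    roots = {}
    out = np.zeros(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        out[i] = roots[r]
    return out


def make_leaf_labels(groups, activity_classes, subfamilies, numbers) -> list[str]:
    """Dendrogram leaf labels in G{group}-A{class}-{subfamily}{num} style,
    e.g. ``G1-A2-M33``."""
    out = []
    for g, ac, sf, num in zip(groups, activity_classes, subfamilies, numbers):
        ac = ac if str(ac).startswith("A") else f"A{ac}"
        out.append(f"G{g}-{ac}-{sf}{num}")
    return out
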
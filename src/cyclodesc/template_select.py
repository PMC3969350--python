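"""Template selection for homology modeling from a bootstrap-annotated tree.

Given a neighbour-joining cladogram over target and known-structure
sequences (bootstrap support as internal-node labels), the rules are:

* **A** — the target's sister is a single leaf of known structure *b*:
  take {b} when the bootstrap support of the (target, b) clade exceeds
  50%, otherwise {b, c} with c the nearest other known leaf by
  topological path length (ties alphabetical).
* **B** — the sister clade is exactly two known leaves {b, c}: take both,
  regardless of support.
* **C** — the sister clade contains two or more known leaves (any
  arrangement): choose two uniformly at random (seeded).
* Fallback — otherwise, the nearest known leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["SupportTree", "select_templates"]


@dataclass
class SupportTree:
    """Rooted tree with bootstrap support (%) and known-structure flags."""

    tree: dendropy.Tree
    known: set[str] = field(default_factory=set)

    @classmethod
    def from_newick(cls, source: str, known, is_path: bool = False) -> "SupportTree":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        return cls(tree=tree, known=set(known))

    def leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon is not None and lf.taxon.label == label:
                return lf
        raise KeyError(f"leaf {label!r} not in tree")

    def known_leaves(self) -> list[str]:
        return sorted(
            lf.taxon.label for lf in self.tree.leaf_node_iter()
            if lf.taxon is not None and lf.taxon.label in self.known
        )


def _support(node: dendropy.Node) -> float | None:
    """Bootstrap support of an internal node (label, dendropy convention)."""
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            pass
    if node.taxon is not None and node.taxon.label is not None:
        try:
            return float(node.taxon.label)
        except ValueError:
            pass
    return None


def _edge_distances(start: dendropy.Node) -> dict[str, int]:
    """Topological (edge-count) distance from a leaf to every other leaf."""
    # climb to root, recording depth of each ancestor; then descend
    dist: dict[str, int] = {}
    seen = {id(start)}
    frontier = [(start, 0)]
    while frontier:
        node, d = frontier.pop()
        if node.is_leaf() and node is not start and node.taxon is not None:
            dist[node.taxon.label] = d
        for nb in list(node.child_nodes()) + ([node.parent_node] if node.parent_node else []):
            if nb is not None and id(nb) not in seen:
                seen.add(id(nb))
                frontier.append((nb, d + 1))
    return dist


def _nearest_known(tree: SupportTree, target_leaf: dendropy.Node,
                   exclude: set[str]) -> str | None:
    dist = _edge_distances(target_leaf)
    candidates = [
        (d, lbl) for lbl, d in dist.items()
        if lbl in tree.known and lbl not in exclude
    ]
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1]))  # ties alphabetical
    return candidates[0][1]


def select_templates(tree: SupportTree, target: str, seed: int = 0) -> list[str]:
    """Template labels (1 or 2) for the target sequence; deterministic given
    (tree, target, seed)."""
    if not tree.known_leaves():
        raise ValueError("tree contains no leaves of known structure")
    leaf = tree.leaf(target)
    parent = leaf.parent_node
    sisters = [c for c in parent.child_nodes() if c is not leaf] if parent else []

    if len(sisters) == 1:
        sister = sisters[0]
        if sister.is_leaf():
            b = sister.taxon.label if sister.taxon else None
            if b is not None and b in tree.known:
                support = _support(parent)
                if support is not None and support > 50.0:
                    return [b]                                     # case A, strong
                c = _nearest_known(tree, leaf, exclude={b})
                return [b] if c is None else sorted([b, c])        # case A, weak
        else:
            sister_leaves = [
                lf.taxon.label for lf in sister.leaf_iter() if lf.taxon is not None
            ]
            known_in_sister = sorted(l for l in sister_leaves if l in tree.known)
            if len(sister_leaves) == 2 and len(known_in_sister) == 2:
                return known_in_sister                             # case B
            if len(known_in_sister) >= 2:                          # case C
                rng = np.random.default_rng(seed)
                pick = rng.choice(len(known_in_sister), size=2, replace=False)
                return sorted(known_in_sister[i] for i in pick)

    nearest = _nearest_known(tree, leaf, exclude=set())            # fallback
    return [nearest]
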
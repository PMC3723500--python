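"""Agglomerative construction of the binary diagnostic hierarchy.

Classes (or groups of classes) are merged bottom-up: at every step the two
current groups with the LOWEST pairwise separability — the best single
reversal pair's |delta| between the pooled groups — are joined, so the
hardest distinctions sit deepest in the tree and the easy, coarse decisions
sit near the root.  The result is a full binary tree: root holds all classes,
each leaf a single class, every internal node the disjoint union of its two
children.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .dataset import ExpressionDataset, PhenotypeSet
from .pairs import prefilter_features

__all__ = ["HierarchyNode", "DiagnosticHierarchy", "group_separability", "build_hierarchy"]


@dataclass
class HierarchyNode:
    node_id: int
    classes: PhenotypeSet
    parent: int | None = None
    children: tuple[int, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return len(self.children) == 0


class DiagnosticHierarchy:
    """Binary tree over phenotype sets; root = all classes, leaves = singletons.

    Node ids are breadth-first from the root (id 1), the left child being the
    group whose sorted class-name tuple is lexicographically smaller — so a
    serialized hierarchy is diff-stable across runs.
    """

    def __init__(self, nodes: dict[int, HierarchyNode], class_universe: PhenotypeSet) -> None:
        self.nodes = nodes
        self.class_universe = class_universe
        self.validate()

    # -- structure -------------------------------------------------------------

    @property
    def root(self) -> HierarchyNode:
        return self.nodes[1]

    @property
    def leaves(self) -> list[HierarchyNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    @property
    def internal_nodes(self) -> list[HierarchyNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    def children(self, node_id: int) -> tuple[HierarchyNode, ...]:
        return tuple(self.nodes[c] for c in self.nodes[node_id].children)

    def ancestors(self, node_id: int) -> list[int]:
        """Node ids from the parent up to (and including) the root."""
        out = []
        p = self.nodes[node_id].parent
        while p is not None:
            out.append(p)
            p = self.nodes[p].parent
        return out

    def leaf_for_class(self, label: str) -> HierarchyNode:
        for n in self.leaves:
            if n.classes == frozenset({label}):
                return n
        raise KeyError(f"no leaf for class {label!r}")

    def validate(self) -> None:
        c = len(self.class_universe)
        if len(self.nodes) != 2 * c - 1:
            raise ValueError(f"{len(self.nodes)} nodes for {c} classes; expected {2 * c - 1}")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].classes != self.class_universe:
            raise ValueError("hierarchy must have exactly one root holding all classes")
        leaves = self.leaves
        if len(leaves) != c or any(len(n.classes) != 1 for n in leaves):
            raise ValueError("leaves must be exactly the singleton classes")
        for n in self.internal_nodes:
            if len(n.children) != 2:
                raise ValueError(f"internal node {n.node_id} must have 2 children")
            a, b = (self.nodes[k] for k in n.children)
            if a.classes & b.classes or (a.classes | b.classes) != n.classes:
                raise ValueError(
                    f"node {n.node_id}: children must partition the node's class set"
                )
            for k in n.children:
                if self.nodes[k].parent != n.node_id:
                    raise ValueError(f"node {k} parent link inconsistent")

    # -- export ----------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "class_universe": sorted(self.class_universe),
            "nodes": [
                {
                    "node_id": n.node_id,
                    "classes": sorted(n.classes),
                    "parent": n.parent,
                    "children": list(n.children),
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosticHierarchy":
        nodes = {
            e["node_id"]: HierarchyNode(
                e["node_id"], frozenset(e["classes"]), e["parent"], tuple(e["children"])
            )
            for e in d["nodes"]
        }
        return cls(nodes, frozenset(d["class_universe"]))

    def to_newick(self) -> str:
        """Newick string with class-set labels, for quick visualization."""

        def render(node_id: int) -> str:
            n = self.nodes[node_id]
            label = "|".join(sorted(n.classes))
            if n.is_leaf:
                return label
            inner = ",".join(render(c) for c in n.children)
            return f"({inner}){label}"

        return render(1) + ";"


def _delta_values(
    dataset: ExpressionDataset,
    pos_idx: np.ndarray,
    neg_idx: np.ndarray,
    features: Sequence[str],
    block: int = 200_000,
) -> np.ndarray:
    """delta for every ordered pair over ``features``, blockwise for memory."""
    feat_pos = {f: k for k, f in enumerate(dataset.features)}
    idx = np.array([feat_pos[f] for f in features])
    x = dataset.values.to_numpy(dtype=float)[idx]
    g = len(features)
    ii, jj = np.nonzero(~np.eye(g, dtype=bool))
    out = np.empty(len(ii))
    for start in range(0, len(ii), block):
        sl = slice(start, start + block)
        z = x[ii[sl]] > x[jj[sl]]
        out[sl] = z[:, pos_idx].mean(axis=1) - z[:, neg_idx].mean(axis=1)
    return out


def group_separability(
    dataset: ExpressionDataset,
    group_a: PhenotypeSet,
    group_b: PhenotypeSet,
    *,
    prefilter_f: int | None = None,
    aggregate: Callable[[np.ndarray], float] | None = None,
) -> float:
    """Best reversal-pair |delta| between two pooled class groups, in [0, 1].

    Samples are restricted to the two groups; group A is the positive stratum
    (the value is symmetric in the groups).  ``aggregate`` maps the
    descending-sorted |delta| values of all ordered pairs to the score;
    the default takes the single best pair.
    """
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    sub = dataset.subset(dataset.class_members(group_a | group_b))
    pos = [s for s in sub.sample_ids if sub.labels[s] in group_a]
    neg = [s for s in sub.sample_ids if sub.labels[s] in group_b]
    if not pos or not neg:
        raise ValueError("both groups need at least one sample")
    cols = {s: k for k, s in enumerate(sub.sample_ids)}
    pos_idx = np.array([cols[s] for s in pos])
    neg_idx = np.array([cols[s] for s in neg])
    feats = prefilter_features(sub, prefilter_f)
    deltas = np.abs(_delta_values(sub, pos_idx, neg_idx, feats))
    deltas[::-1].sort()
    if aggregate is None:
        return float(deltas[0])
    return float(aggregate(deltas))


def build_hierarchy(
    dataset: ExpressionDataset,
    *,
    prefilter_f: int | None = None,
    aggregate: Callable[[np.ndarray], float] | None = None,
) -> DiagnosticHierarchy:
    """Iteratively merge the two least-separable class groups into a binary tree.

    Ties in separability break on smaller combined sample count, then on the
    lexicographically smallest sorted class-name tuple of the union, so the
    construction is fully deterministic.
    """
    classes = sorted(dataset.classes)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to build a hierarchy")
    counts = dataset.labels.value_counts()
    small = [c for c in classes if counts.get(c, 0) < 2]
    if small:
        raise ValueError(f"classes with < 2 samples (separability degenerate): {small}")

    # Each live group is a frozenset of classes; `tree` maps a group to its
    # (left, right) child groups once merged.
    groups: list[PhenotypeSet] = [frozenset({c}) for c in classes]
    tree: dict[PhenotypeSet, tuple[PhenotypeSet, PhenotypeSet]] = {}
    n_samples = {g: len(dataset.class_members(g)) for g in groups}

    sep: dict[frozenset, float] = {}
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            key = frozenset({groups[a], groups[b]})
            sep[key] = group_separability(
                dataset, groups[a], groups[b], prefilter_f=prefilter_f, aggregate=aggregate
            )

    while len(groups) > 1:
        best = min(
            (
                (sep[frozenset({ga, gb})], n_samples[ga] + n_samples[gb], tuple(sorted(ga | gb)), ga, gb)
                for i, ga in enumerate(groups)
                for gb in groups[i + 1 :]
            ),
            key=lambda t: t[:3],
        )
        _, _, _, ga, gb = best
        left, right = sorted((ga, gb), key=lambda g: tuple(sorted(g)))
        merged = ga | gb
        tree[merged] = (left, right)
        groups = [g for g in groups if g not in (ga, gb)] + [merged]
        n_samples[merged] = n_samples[ga] + n_samples[gb]
        for g in groups[:-1]:
            sep[frozenset({g, merged})] = group_separability(
                dataset, g, merged, prefilter_f=prefilter_f, aggregate=aggregate
            )

    # Breadth-first numbering from the root.
    root_group = groups[0]
    nodes: dict[int, HierarchyNode] = {}
    queue: list[tuple[PhenotypeSet, int | None]] = [(root_group, None)]
    next_id = 1
    order: list[tuple[int, PhenotypeSet]] = []
    while queue:
        group, parent = queue.pop(0)
        nid = next_id
        next_id += 1
        nodes[nid] = HierarchyNode(nid, group, parent)
        order.append((nid, group))
        if group in tree:
            left, right = tree[group]
            queue.append((left, nid))
            queue.append((right, nid))
    # Second pass: connect children now that ids are assigned.
    by_parent: dict[int, list[int]] = {}
    for nid, node in nodes.items():
        if node.parent is not None:
            by_parent.setdefault(node.parent, []).append(nid)
    for pid, kids in by_parent.items():
        nodes[pid].children = tuple(sorted(kids))
    return DiagnosticHierarchy(nodes, frozenset(classes))
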
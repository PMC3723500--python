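"""Learning of node marker panels f_t and single-pair edge classifiers g_t,s.

A node classifier f_t is a voting rule over a small, feature-disjoint set of
oriented gene pairs P_t: f_t(x) = 1 iff at least k_t of the comparisons
"gene_i higher than gene_j" hold in x.  Its positive training data are ALL
samples of the node's phenotype set L_t and its negative data all remaining
samples — a one-vs-rest test, not a sibling-vs-sibling test.  The threshold
k_t is the largest value that keeps training sensitivity at the configured
target (default 1.0): each vote the positives can spare is converted into
specificity.

An edge classifier g_t,s is a single oriented pair separating the two child
class-groups of an internal node, trained only on samples under that node;
it is used solely to break ties among candidate phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .config import RunConfig
from .dataset import ExpressionDataset, GenePair, PhenotypeSet, validate_dataset
from .hierarchy import DiagnosticHierarchy, HierarchyNode, build_hierarchy
from .pairs import score_all_pairs

__all__ = [
    "NodePanel",
    "EdgeClassifier",
    "MarkerPanel",
    "InseparableNodeError",
    "learn_node_panel",
    "learn_edge_classifier",
    "learn_marker_panel",
]


class InseparableNodeError(ValueError):
    """No gene pair with positive delta exists for a node's one-vs-rest split."""


@dataclass
class NodePanel:
    node_id: int
    pairs: tuple[GenePair, ...]
    threshold_k: int
    training_sensitivity: float = float("nan")
    training_specificity: float = float("nan")

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"node {self.node_id}: panel needs at least one pair")
        if not 1 <= self.threshold_k <= len(self.pairs):
            raise ValueError(
                f"node {self.node_id}: k={self.threshold_k} outside 1..{len(self.pairs)}"
            )
        feats = [g for p in self.pairs for g in p]
        if len(feats) != len(set(feats)):
            raise ValueError(f"node {self.node_id}: features reused within the panel")


@dataclass
class EdgeClassifier:
    parent_id: int
    pair: GenePair
    child_true: int
    child_false: int


class MarkerPanel:
    """A fitted hierarchy plus its node panels and edge classifiers."""

    def __init__(
        self,
        hierarchy: DiagnosticHierarchy,
        node_panels: dict[int, NodePanel],
        edge_classifiers: dict[int, EdgeClassifier],
        symbols: dict[str, str] | None = None,
    ) -> None:
        self.hierarchy = hierarchy
        self.node_panels = dict(sorted(node_panels.items()))
        self.edge_classifiers = dict(sorted(edge_classifiers.items()))
        self.symbols = dict(symbols) if symbols else {}
        c = len(hierarchy.class_universe)
        if set(node_panels) != {n.node_id for n in hierarchy.nodes.values() if n.parent is not None}:
            raise ValueError(f"expected node panels at all {2 * c - 2} non-root nodes")
        if set(edge_classifiers) != {n.node_id for n in hierarchy.internal_nodes}:
            raise ValueError(f"expected edge classifiers at all {c - 1} internal nodes")
        for pid, edge in edge_classifiers.items():
            kids = set(hierarchy.nodes[pid].children)
            if {edge.child_true, edge.child_false} != kids:
                raise ValueError(f"edge at node {pid} routes outside its children")

    # -- bookkeeping -----------------------------------------------------------

    @property
    def features(self) -> list[str]:
        """All distinct feature ids used by node panels and edges, sorted."""
        feats = {g for p in self.node_panels.values() for pair in p.pairs for g in pair}
        feats |= {g for e in self.edge_classifiers.values() for g in e.pair}
        return sorted(feats)

    @property
    def n_pair_entries(self) -> int:
        """Total gene-pair entries across node and edge panels."""
        return sum(len(p.pairs) for p in self.node_panels.values()) + len(self.edge_classifiers)

    def gene_symbols(self) -> list[str]:
        """Distinct gene symbols (features fall back to their own id), sorted."""
        return sorted({self.symbols.get(f, f) for f in self.features})

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "hierarchy": self.hierarchy.to_dict(),
            "node_panels": [
                {
                    "node": p.node_id,
                    "classes": sorted(self.hierarchy.nodes[p.node_id].classes),
                    "pairs": [[q.gene_i, q.gene_j] for q in p.pairs],
                    "k": p.threshold_k,
                    "training_sensitivity": p.training_sensitivity,
                    "training_specificity": p.training_specificity,
                }
                for p in self.node_panels.values()
            ],
            "edges": [
                {
                    "parent": e.parent_id,
                    "pair": [e.pair.gene_i, e.pair.gene_j],
                    "child_true": e.child_true,
                    "child_false": e.child_false,
                }
                for e in self.edge_classifiers.values()
            ],
            "symbols": dict(sorted(self.symbols.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        hierarchy = DiagnosticHierarchy.from_dict(d["hierarchy"])
        node_panels = {
            e["node"]: NodePanel(
                e["node"],
                tuple(GenePair(i, j) for i, j in e["pairs"]),
                e["k"],
                e.get("training_sensitivity", float("nan")),
                e.get("training_specificity", float("nan")),
            )
            for e in d["node_panels"]
        }
        edges = {
            e["parent"]: EdgeClassifier(
                e["parent"], GenePair(*e["pair"]), e["child_true"], e["child_false"]
            )
            for e in d["edges"]
        }
        return cls(hierarchy, node_panels, edges, d.get("symbols"))


def _sens_spec_curve(z_pos: np.ndarray, z_neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and specificity for every threshold k = 1..n_pairs.

    ``z_pos``/``z_neg`` are (n_pairs, n_samples) Boolean vote matrices.
    """
    m = z_pos.shape[0]
    ks = np.arange(1, m + 1)
    votes_pos = z_pos.sum(axis=0)
    votes_neg = z_neg.sum(axis=0)
    sens = (votes_pos[None, :] >= ks[:, None]).mean(axis=1)
    spec = (votes_neg[None, :] < ks[:, None]).mean(axis=1)
    return sens, spec


def _pick_k(votes_pos: np.ndarray, m: int, target: Fraction) -> tuple[int, Fraction]:
    """Largest k whose training sensitivity meets the (possibly relaxed) target.

    Counts are compared in exact rational arithmetic.  If no k reaches the
    target, the target falls back to the maximum attainable sensitivity
    (reached at k=1).
    """
    n_pos = len(votes_pos)
    sens_of = lambda k: Fraction(int((votes_pos >= k).sum()), n_pos)
    eff_target = target if sens_of(1) >= target else sens_of(1)
    best = 1
    for k in range(1, m + 1):
        if sens_of(k) >= eff_target:
            best = k
    return best, sens_of(best)


def learn_node_panel(
    dataset: ExpressionDataset,
    node: HierarchyNode,
    config: RunConfig | None = None,
) -> NodePanel:
    """Greedy assembly of a feature-disjoint pair panel for one node.

    Pairs are taken in score order (descending delta, margin, lexicographic),
    skipping any pair that reuses a feature already in the panel.  Growth
    stops once the sensitivity target is reachable and a further pair fails
    to improve training specificity by ``min_specificity_gain``, or at
    ``max_pairs``.
    """
    config = config or RunConfig()
    if node.parent is None:
        raise ValueError("the root has no classifier; learn panels at non-root nodes")
    target = Fraction(str(config.sensitivity_target))

    scores = score_all_pairs(dataset, node.classes, prefilter_f=config.prefilter_f)
    if scores[0].delta <= 0:
        raise InseparableNodeError(
            f"node {node.node_id} ({sorted(node.classes)}): no pair with delta > 0"
        )

    pos_ids = set(dataset.class_members(node.classes))
    cols = {s: k for k, s in enumerate(dataset.sample_ids)}
    pos_idx = np.array([cols[s] for s in dataset.sample_ids if s in pos_ids])
    neg_idx = np.array([cols[s] for s in dataset.sample_ids if s not in pos_ids])
    x = dataset.values.to_numpy(dtype=float)
    feat = {f: k for k, f in enumerate(dataset.features)}

    min_gain = Fraction(str(config.min_specificity_gain))
    chosen: list[GenePair] = []
    used_feats: set[str] = set()
    z_rows: list[np.ndarray] = []
    state: tuple[int, Fraction, Fraction] | None = None  # (k, sens, spec) of `chosen`

    for s in scores:
        if s.delta <= 0 or len(chosen) >= config.max_pairs:
            break
        p = s.pair
        if p.gene_i in used_feats or p.gene_j in used_feats:
            continue
        z = x[feat[p.gene_i]] > x[feat[p.gene_j]]
        votes = np.vstack(z_rows + [z])
        votes_pos = votes[:, pos_idx].sum(axis=0)
        votes_neg = votes[:, neg_idx].sum(axis=0)
        k, sens = _pick_k(votes_pos, votes.shape[0], target)
        spec = Fraction(int((votes_neg < k).sum()), len(neg_idx))

        if state is not None:
            prev_sens, prev_spec = state[1], state[2]
            # Once the sensitivity target is reachable, a further pair must buy
            # a real specificity gain (without losing sensitivity) to be kept.
            if prev_sens >= target and not (spec - prev_spec >= min_gain and sens >= prev_sens):
                break
        chosen.append(p)
        used_feats.update(p)
        z_rows.append(z)
        state = (k, sens, spec)
        if sens == 1 and spec == 1:
            break

    assert state is not None
    k, sens, spec = state
    return NodePanel(node.node_id, tuple(chosen), k, float(sens), float(spec))


def learn_edge_classifier(
    dataset: ExpressionDataset,
    hierarchy: DiagnosticHierarchy,
    parent: HierarchyNode,
    config: RunConfig | None = None,
) -> EdgeClassifier:
    """Top-scoring single pair separating the two child groups of ``parent``.

    Training samples are restricted to the classes under the parent; the pair
    is oriented so that Z=1 routes to ``child_true``.  Which child is scored
    as positive is fixed by sorted class names, so swapping the children's
    declaration order returns the same, consistently oriented pair.
    """
    config = config or RunConfig()
    if parent.is_leaf:
        raise ValueError(f"node {parent.node_id} is a leaf; edges live at internal nodes")
    kids = sorted(hierarchy.children(parent.node_id), key=lambda n: tuple(sorted(n.classes)))
    pos_child, neg_child = kids
    sub = dataset.subset(dataset.class_members(parent.classes))
    scores = score_all_pairs(sub, pos_child.classes, prefilter_f=config.prefilter_f)
    if scores[0].delta <= 0:
        raise InseparableNodeError(
            f"edge under node {parent.node_id}: no pair with delta > 0 between children"
        )
    return EdgeClassifier(parent.node_id, scores[0].pair, pos_child.node_id, neg_child.node_id)


def learn_marker_panel(
    dataset: ExpressionDataset,
    config: RunConfig | None = None,
    hierarchy: DiagnosticHierarchy | None = None,
) -> MarkerPanel:
    """Full panel fit: hierarchy (unless supplied), all node panels, all edges.

    Deterministic given the dataset and configuration.
    """
    config = config or RunConfig()
    problems = validate_dataset(dataset)
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems))
    if len(dataset.classes) < 2:
        raise ValueError("need >= 2 classes")
    if hierarchy is None:
        hierarchy = build_hierarchy(dataset, prefilter_f=config.prefilter_f)
    node_panels = {
        n.node_id: learn_node_panel(dataset, n, config)
        for n in hierarchy.nodes.values()
        if n.parent is not None
    }
    edges = {
        n.node_id: learn_edge_classifier(dataset, hierarchy, n, config)
        for n in hierarchy.internal_nodes
    }
    return MarkerPanel(hierarchy, node_panels, edges, symbols=dataset.symbols)
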
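"""Coarse-to-fine screening and decision-tree disambiguation of a profile.

Screening executes node classifiers breadth-first; a node runs only if every
ancestor ran and was positive, so a negative response prunes its whole
subtree.  Candidate phenotypes L(x) are the leaves whose entire root-to-leaf
chain tested positive.  Zero candidates -> "Unclassified"; one -> that label;
several -> a full decision-tree descent from the root over the single-pair
edge classifiers picks the unique label.  The descent is not restricted to
candidate leaves, so with pathological inputs the final label can fall
outside L(x); the trace records the path for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .dataset import ExpressionDataset, ExpressionProfile, PhenotypeSet
from .learn import MarkerPanel, NodePanel

__all__ = [
    "UNCLASSIFIED",
    "PredictionResult",
    "apply_node_classifier",
    "screen",
    "disambiguate",
    "classify",
    "classify_dataset",
    "predictions_to_frame",
]

UNCLASSIFIED = "Unclassified"

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_EXECUTED = "not_executed"


@dataclass
class PredictionResult:
    sample_id: str
    candidates: PhenotypeSet
    final_label: str
    node_outcomes: Mapping[int, str]
    disambiguation_path: tuple[int, ...] = ()

    @property
    def unclassified(self) -> bool:
        return self.final_label == UNCLASSIFIED

    @property
    def disambiguated(self) -> bool:
        return len(self.disambiguation_path) > 0


def apply_node_classifier(profile: ExpressionProfile, panel: NodePanel) -> int:
    """1 iff at least ``threshold_k`` of the panel's pair comparisons hold."""
    votes = sum(int(profile[p.gene_i] > profile[p.gene_j]) for p in panel.pairs)
    return int(votes >= panel.threshold_k)


def screen(
    profile: ExpressionProfile, panel: MarkerPanel
) -> tuple[PhenotypeSet, dict[int, str]]:
    """Breadth-first adaptive screening; returns (candidates, node outcomes)."""
    h = panel.hierarchy
    outcomes: dict[int, str] = {
        n.node_id: NOT_EXECUTED for n in h.nodes.values() if n.parent is not None
    }
    queue = list(h.root.children)
    while queue:
        nid = queue.pop(0)
        result = apply_node_classifier(profile, panel.node_panels[nid])
        outcomes[nid] = POSITIVE if result else NEGATIVE
        if result:
            queue.extend(h.nodes[nid].children)
    candidates = frozenset(
        next(iter(leaf.classes))
        for leaf in h.leaves
        if outcomes[leaf.node_id] == POSITIVE
        and all(outcomes.get(a, POSITIVE) == POSITIVE for a in h.ancestors(leaf.node_id))
    )
    return candidates, outcomes


def disambiguate(profile: ExpressionProfile, panel: MarkerPanel) -> str:
    """Full decision-tree descent from the root to a unique leaf label."""
    label, _ = _descend(profile, panel)
    return label


def _descend(profile: ExpressionProfile, panel: MarkerPanel) -> tuple[str, tuple[int, ...]]:
    h = panel.hierarchy
    nid = h.root.node_id
    path = [nid]
    while not h.nodes[nid].is_leaf:
        edge = panel.edge_classifiers[nid]
        z = int(profile[edge.pair.gene_i] > profile[edge.pair.gene_j])
        nid = edge.child_true if z else edge.child_false
        path.append(nid)
    (label,) = h.nodes[nid].classes
    return label, tuple(path)


def classify(profile: ExpressionProfile, panel: MarkerPanel) -> PredictionResult:
    """Screen, then label: Unclassified / unique candidate / disambiguated."""
    candidates, outcomes = screen(profile, panel)
    if len(candidates) == 0:
        return PredictionResult(profile.sample_id, candidates, UNCLASSIFIED, outcomes)
    if len(candidates) == 1:
        (label,) = candidates
        return PredictionResult(profile.sample_id, candidates, label, outcomes)
    label, path = _descend(profile, panel)
    return PredictionResult(profile.sample_id, candidates, label, outcomes, path)


def classify_dataset(
    dataset: ExpressionDataset, panel: MarkerPanel
) -> list[PredictionResult]:
    """Classify every sample of a dataset (features restricted to the panel's)."""
    missing = [f for f in panel.features if f not in set(dataset.features)]
    if missing:
        raise KeyError(f"dataset lacks panel features: {missing}")
    sub = dataset.values.loc[panel.features]
    results = []
    for s in sub.columns:
        profile = ExpressionProfile(s, sub[s].to_dict())
        results.append(classify(profile, panel))
    return results


def predictions_to_frame(results: Iterable[PredictionResult]) -> pd.DataFrame:
    """Tabular prediction output (one row per sample)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "final_label": r.final_label,
            "n_candidates": len(r.candidates),
            "candidates": ";".join(sorted(r.candidates)),
            "disambiguated": r.disambiguated,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["sample_id", "final_label", "n_candidates", "candidates", "disambiguated"])
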
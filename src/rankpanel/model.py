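"""Model/Results front-end over the library.

`HierarchicalPairClassifier` is built from an `ExpressionDataset` (or a raw
DataFrame + label mappings); `fit()` learns the diagnostic hierarchy, the
node marker panels and the edge classifiers, and returns a
`MarkerPanelResults` carrying the fitted `MarkerPanel`, per-node training
diagnostics, resubstitution performance and a printable `summary()`.
Prediction, validation designs and serialization hang off the results
object.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .dataset import ExpressionDataset, ExpressionProfile
from .hierarchy import DiagnosticHierarchy
from .learn import MarkerPanel, learn_marker_panel
from .predict import PredictionResult, classify, classify_dataset, predictions_to_frame
from .validate import ValidationReport, confusion_matrix, cross_validate

__all__ = ["HierarchicalPairClassifier", "MarkerPanelResults"]


class HierarchicalPairClassifier:
    """Hierarchical multi-class classifier over rank-reversal gene pairs.

    Parameters
    ----------
    dataset : ExpressionDataset
        Training data: feature x sample matrix with phenotype and study labels.
    config : RunConfig, optional
        Learning knobs (sensitivity target, panel size cap, pre-filter...).
    hierarchy : DiagnosticHierarchy, optional
        Fix the tree instead of re-deriving it agglomeratively.

    Examples
    --------
    >>> model = HierarchicalPairClassifier(dataset)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.predict(new_dataset)
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        config: RunConfig | None = None,
        hierarchy: DiagnosticHierarchy | None = None,
    ) -> None:
        self.dataset = dataset
        self.config = config or RunConfig()
        self.hierarchy = hierarchy

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        labels: Mapping[str, str],
        studies: Mapping[str, str] | None = None,
        config: RunConfig | None = None,
    ) -> "HierarchicalPairClassifier":
        """Build from a feature x sample DataFrame plus label mappings."""
        return cls(ExpressionDataset(values, labels, studies), config)

    def fit(self) -> "MarkerPanelResults":
        panel = learn_marker_panel(self.dataset, self.config, hierarchy=self.hierarchy)
        return MarkerPanelResults(self, panel)

    def cross_validate(self) -> ValidationReport:
        """Repeated stratified k-fold CV with full relearning per split."""
        return cross_validate(self.dataset, self.config)


class MarkerPanelResults:
    """Fitted marker panel with training diagnostics."""

    def __init__(self, model: HierarchicalPairClassifier, panel: MarkerPanel) -> None:
        self.model = model
        self.panel = panel
        self._resub: ValidationReport | None = None

    # -- accessors -------------------------------------------------------------

    @property
    def hierarchy(self) -> DiagnosticHierarchy:
        return self.panel.hierarchy

    @property
    def node_panels(self):
        return self.panel.node_panels

    @property
    def edge_classifiers(self):
        return self.panel.edge_classifiers

    # -- prediction ------------------------------------------------------------

    def predict(self, data: ExpressionDataset | Sequence[ExpressionProfile]) -> pd.DataFrame:
        """Classify new samples; returns the tabular prediction frame."""
        return predictions_to_frame(self.predict_results(data))

    def predict_results(
        self, data: ExpressionDataset | Sequence[ExpressionProfile]
    ) -> list[PredictionResult]:
        if isinstance(data, ExpressionDataset):
            return classify_dataset(data, self.panel)
        return [classify(p, self.panel) for p in data]

    # -- diagnostics -----------------------------------------------------------

    def resubstitution_report(self) -> ValidationReport:
        """Apparent (training-data) performance; optimistic by construction."""
        if self._resub is None:
            ds = self.model.dataset
            preds = classify_dataset(ds, self.panel)
            cm = confusion_matrix(ds.labels.to_dict(), preds, sorted(ds.classes))
            self._resub = ValidationReport.from_confusion(cm)
        return self._resub

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        ds = self.model.dataset
        resub = self.resubstitution_report()
        h = self.panel.hierarchy
        lines = [
            "Hierarchical rank-pair marker panel",
            "=" * 74,
            f"Classes: {len(h.class_universe)}   Samples: {ds.n_samples}   "
            f"Features: {ds.n_features}   Studies: {len(set(ds.studies.values))}",
            f"Nodes: {len(h.nodes)}   Node panels: {len(self.panel.node_panels)}   "
            f"Edge classifiers: {len(self.panel.edge_classifiers)}",
            f"Resubstitution macro accuracy: {resub.macro_accuracy:.3f}",
            "",
            "Hierarchy (newick): " + h.to_newick(),
            "",
            f"{'node':>4} {'classes':<28} {'pairs':>5} {'k':>3} {'sens':>6} {'spec':>6}",
            "-" * 74,
        ]
        for nid, p in self.panel.node_panels.items():
            classes = "+".join(sorted(h.nodes[nid].classes))
            lines.append(
                f"{nid:>4} {classes[:28]:<28} {len(p.pairs):>5} {p.threshold_k:>3} "
                f"{p.training_sensitivity:>6.3f} {p.training_specificity:>6.3f}"
            )
        lines += ["", f"{'edge at':>7}  {'pair':<28} {'Z=1 ->':<20} {'Z=0 ->':<20}", "-" * 74]
        for pid, e in self.panel.edge_classifiers.items():
            t = "+".join(sorted(h.nodes[e.child_true].classes))
            f = "+".join(sorted(h.nodes[e.child_false].classes))
            lines.append(
                f"{pid:>7}  {e.pair.gene_i + ' > ' + e.pair.gene_j:<28} {t[:20]:<20} {f[:20]:<20}"
            )
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        from .io import write_panel_json

        write_panel_json(self.panel, path)
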
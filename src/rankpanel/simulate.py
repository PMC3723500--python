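"""Synthetic multi-class, multi-study expression data with planted reversals.

The generator emulates the only structure a rank-pair classifier can see:
within-profile orderings, class-conditional reversals of specific gene pairs,
and study-level (batch) perturbations of those orderings.  Values live on a
log-intensity-like scale: every feature is baseline + Gaussian noise, and a
planted pair (i, j) is shifted symmetrically apart by +-d/2 in the positive
classes and mirrored in the rest, where

    d = sqrt(2) * noise_sd * Phi^-1((1 + delta_target) / 2)

so that P(x_i > x_j | positive) - P(x_i > x_j | negative) = delta_target
under the Normal difference distribution (x_i - x_j ~ N(+-d, 2 noise_sd^2)).
Batch structure comes in two forms: additive per-(study, feature) offsets
~ N(0, batch_shift_sd), and — the hard confound — outright inversion of a
planted pair's orientation within single studies at rate
``batch_reversal_rate``.

The generator makes no attempt to imitate probe-level intensity
distributions or detection-call statistics of real microarrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import ExpressionDataset, GenePair, PhenotypeSet
from .hierarchy import DiagnosticHierarchy, HierarchyNode
from .learn import MarkerPanel

__all__ = [
    "PlantedPair",
    "SyntheticSpec",
    "PlantedTruth",
    "generate_dataset",
    "recover_planted",
    "feature_names",
    "hierarchical_planting",
    "planted_hierarchy",
    "strong_signal_spec",
    "pure_noise_spec",
    "batch_confounded_spec",
]

# delta_target = 1 is admitted but realised as a near-deterministic shift:
# Phi^-1 is evaluated at (1 + min(delta, 1 - EPS)) / 2.
_DELTA_CAP = 1.0 - 1e-6


def feature_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedPair:
    pair: GenePair
    positive: PhenotypeSet
    delta_target: float

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_target <= 1.0:
            raise ValueError("delta_target must lie in (0, 1]")


@dataclass
class SyntheticSpec:
    classes: Sequence[str]
    n_per_class_per_study: int = 10
    studies: Sequence[str] = ("lab1",)
    n_features: int = 40
    planted: Sequence[PlantedPair] = ()
    baseline_mean: float = 8.0
    noise_sd: float = 1.0
    batch_shift_sd: float = 0.0
    batch_reversal_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class names must be unique")
        if self.n_features < 4:
            raise ValueError("n_features must be >= 4")
        if self.n_per_class_per_study < 1:
            raise ValueError("n_per_class_per_study must be >= 1")
        if self.noise_sd < 0 or self.batch_shift_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.batch_reversal_rate <= 1.0:
            raise ValueError("batch_reversal_rate must be in [0, 1]")
        feats = set(feature_names(self.n_features))
        for pp in self.planted:
            if pp.pair.gene_i not in feats or pp.pair.gene_j not in feats:
                raise ValueError(f"planted pair {pp.pair} references unknown features")
            unknown = set(pp.positive) - set(self.classes)
            if unknown:
                raise ValueError(f"planted pair {pp.pair}: unknown classes {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_per_class_per_study": self.n_per_class_per_study,
            "studies": list(self.studies),
            "n_features": self.n_features,
            "planted": [
                {
                    "pair": [pp.pair.gene_i, pp.pair.gene_j],
                    "positive": sorted(pp.positive),
                    "delta_target": pp.delta_target,
                }
                for pp in self.planted
            ],
            "baseline_mean": self.baseline_mean,
            "noise_sd": self.noise_sd,
            "batch_shift_sd": self.batch_shift_sd,
            "batch_reversal_rate": self.batch_reversal_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["planted"] = tuple(
            PlantedPair(GenePair(*e["pair"]), frozenset(e["positive"]), e["delta_target"])
            for e in d.get("planted", [])
        )
        return cls(**d)


def shift_for_delta(delta_target: float, noise_sd: float) -> float:
    """Mean separation d achieving the target delta at the given noise level."""
    if noise_sd == 0:
        return 1.0
    return float(np.sqrt(2.0) * noise_sd * norm.ppf((1.0 + min(delta_target, _DELTA_CAP)) / 2.0))


def expected_delta(shift: float, noise_sd: float) -> float:
    """Closed-form delta implied by a symmetric shift under Normal noise."""
    if noise_sd == 0:
        return 1.0 if shift > 0 else 0.0
    return float(2.0 * norm.cdf(shift / (np.sqrt(2.0) * noise_sd)) - 1.0)


def hierarchical_planting(
    classes: Sequence[str], delta_target: float = 1.0, first_feature: int = 1
) -> list[PlantedPair]:
    """One planted reversal pair per node of a balanced binary class hierarchy.

    Splitting the (sorted) class list recursively in half yields 2C-2
    non-root class sets; each gets its own disjoint feature pair whose
    orientation reverses between that set and all other classes.  Every
    one-vs-rest node test and every sibling-vs-sibling edge of a compatible
    hierarchy then has genuine signal — the planted analogue of phenotype
    groups sharing expression traits at every granularity.
    """
    sets: list[tuple[str, ...]] = []

    def split(group: tuple[str, ...]) -> None:
        if len(group) == 1:
            return
        mid = (len(group) + 1) // 2
        for child in (group[:mid], group[mid:]):
            sets.append(child)
            split(child)

    split(tuple(sorted(classes)))
    planted = []
    f = first_feature
    for s in sets:
        planted.append(
            PlantedPair(GenePair(f"g{f:04d}", f"g{f + 1:04d}"), frozenset(s), delta_target)
        )
        f += 2
    return planted


def planted_hierarchy(classes: Sequence[str]) -> DiagnosticHierarchy:
    """The balanced binary tree over ``classes`` that hierarchical_planting
    plants signal for, as an explicit DiagnosticHierarchy.

    Useful when the data are so cleanly separable that every split carries
    identical separability (the agglomerative builder then has no topology
    signal to recover and falls back to tie-breaks).
    """
    nodes: dict[int, HierarchyNode] = {}
    queue: list[tuple[tuple[str, ...], int | None]] = [(tuple(sorted(classes)), None)]
    next_id = 1
    pending: list[tuple[int, tuple[str, ...]]] = []
    while queue:
        group, parent = queue.pop(0)
        nid = next_id
        next_id += 1
        nodes[nid] = HierarchyNode(nid, frozenset(group), parent)
        if len(group) > 1:
            mid = (len(group) + 1) // 2
            queue.append((group[:mid], nid))
            queue.append((group[mid:], nid))
    for nid, node in nodes.items():
        kids = tuple(k for k, n in nodes.items() if n.parent == nid)
        nodes[nid].children = kids
    return DiagnosticHierarchy(nodes, frozenset(classes))


def strong_signal_spec(seed: int = 0, n_classes: int = 7, noise_sd: float = 1.0) -> SyntheticSpec:
    """Canonical strong-signal scenario: hierarchically planted perfect reversals.

    Seven classes across two studies, 12 samples per class (6 per study), a
    near-deterministic (delta 1.0) reversal pair for every node of a balanced
    class hierarchy, Gaussian noise on a log-like scale (default sd 1.0;
    ``noise_sd=0`` gives the fully deterministic variant where every planted
    reversal is exact), no batch structure.  Residual classification error
    comes only from finite-sample pair selection.
    """
    classes = [f"c{i}" for i in range(1, n_classes + 1)]
    planted = hierarchical_planting(classes, 1.0)
    return SyntheticSpec(
        classes=classes,
        n_per_class_per_study=6,
        studies=("lab1", "lab2"),
        n_features=max(4 * len(planted), 2 * len(planted) + 24),
        planted=planted,
        noise_sd=noise_sd,
        seed=seed,
    )


def pure_noise_spec(seed: int = 0, n_classes: int = 4, n_per_class: int = 12) -> SyntheticSpec:
    """No planted structure at all: class labels carry zero signal."""
    return SyntheticSpec(
        classes=[f"c{i}" for i in range(1, n_classes + 1)],
        n_per_class_per_study=n_per_class,
        studies=("lab1",),
        n_features=30,
        planted=(),
        noise_sd=1.0,
        seed=seed,
    )


def batch_confounded_spec(seed: int = 0) -> SyntheticSpec:
    """Multi-study scenario with batch shifts and study-level pair inversions.

    Four classes in five studies (10 samples per class per study),
    hierarchically planted reversals at delta 0.9, unit noise, additive
    per-(study, feature) offsets at sd 0.5 and a 25% chance that any planted
    pair is outright inverted within any single study — the confound that
    makes single-study signatures fragile across labs.
    """
    classes = ["c1", "c2", "c3", "c4"]
    return SyntheticSpec(
        classes=classes,
        n_per_class_per_study=10,
        studies=tuple(f"lab{i}" for i in range(1, 6)),
        n_features=24,
        planted=hierarchical_planting(classes, 0.9),
        noise_sd=1.0,
        batch_shift_sd=0.5,
        batch_reversal_rate=0.25,
        seed=seed,
    )


@dataclass
class PlantedTruth:
    """Ground truth emitted with a synthetic dataset.

    ``realized`` holds the empirical delta of every planted pair per study
    and overall — recomputable from the dataset alone; ``reversed_in`` lists
    the (pair, study) combinations whose orientation the batch confound
    inverted.
    """

    spec: SyntheticSpec
    realized: dict[GenePair, dict[str, float]] = field(default_factory=dict)
    reversed_in: list[tuple[GenePair, str]] = field(default_factory=list)


def _empirical_delta(dataset: ExpressionDataset, pp: PlantedPair, samples: list[str]) -> float:
    xi = dataset.values.loc[pp.pair.gene_i, samples].to_numpy(dtype=float)
    xj = dataset.values.loc[pp.pair.gene_j, samples].to_numpy(dtype=float)
    z = xi > xj
    is_pos = np.array([dataset.labels[s] in pp.positive for s in samples])
    if is_pos.all() or (~is_pos).all():
        return float("nan")
    return float(z[is_pos].mean() - z[~is_pos].mean())


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, PlantedTruth]:
    """Draw a dataset honoring the spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    feats = feature_names(spec.n_features)
    feat_idx = {f: k for k, f in enumerate(feats)}

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    studies: dict[str, str] = {}
    for study in spec.studies:
        for cls in spec.classes:
            for r in range(spec.n_per_class_per_study):
                sid = f"{study}.{cls}.{r + 1}"
                sample_ids.append(sid)
                labels[sid] = cls
                studies[sid] = study

    n = len(sample_ids)
    x = spec.baseline_mean + rng.normal(0.0, spec.noise_sd, size=(spec.n_features, n))

    # Planted class-conditional reversals.
    label_arr = np.array([labels[s] for s in sample_ids])
    for pp in spec.planted:
        d = shift_for_delta(pp.delta_target, spec.noise_sd)
        pos = np.isin(label_arr, sorted(pp.positive))
        i, j = feat_idx[pp.pair.gene_i], feat_idx[pp.pair.gene_j]
        x[i, pos] += d / 2.0
        x[j, pos] -= d / 2.0
        x[i, ~pos] -= d / 2.0
        x[j, ~pos] += d / 2.0

    # Additive per-(study, feature) batch offsets.
    study_arr = np.array([studies[s] for s in sample_ids])
    if spec.batch_shift_sd > 0:
        for study in spec.studies:
            offsets = rng.normal(0.0, spec.batch_shift_sd, size=spec.n_features)
            x[:, study_arr == study] += offsets[:, None]

    # Batch confound: invert a planted pair's orientation within single studies.
    reversed_in: list[tuple[GenePair, str]] = []
    for pp in spec.planted:
        for study in spec.studies:
            if rng.random() < spec.batch_reversal_rate:
                i, j = feat_idx[pp.pair.gene_i], feat_idx[pp.pair.gene_j]
                cols = study_arr == study
                tmp = x[i, cols].copy()
                x[i, cols] = x[j, cols]
                x[j, cols] = tmp
                reversed_in.append((pp.pair, study))

    values = pd.DataFrame(x, index=feats, columns=sample_ids)
    dataset = ExpressionDataset(values, labels, studies, classes=spec.classes)

    truth = PlantedTruth(spec, reversed_in=reversed_in)
    for pp in spec.planted:
        per_study = {
            study: _empirical_delta(dataset, pp, [s for s in sample_ids if studies[s] == study])
            for study in spec.studies
        }
        per_study["__all__"] = _empirical_delta(dataset, pp, sample_ids)
        truth.realized[pp.pair] = per_study
    return dataset, truth


@dataclass
class RecoveryReport:
    statuses: dict[GenePair, str] = field(default_factory=dict)  # found|equivalent|missed

    @property
    def fraction_recovered(self) -> float:
        """Found or Boolean-equivalent planted pairs, over all planted pairs."""
        if not self.statuses:
            return float("nan")
        hits = sum(1 for s in self.statuses.values() if s in ("found", "equivalent"))
        return hits / len(self.statuses)


def recover_planted(
    dataset: ExpressionDataset, truth: PlantedTruth, learned: MarkerPanel
) -> RecoveryReport:
    """Did each planted pair surface, in orientation, in its node's learned panel?

    "Equivalent" means a learned pair whose Boolean column over the dataset's
    samples is identical to the planted pair's — empirically indistinguishable
    on the training data.
    """
    report = RecoveryReport()
    x = dataset.values
    for pp in truth.spec.planted:
        node_panels = [
            p
            for p in learned.node_panels.values()
            if learned.hierarchy.nodes[p.node_id].classes == pp.positive
        ] or list(learned.node_panels.values())
        planted_z = (
            x.loc[pp.pair.gene_i].to_numpy() > x.loc[pp.pair.gene_j].to_numpy()
        )
        status = "missed"
        for panel in node_panels:
            if pp.pair in panel.pairs:
                status = "found"
                break
            for q in panel.pairs:
                z = x.loc[q.gene_i].to_numpy() > x.loc[q.gene_j].to_numpy()
                if np.array_equal(z, planted_z):
                    status = "equivalent"
                    break
            if status != "missed":
                break
        report.statuses[pp.pair] = status
    return report
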
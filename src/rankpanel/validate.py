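"""Evaluation designs: repeated stratified k-fold CV, hold-one-lab-in,
leave-one-lab-out, fixed-size subsampled training, confusion matrices and
accuracy signal-to-noise ratios.

Every design relearns the entire pipeline — optional detection filter,
hierarchy, node panels, edge classifiers — on each training split, and an
"Unclassified" outcome always counts as a misclassification.  Macro accuracy
is the unweighted mean of per-class accuracies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .dataset import ExpressionDataset
from .learn import MarkerPanel, learn_marker_panel
from .predict import UNCLASSIFIED, PredictionResult, classify_dataset

__all__ = [
    "ConfusionMatrix",
    "ValidationReport",
    "confusion_matrix",
    "stratified_folds",
    "cross_validate",
    "hold_one_lab_in",
    "leave_one_lab_out",
    "subsampled_validation",
    "SubsampleReport",
    "snr",
]


class ConfusionMatrix:
    """Counts with truth on rows; predicted classes plus an Unclassified column."""

    def __init__(self, classes: Sequence[str], counts: pd.DataFrame | None = None) -> None:
        self.classes = list(classes)
        cols = self.classes + [UNCLASSIFIED]
        if counts is None:
            counts = pd.DataFrame(0, index=self.classes, columns=cols, dtype=int)
        self.counts = counts.loc[self.classes, cols]

    def add(self, truth_label: str, predicted: str) -> None:
        col = predicted if predicted in self.counts.columns else UNCLASSIFIED
        self.counts.loc[truth_label, col] += 1

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("confusion matrices cover different class sets")
        return ConfusionMatrix(self.classes, self.counts + other.counts)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def percentages(self) -> pd.DataFrame:
        """Row-normalised view (rows sum to 100 within rounding)."""
        totals = self.row_totals.replace(0, np.nan)
        return 100.0 * self.counts.div(totals, axis=0)

    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for c in self.classes:
            total = int(self.row_totals[c])
            out[c] = float(self.counts.loc[c, c]) / total if total else float("nan")
        return out

    def macro_accuracy(self) -> float:
        accs = [a for a in self.per_class_accuracy().values() if not math.isnan(a)]
        return float(np.mean(accs)) if accs else float("nan")


def confusion_matrix(
    truth: Mapping[str, str], predictions: Iterable[PredictionResult],
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    preds = list(predictions)
    unknown = [r.sample_id for r in preds if r.sample_id not in truth]
    if unknown:
        raise KeyError(f"predictions for samples without truth labels: {unknown}")
    if classes is None:
        classes = sorted(set(truth[r.sample_id] for r in preds))
    cm = ConfusionMatrix(classes)
    for r in preds:
        cm.add(truth[r.sample_id], r.final_label)
    return cm


def snr(accuracies: Sequence[float]) -> float:
    """Mean over sample standard deviation (n-1); inf flags zero dispersion."""
    if len(accuracies) < 2:
        raise ValueError("snr needs at least 2 values")
    arr = np.asarray(accuracies, dtype=float)
    if np.ptp(arr) == 0.0:  # exactly constant: dispersion is 0 by definition
        return float("inf")
    return float(arr.mean() / arr.std(ddof=1))


@dataclass
class ValidationReport:
    confusion: ConfusionMatrix
    per_class_accuracy: dict[str, float]
    macro_accuracy: float
    run_accuracies: list[float] = field(default_factory=list)
    snr: float | None = None

    @classmethod
    def from_confusion(
        cls, cm: ConfusionMatrix, run_accuracies: Sequence[float] = ()
    ) -> "ValidationReport":
        runs = list(run_accuracies)
        return cls(
            confusion=cm,
            per_class_accuracy=cm.per_class_accuracy(),
            macro_accuracy=cm.macro_accuracy(),
            run_accuracies=runs,
            snr=snr(runs) if len(runs) >= 2 else None,
        )

    def to_dict(self) -> dict:
        return {
            "classes": self.confusion.classes,
            "counts": self.confusion.counts.to_dict(orient="split"),
            "per_class_accuracy": self.per_class_accuracy,
            "macro_accuracy": self.macro_accuracy,
            "run_accuracies": self.run_accuracies,
            "snr": None if self.snr is None else (self.snr if math.isfinite(self.snr) else "inf"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def to_csv(self, path: str | Path) -> None:
        out = self.confusion.counts.copy()
        out["per_class_accuracy"] = pd.Series(self.per_class_accuracy)
        out.to_csv(path)


def _assert_no_leakage(train_ids: Sequence[str], test_ids: Sequence[str]) -> None:
    overlap = set(train_ids) & set(test_ids)
    assert not overlap, f"train/test leakage: {sorted(overlap)[:5]}"


def _apply_detection_filter(
    train: ExpressionDataset,
    test: ExpressionDataset,
    detection_flags: pd.DataFrame | None,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Drop features undetected in every TRAINING sample from both splits."""
    if detection_flags is None:
        return train, test
    flags = detection_flags.loc[train.features, train.sample_ids]
    keep = [f for f in train.features if bool(flags.loc[f].any())]
    return train.subset_features(keep), test.subset_features(keep)


def stratified_folds(
    dataset: ExpressionDataset, folds: int, rng: np.random.Generator
) -> list[list[str]]:
    """Per-class shuffle, then round-robin assignment to folds."""
    assignment: list[list[str]] = [[] for _ in range(folds)]
    for cls in sorted(dataset.classes):
        members = dataset.class_members([cls])
        if len(members) < folds:
            raise ValueError(f"class {cls!r} has {len(members)} samples < {folds} folds")
        members = list(np.array(members)[rng.permutation(len(members))])
        for m, s in enumerate(members):
            assignment[m % folds].append(s)
    return assignment


def cross_validate(
    dataset: ExpressionDataset,
    config: RunConfig | None = None,
    detection_flags: pd.DataFrame | None = None,
) -> ValidationReport:
    """Repeated stratified k-fold CV with full pipeline relearning per split.

    The headline confusion matrix pools counts across all folds and repeats;
    per-repeat macro accuracies are retained for dispersion/SNR.
    """
    config = config or RunConfig()
    classes = sorted(dataset.classes)
    pooled = ConfusionMatrix(classes)
    run_accuracies: list[float] = []
    for rep in range(config.repeats):
        rng = np.random.default_rng([config.seed, rep])
        rep_cm = ConfusionMatrix(classes)
        for fold_ids in stratified_folds(dataset, config.folds, rng):
            train_ids = [s for s in dataset.sample_ids if s not in set(fold_ids)]
            _assert_no_leakage(train_ids, fold_ids)
            train = dataset.subset(train_ids)
            test = dataset.subset(fold_ids)
            train, test = _apply_detection_filter(train, test, detection_flags)
            panel = learn_marker_panel(train, config)
            for r in classify_dataset(test, panel):
                rep_cm.add(dataset.labels[r.sample_id], r.final_label)
        pooled = pooled + rep_cm
        run_accuracies.append(rep_cm.macro_accuracy())
    return ValidationReport.from_confusion(pooled, run_accuracies)


def _target_class_accuracy(
    predictions: Iterable[PredictionResult], target_class: str
) -> float:
    preds = list(predictions)
    return float(np.mean([r.final_label == target_class for r in preds]))


def _studies_of(dataset: ExpressionDataset, target_class: str) -> list[str]:
    studies = sorted(
        {dataset.studies[s] for s in dataset.class_members([target_class])}
    )
    if len(studies) < 2:
        raise ValueError(f"class {target_class!r} present in < 2 studies")
    return studies


def hold_one_lab_in(
    dataset: ExpressionDataset,
    target_class: str,
    config: RunConfig | None = None,
) -> list[tuple[str, str, float]]:
    """Train the target class from ONE study (plus all other-class data);
    test on the target class in every other study.

    Returns (train_study, test_study, accuracy) triples; the headline number
    is their plain average.
    """
    config = config or RunConfig()
    studies = _studies_of(dataset, target_class)
    target_ids = set(dataset.class_members([target_class]))
    results: list[tuple[str, str, float]] = []
    for train_study in studies:
        train_ids = [
            s
            for s in dataset.sample_ids
            if s not in target_ids or dataset.studies[s] == train_study
        ]
        panel = learn_marker_panel(dataset.subset(train_ids), config)
        for test_study in studies:
            if test_study == train_study:
                continue
            test_ids = [
                s for s in target_ids if dataset.studies[s] == test_study
            ]
            _assert_no_leakage(train_ids, test_ids)
            preds = classify_dataset(dataset.subset(test_ids), panel)
            results.append((train_study, test_study, _target_class_accuracy(preds, target_class)))
    return results


def leave_one_lab_out(
    dataset: ExpressionDataset,
    target_class: str,
    config: RunConfig | None = None,
) -> list[tuple[str, float]]:
    """Withhold the target class of one study; train on everything else."""
    config = config or RunConfig()
    studies = _studies_of(dataset, target_class)
    target_ids = set(dataset.class_members([target_class]))
    results: list[tuple[str, float]] = []
    for held_out in studies:
        test_ids = [s for s in target_ids if dataset.studies[s] == held_out]
        train_ids = [s for s in dataset.sample_ids if s not in set(test_ids)]
        _assert_no_leakage(train_ids, test_ids)
        panel = learn_marker_panel(dataset.subset(train_ids), config)
        preds = classify_dataset(dataset.subset(test_ids), panel)
        results.append((held_out, _target_class_accuracy(preds, target_class)))
    return results


@dataclass
class SubsampleReport:
    mode: str
    n: int
    per_repeat: list[float]
    per_study: dict[str, list[float]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_repeat, ddof=1)) if len(self.per_repeat) > 1 else 0.0


def subsampled_validation(
    dataset: ExpressionDataset,
    target_class: str,
    *,
    mode: str,
    n: int = 50,
    repeats: int = 10,
    source_study: str | None = None,
    held_out_study: str | None = None,
    config: RunConfig | None = None,
) -> SubsampleReport:
    """Fixed-size training draws for the target class.

    mode="single_study": draw ``n`` target-class training samples from
    ``source_study`` only; evaluate on the target class in every other study.
    mode="combined": hold out ``held_out_study``; draw ``n`` target-class
    samples pooled across the remaining studies; evaluate on the held-out
    study.  Either way all other-class samples train in full, the whole
    pipeline is relearned per repeat, and per-repeat accuracies are returned
    for dispersion comparison.
    """
    config = config or RunConfig()
    studies = _studies_of(dataset, target_class)
    target_ids = [s for s in dataset.sample_ids if dataset.labels[s] == target_class]
    other_ids = [s for s in dataset.sample_ids if dataset.labels[s] != target_class]

    if mode == "single_study":
        if source_study is None:
            raise ValueError("single_study mode needs source_study")
        pool = [s for s in target_ids if dataset.studies[s] == source_study]
        eval_studies = [s for s in studies if s != source_study]
    elif mode == "combined":
        if held_out_study is None:
            raise ValueError("combined mode needs held_out_study")
        pool = [s for s in target_ids if dataset.studies[s] != held_out_study]
        eval_studies = [held_out_study]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n > len(pool):
        raise ValueError(f"n={n} exceeds the {len(pool)} available target-class samples")

    per_repeat: list[float] = []
    per_study: dict[str, list[float]] = {s: [] for s in eval_studies}
    for rep in range(repeats):
        rng = np.random.default_rng([config.seed, rep, 7])
        draw = list(np.array(pool)[rng.permutation(len(pool))[:n]])
        train_ids = [s for s in dataset.sample_ids if s in set(draw) or s in set(other_ids)]
        panel = learn_marker_panel(dataset.subset(train_ids), config)
        accs = []
        for es in eval_studies:
            test_ids = [
                s for s in target_ids if dataset.studies[s] == es and s not in set(draw)
            ]
            _assert_no_leakage(train_ids, test_ids)
            preds = classify_dataset(dataset.subset(test_ids), panel)
            acc = _target_class_accuracy(preds, target_class)
            per_study[es].append(acc)
            accs.append(acc)
        per_repeat.append(float(np.mean(accs)))
    return SubsampleReport(mode, n, per_repeat, per_study)
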
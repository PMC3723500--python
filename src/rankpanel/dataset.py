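"""Core domain types: expression profiles, datasets, gene pairs, pair scores.

All downstream classification decisions depend only on the *within-profile
ordering* of expression values, so values may arrive on any monotone
per-profile scale (log2 intensities, ranks, normalised counts...).  The
classifier unit is the feature/probe, not the gene symbol: two probes of the
same gene are distinct features, and an optional feature -> symbol mapping is
carried as annotation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "ExpressionDataset",
    "PhenotypeSet",
    "GenePair",
    "PairScore",
    "validate_dataset",
]


# A phenotype set is a frozen set of class-name strings; a light alias keeps
# signatures readable without wrapping the stdlib type.
PhenotypeSet = frozenset


@dataclass(frozen=True, order=True)
class GenePair:
    """Ordered gene pair: ``gene_i`` is hypothesised higher in the positive set."""

    gene_i: str
    gene_j: str

    def __post_init__(self) -> None:
        if self.gene_i == self.gene_j:
            raise ValueError(f"gene pair must use two distinct features, got {self.gene_i!r} twice")

    @property
    def reversed(self) -> "GenePair":
        return GenePair(self.gene_j, self.gene_i)

    def __iter__(self):
        return iter((self.gene_i, self.gene_j))


@dataclass(frozen=True)
class PairScore:
    """Score of an oriented pair against a positive phenotype set.

    ``delta`` is the empirical P(Z=1 | positive) - P(Z=1 | negative), in
    [-1, 1].  ``margin`` is the secondary tie-break statistic: the mean over
    scored samples of |rank(gene_i) - rank(gene_j)| on within-profile ranks.
    """

    pair: GenePair
    delta: float
    margin: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.delta <= 1.0 + 1e-12:
            raise ValueError(f"delta out of [-1, 1]: {self.delta}")
        if self.margin < 0:
            raise ValueError(f"margin must be >= 0, got {self.margin}")

    @property
    def sort_key(self):
        # Descending delta, then descending margin, then lexicographic pair.
        return (-self.delta, -self.margin, self.pair.gene_i, self.pair.gene_j)


@dataclass
class ExpressionProfile:
    """A single expression profile: sample id plus feature -> value mapping."""

    sample_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError(f"profile {self.sample_id!r} needs >= 2 features for pair comparisons")
        bad = [f for f, v in self.values.items() if not math.isfinite(float(v))]
        if bad:
            raise ValueError(f"profile {self.sample_id!r} has non-finite values for features {bad}")

    def __getitem__(self, feature: str) -> float:
        try:
            return float(self.values[feature])
        except KeyError:
            raise KeyError(f"feature {feature!r} absent from profile {self.sample_id!r}") from None


class ExpressionDataset:
    """Feature x sample expression matrix with per-sample phenotype and study labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Features on rows (index = feature ids), samples on columns.
    labels : mapping sample_id -> phenotype name
    studies : mapping sample_id -> study/batch id
    classes : optional iterable declaring the phenotype universe; defaults to
        the labels observed.
    symbols : optional feature id -> gene symbol annotation (e.g. two probes of
        one gene map to the same symbol).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        labels: Mapping[str, str],
        studies: Mapping[str, str] | None = None,
        classes: Iterable[str] | None = None,
        symbols: Mapping[str, str] | None = None,
    ) -> None:
        self.values = values
        self.labels = pd.Series(dict(labels), dtype=object)
        if studies is None:
            studies = {s: "study1" for s in values.columns}
        self.studies = pd.Series(dict(studies), dtype=object)
        if classes is None:
            classes = sorted(set(self.labels.values))
        self.classes = PhenotypeSet(classes)
        self.symbols = dict(symbols) if symbols else {}

    # -- convenience accessors -------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def profile(self, sample_id: str) -> ExpressionProfile:
        return ExpressionProfile(sample_id, self.values[sample_id].to_dict())

    def iter_profiles(self) -> Iterable[ExpressionProfile]:
        for s in self.sample_ids:
            yield self.profile(s)

    def class_members(self, classes: Iterable[str]) -> list[str]:
        """Sample ids whose label lies in ``classes`` (dataset column order)."""
        wanted = set(classes)
        return [s for s in self.sample_ids if self.labels.get(s) in wanted]

    def subset(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        """New dataset restricted to the given samples (feature order kept)."""
        ids = list(sample_ids)
        return ExpressionDataset(
            self.values[ids],
            {s: self.labels[s] for s in ids},
            {s: self.studies[s] for s in ids},
            classes=self.classes,
            symbols=self.symbols,
        )

    def subset_features(self, features: Sequence[str]) -> "ExpressionDataset":
        feats = list(features)
        return ExpressionDataset(
            self.values.loc[feats],
            self.labels.to_dict(),
            self.studies.to_dict(),
            classes=self.classes,
            symbols=self.symbols,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionDataset({self.n_features} features x {self.n_samples} samples, "
            f"{len(self.classes)} classes, {len(set(self.studies.values))} studies)"
        )


def validate_dataset(dataset: ExpressionDataset) -> list[str]:
    """Structural validation; returns a list of violation descriptions.

    An empty report means every downstream learning operation will accept the
    dataset without structural failure.  Side-effect free and idempotent.
    """
    report: list[str] = []
    values = dataset.values

    if values.shape[0] < 2:
        report.append(f"dataset has {values.shape[0]} features; >= 2 required for pair comparisons")

    dup_feats = values.index[values.index.duplicated()].unique().tolist()
    if dup_feats:
        report.append(f"duplicate feature ids: {dup_feats}")
    dup_samples = values.columns[values.columns.duplicated()].unique().tolist()
    if dup_samples:
        report.append(f"duplicate sample ids: {dup_samples}")

    arr = values.to_numpy(dtype=float, na_value=np.nan)
    bad = np.argwhere(~np.isfinite(arr))
    for r, c in bad[:50]:
        report.append(
            f"non-finite value for feature {values.index[r]!r} in sample {values.columns[c]!r}"
        )

    for s in values.columns:
        if s not in dataset.labels.index or pd.isna(dataset.labels.get(s)):
            report.append(f"sample {s!r} has no phenotype label")
        elif dataset.labels[s] not in dataset.classes:
            report.append(
                f"sample {s!r} labeled {dataset.labels[s]!r}, not in the declared phenotype set"
            )
        study = dataset.studies.get(s)
        if s not in dataset.studies.index or not isinstance(study, str) or study == "":
            report.append(f"sample {s!r} has a missing or empty study id")

    return report
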
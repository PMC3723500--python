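"""Readers/writers for expression TSV, metadata TSV and panel JSON, plus the
detection-flag feature filter.

The expression interchange format is a plain tab-separated matrix: first
column = feature id, header row = sample ids, numeric body.  Missing values
are rejected outright — a rank comparison against an absent value has no
defined outcome.  Preprocessing from raw arrays is upstream of this tool;
because classification depends only on within-profile orderings, any sane
per-profile monotone normalization feeds in cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .learn import MarkerPanel

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "load_dataset",
    "filter_undetected",
    "read_panel_json",
    "write_panel_json",
    "panel_json_text",
    "read_allowlist",
]

_META_COLUMNS = ("sample_id", "phenotype", "study_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Feature x sample matrix from TSV; malformed input raises with coordinates."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if not samples:
        raise ValueError(f"{path}: expected a header row of sample ids and a feature-id column")
    dup_s = sorted({s for s in samples if samples.count(s) > 1})
    if dup_s:
        raise ValueError(f"{path}: duplicated sample id(s) in header: {dup_s}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.name is None or df.columns.size == 0:
        raise ValueError(f"{path}: expected a header row of sample ids and a feature-id column")
    dup_f = df.index[df.index.duplicated()].unique().tolist()
    if dup_f:
        raise ValueError(f"{path}: duplicated feature id(s): {dup_f}")
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(out.isna().to_numpy() | ~np.isfinite(out.to_numpy(na_value=np.nan)))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell {df.iloc[r, c]!r} at "
            f"feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    out.index.name = df.index.name
    return out.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix = matrix.copy()
    if matrix.index.name is None:
        matrix.index.name = "feature_id"
    matrix.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata_tsv(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """sample_id/phenotype/study_id table -> (labels, studies) mappings."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated sample id(s): {dup}")
    labels = dict(zip(df["sample_id"], df["phenotype"]))
    studies = dict(zip(df["sample_id"], df["study_id"]))
    return labels, studies


def write_metadata_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "phenotype": [dataset.labels[s] for s in dataset.sample_ids],
            "study_id": [dataset.studies[s] for s in dataset.sample_ids],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_dataset(
    expression_path: str | Path,
    metadata_path: str | Path,
    allowlist: list[str] | None = None,
) -> tuple[ExpressionDataset, list[str]]:
    """Join matrix and metadata; returns (dataset, warnings).

    Samples present in the matrix but absent from metadata are an error;
    orphan metadata rows only produce a warning.  An optional feature
    allowlist (e.g. genes encoding extracellular products) restricts the
    feature universe before any learning.
    """
    matrix = read_expression_tsv(expression_path)
    labels, studies = read_metadata_tsv(metadata_path)
    unlabeled = [s for s in matrix.columns if s not in labels]
    if unlabeled:
        raise ValueError(f"samples in matrix but not in metadata: {unlabeled}")
    warnings = []
    orphans = [s for s in labels if s not in set(matrix.columns)]
    if orphans:
        warnings.append(f"metadata rows without expression data: {orphans}")
    if allowlist is not None:
        present = [f for f in matrix.index if f in set(allowlist)]
        absent = sorted(set(allowlist) - set(matrix.index))
        if absent:
            warnings.append(f"allowlist features absent from the matrix: {absent[:10]}")
        if len(present) < 2:
            raise ValueError("allowlist leaves fewer than 2 features")
        matrix = matrix.loc[present]
    keep = [s for s in matrix.columns]
    dataset = ExpressionDataset(
        matrix,
        {s: labels[s] for s in keep},
        {s: studies[s] for s in keep},
    )
    return dataset, warnings


def filter_undetected(
    matrix: pd.DataFrame,
    detection_flags: pd.DataFrame | None,
    train_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Drop features flagged undetected in ALL training samples.

    ``detection_flags`` is a Boolean feature x sample table (True = detected);
    the kept-feature decision is derived from ``train_samples`` only (default:
    every column of the flags) and then applied to the full matrix, so test
    columns never influence the filter.  ``None`` flags are the identity.
    """
    if detection_flags is None:
        return matrix
    if not detection_flags.index.equals(matrix.index):
        raise ValueError("detection flags and matrix cover different features")
    cols = train_samples if train_samples is not None else list(detection_flags.columns)
    missing = [s for s in cols if s not in detection_flags.columns]
    if missing:
        raise ValueError(f"training samples without detection flags: {missing}")
    keep = detection_flags[cols].any(axis=1)
    return matrix.loc[keep[keep].index]


def read_allowlist(path: str | Path) -> list[str]:
    """One feature id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def panel_json_text(panel: MarkerPanel) -> str:
    """Canonical JSON serialization (sorted keys, stable indentation)."""
    return json.dumps(panel.to_dict(), indent=2, sort_keys=True) + "\n"


def write_panel_json(panel: MarkerPanel, path: str | Path) -> None:
    Path(path).write_text(panel_json_text(panel))


def read_panel_json(path: str | Path) -> MarkerPanel:
    return MarkerPanel.from_dict(json.loads(Path(path).read_text()))
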
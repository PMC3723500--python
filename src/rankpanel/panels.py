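"""Packaged brain-tumor marker panel and study bookkeeping.

This module ships, as data, the published hierarchical marker panel for six
human brain cancers plus normal brain — ependymoma (EPN), glioblastoma
multiforme (GBM), medulloblastoma (MDL), meningioma (MNG), oligodendroglioma
(OLG), pilocytic astrocytoma (PA), "normal" — together with the multi-study
sample inventory it was trained on.  The hierarchy and node numbering are
transcribed verbatim (explicitly encoded, not re-derived from data).

Two gene symbols appear twice with distinct microarray probes: DDR1 (two
probes, mirrored at the glioma/medulloblastoma nodes) and CD59 (two pairs at
the pilocytic-astrocytoma node).  They are carried as distinct features
"DDR1#1"/"DDR1#2" and "CD59#1"/"CD59#2" annotated with a shared symbol — the
classifier unit is the probe, so the panel has 46 distinct features over 44
gene symbols and 39 gene-pair entries in total.
"""

from __future__ import annotations

import pandas as pd

from .dataset import ExpressionProfile, GenePair
from .hierarchy import DiagnosticHierarchy, HierarchyNode
from .learn import EdgeClassifier, MarkerPanel, NodePanel

__all__ = [
    "BRAIN_CLASSES",
    "load_printed_brain_panel",
    "brain_study_table",
    "brain_signature_patterns",
    "signature_profile",
]

BRAIN_CLASSES = ("EPN", "GBM", "MDL", "MNG", "OLG", "PA", "normal")

# Hierarchy: node id -> (classes, parent, children); root = 1, ids breadth-first.
_HIERARCHY = {
    1: (BRAIN_CLASSES, None, (2, 3)),
    2: (("EPN", "GBM", "MDL", "MNG", "OLG", "PA"), 1, (4, 5)),
    3: (("normal",), 1, ()),
    4: (("EPN", "GBM", "MDL", "OLG", "PA"), 2, (6, 7)),
    5: (("MNG",), 2, ()),
    6: (("EPN", "GBM", "OLG", "PA"), 4, (8, 9)),
    7: (("MDL",), 4, ()),
    8: (("EPN",), 6, ()),
    9: (("GBM", "OLG", "PA"), 6, (10, 11)),
    10: (("GBM", "OLG"), 9, (12, 13)),
    11: (("PA",), 9, ()),
    12: (("GBM",), 10, ()),
    13: (("OLG",), 10, ()),
}

# Node marker panel: node id -> (pairs (gene_i higher), threshold k).
_NODE_PANELS: dict[int, tuple[list[tuple[str, str]], int]] = {
    2: ([("PRPF40A", "PURA")], 1),
    3: ([("PURA", "PRPF40A")], 1),
    4: ([("NRCAM", "ISLR"), ("IDH2", "GMDS")], 1),
    5: ([("ISLR", "NRCAM")], 1),
    6: (
        [
            ("SALL1", "PAFAH1B3"),
            ("SRI", "NBEA"),
            ("DDR1#1", "TIA1"),
            ("DDR1#2", "MAB21L1"),
            ("ITPKB", "PDS5B"),
        ],
        2,
    ),
    7: (
        [
            ("PAFAH1B3", "SALL1"),
            ("NBEA", "SRI"),
            ("TIA1", "DDR1#1"),
            ("MAB21L1", "DDR1#2"),
            ("PDS5B", "ITPKB"),
        ],
        4,
    ),
    8: (
        [
            ("NUP62CL", "ZNF280A"),
            ("GALNS", "WAS"),
            ("CELSR1", "OR10H3"),
            ("TLE4", "OLIG2"),
        ],
        2,
    ),
    9: ([("ZNF280A", "NUP62CL")], 1),
    10: ([("DDX27", "KCNMA1"), ("COX7A2", "GNPTAB")], 1),
    11: (
        [
            ("KCNMA1", "DDX27"),
            ("GNPTAB", "NDUFS2"),
            ("APOD", "PPIA"),
            ("CD59#1", "SNRPB2"),
            ("SEMA3E", "ADAMTS3"),
            ("CD59#2", "HINT1"),
            ("BAMBI", "CIAPIN1"),
        ],
        3,
    ),
    12: ([("FLNA", "TNKS2"), ("ITGB3BP", "RB1CC1"), ("DDX27", "TRIM8")], 1),
    13: ([("LARP5", "ANXA1")], 1),
}

# Decision-tree (edge) classifiers: parent node -> (pair, child on Z=1, child on Z=0).
_EDGES: dict[int, tuple[tuple[str, str], int, int]] = {
    1: (("PRPF40A", "PURA"), 2, 3),
    2: (("NRCAM", "ISLR"), 4, 5),
    4: (("SRI", "NBEA"), 6, 7),
    6: (("NUP62CL", "OR10H3"), 8, 9),
    9: (("DDX27", "KCNMA1"), 10, 11),
    10: (("FLNA", "TNKS2"), 12, 13),
}

# Edge order used by the printed binary signature table (top to bottom).
_EDGE_ORDER = (1, 2, 4, 6, 9, 10)

# Phenotype-specific binary signatures over the ordered edges; None = unused.
_SIGNATURES: dict[str, tuple[int | None, ...]] = {
    "EPN": (1, 1, 1, 1, None, None),
    "GBM": (1, 1, 1, 0, 1, 1),
    "MDL": (1, 1, 0, None, None, None),
    "MNG": (1, 0, None, None, None, None),
    "OLG": (1, 1, 1, 0, 1, 0),
    "PA": (1, 1, 1, 0, 0, None),
    "normal": (0, None, None, None, None, None),
}

_SYMBOLS = {
    "DDR1#1": "DDR1",
    "DDR1#2": "DDR1",
    "CD59#1": "CD59",
    "CD59#2": "CD59",
}

# Multi-study sample inventory: (phenotype, accession, first author (year), n).
_STUDY_TABLE = [
    ("Ependymoma", "GSE16155", "Donson (2009)", 19),
    ("Ependymoma", "GSE21687", "Johnson (2010)", 83),
    ("Glioblastoma Multiforme", "GSE4412", "Freije (2004)", 59),
    ("Glioblastoma Multiforme", "GSE4271", "Phillips (2006)", 76),
    ("Glioblastoma Multiforme", "GSE8692", "Liu (2007)", 6),
    ("Glioblastoma Multiforme", "GSE9171", "Wiedemeyer (2008)", 13),
    ("Glioblastoma Multiforme", "GSE4290", "Sun (2006)", 77),
    ("Medulloblastoma", "GSE10327", "Kool (2008)", 61),
    ("Medulloblastoma", "GSE12992", "Fattet (2009)", 40),
    ("Meningioma", "GSE4780", "Scheck (2006)", 62),
    ("Meningioma", "GSE9438", "Claus (2008)", 31),
    ("Meningioma", "GSE16581", "Lee (2010)", 68),
    ("Oligodendroglioma", "GSE4412", "Freije (2004)", 11),
    ("Oligodendroglioma", "GSE4290", "Sun (2006)", 50),
    ("Pilocytic Astrocytoma", "GSE12907", "Wong (2005)", 21),
    ("Pilocytic Astrocytoma", "GSE5675", "Sharma (2007)", 41),
    ("Normal Brain", "GSE3526", "Roth (2006)", 146),
    ("Normal Brain", "GSE7307", "Roth (2007)", 57),
]

_PHENOTYPE_ABBREV = {
    "Ependymoma": "EPN",
    "Glioblastoma Multiforme": "GBM",
    "Medulloblastoma": "MDL",
    "Meningioma": "MNG",
    "Oligodendroglioma": "OLG",
    "Pilocytic Astrocytoma": "PA",
    "Normal Brain": "normal",
}


def load_printed_brain_panel() -> MarkerPanel:
    """The packaged brain marker panel as a structurally valid MarkerPanel."""
    nodes = {
        nid: HierarchyNode(nid, frozenset(classes), parent, tuple(children))
        for nid, (classes, parent, children) in _HIERARCHY.items()
    }
    hierarchy = DiagnosticHierarchy(nodes, frozenset(BRAIN_CLASSES))
    node_panels = {
        nid: NodePanel(nid, tuple(GenePair(i, j) for i, j in pairs), k)
        for nid, (pairs, k) in _NODE_PANELS.items()
    }
    edges = {
        pid: EdgeClassifier(pid, GenePair(i, j), t, f)
        for pid, ((i, j), t, f) in _EDGES.items()
    }
    return MarkerPanel(hierarchy, node_panels, edges, symbols=_SYMBOLS)


def brain_study_table() -> pd.DataFrame:
    """Per-(phenotype, accession) sample inventory behind the printed panel."""
    df = pd.DataFrame(_STUDY_TABLE, columns=["phenotype", "accession", "reference", "n_samples"])
    df["class"] = df["phenotype"].map(_PHENOTYPE_ABBREV)
    return df


def brain_signature_patterns() -> dict[str, tuple[int | None, ...]]:
    """Phenotype -> binary outcomes over the ordered edge pairs (None = unused)."""
    return dict(_SIGNATURES)


def edge_pair_order() -> list[GenePair]:
    """Edge gene pairs in the printed signature-table order (root first)."""
    return [GenePair(*_EDGES[pid][0]) for pid in _EDGE_ORDER]


def signature_profile(phenotype: str, low: float = 1.0, high: float = 2.0) -> ExpressionProfile:
    """A minimal expression profile realizing a phenotype's binary signature.

    Only the edge-classifier genes appearing in used rows of the signature get
    values; the decision-tree descent never reads the unused ones.
    """
    pattern = _SIGNATURES[phenotype]
    values: dict[str, float] = {}
    for (pid, outcome) in zip(_EDGE_ORDER, pattern):
        if outcome is None:
            continue
        (gi, gj), _, _ = _EDGES[pid]
        values[gi] = high if outcome else low
        values[gj] = low if outcome else high
    return ExpressionProfile(f"signature.{phenotype}", values)
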
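"""Boolean reversal features Z_ij and their class-conditional scoring.

The primitive is the top-scoring-pair (TSP) feature: for an oriented pair
(i, j), Z_ij(x) = 1 iff x_i > x_j strictly (ties resolve to 0).  Pairs are
scored by delta = P-hat(Z=1 | positive) - P-hat(Z=1 | negative), the classic
TSP score; the secondary tie-break statistic is the mean within-profile rank
gap, as in published TSP refinements.  Both are invariant to any strictly
increasing transform applied per profile.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .dataset import ExpressionDataset, ExpressionProfile, GenePair, PairScore, PhenotypeSet

__all__ = [
    "boolean_feature",
    "pair_score",
    "score_all_pairs",
    "all_ordered_pairs",
    "prefilter_features",
]


def boolean_feature(profile: ExpressionProfile, pair: GenePair) -> int:
    """Z_ij(x): 1 iff gene_i is expressed strictly higher than gene_j."""
    return int(profile[pair.gene_i] > profile[pair.gene_j])


def prefilter_features(dataset: ExpressionDataset, top_f: int | None) -> list[str]:
    """Top ``top_f`` features by across-sample variance of within-profile rank.

    All-pairs scoring is quadratic in the feature count; this engineering
    pre-filter keeps candidate generation tractable on genome-scale matrices.
    ``top_f=None`` keeps everything.
    """
    feats = dataset.features
    if top_f is None or len(feats) <= top_f:
        return feats
    ranks = rankdata(dataset.values.to_numpy(dtype=float), axis=0)
    var = ranks.var(axis=1)
    # Stable among ties: argsort on (-variance, position).
    order = np.lexsort((np.arange(len(feats)), -var))
    keep = sorted(order[:top_f])
    return [feats[i] for i in keep]


def all_ordered_pairs(features: Sequence[str]) -> list[GenePair]:
    """Every ordered pair (i, j), i != j, over the feature list."""
    return [GenePair(a, b) for a in features for b in features if a != b]


def _split_samples(dataset: ExpressionDataset, positive: PhenotypeSet):
    pos = dataset.class_members(positive)
    neg = [s for s in dataset.sample_ids if s not in set(pos)]
    if not pos:
        raise ValueError(f"no samples labeled with the positive phenotype set {sorted(positive)}")
    if not neg:
        raise ValueError("no negative samples: the positive set covers every sample")
    return pos, neg


def pair_score(dataset: ExpressionDataset, pair: GenePair, positive: PhenotypeSet) -> PairScore:
    """Score one oriented pair: empirical delta plus the mean rank-gap margin."""
    scores = score_all_pairs(dataset, positive, [pair], sort=False)
    return scores[0]


def score_all_pairs(
    dataset: ExpressionDataset,
    positive: PhenotypeSet,
    candidates: Sequence[GenePair] | None = None,
    *,
    prefilter_f: int | None = None,
    sort: bool = True,
) -> list[PairScore]:
    """Score candidate pairs against ``positive`` vs all remaining samples.

    Returns scores sorted by descending delta, then descending margin, then
    lexicographic (gene_i, gene_j) — a total, deterministic order.  With
    ``candidates=None`` all ordered pairs over the (optionally pre-filtered)
    feature universe are scored.
    """
    if candidates is None:
        candidates = all_ordered_pairs(prefilter_features(dataset, prefilter_f))
    if len(candidates) == 0:
        raise ValueError("no candidate pairs to score")

    pos, neg = _split_samples(dataset, positive)
    feat_index = {f: k for k, f in enumerate(dataset.features)}
    try:
        ii = np.array([feat_index[p.gene_i] for p in candidates])
        jj = np.array([feat_index[p.gene_j] for p in candidates])
    except KeyError as e:
        raise KeyError(f"candidate pair references unknown feature {e.args[0]!r}") from None

    x = dataset.values.to_numpy(dtype=float)
    cols = {s: k for k, s in enumerate(dataset.sample_ids)}
    pos_idx = np.array([cols[s] for s in pos])
    neg_idx = np.array([cols[s] for s in neg])
    used = np.concatenate([pos_idx, neg_idx])

    z = x[ii] > x[jj]  # (n_pairs, n_samples); strict comparison, ties -> 0
    delta = z[:, pos_idx].mean(axis=1) - z[:, neg_idx].mean(axis=1)

    # Margin over the scored (positive + negative) samples, on within-profile ranks.
    ranks = rankdata(x[:, used], axis=0)
    margin = np.abs(ranks[ii] - ranks[jj]).mean(axis=1)

    scores = [
        PairScore(p, float(d), float(m)) for p, d, m in zip(candidates, delta, margin)
    ]
    if sort:
        scores.sort(key=lambda s: s.sort_key)
    return scores
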
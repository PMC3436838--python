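"""Ranking imaging features by their fitted association weights.

The global ranking scores each feature by the l2 norm of its full
(SNP, visit) coefficient slab -- exactly the quantity the row-group penalty
drives to zero, so features surviving regularization rank highest.  The
per-SNP ranking scores features by the absolute temporal mean of their
coefficient for that SNP, demoting features whose sign flips across visits;
the signed mean is kept alongside for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CoefficientTensor, unfold_mode1

__all__ = [
    "MarkerRanking",
    "rank_markers_global",
    "top_markers_for_snp",
    "support_recovery_score",
]

GLOBAL_SCOPE = "GLOBAL"


@dataclass
class MarkerRanking:
    """Ordered (feature_id, score) entries; ties keep input feature order."""

    entries: list[tuple[str, float]]
    scope: str = GLOBAL_SCOPE
    signed_means: dict[str, float] | None = None  # per-SNP rankings only

    def feature_ids(self) -> list[str]:
        return [fid for fid, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, (fid, score) in enumerate(self.entries, start=1):
            row = {"rank": rank, "feature_id": fid, "score": score}
            if self.signed_means is not None:
                row["signed_mean"] = self.signed_means[fid]
            rows.append(row)
        return pd.DataFrame(rows)


def _stable_order(scores: np.ndarray) -> np.ndarray:
    # descending score, input order on ties
    return np.argsort(-scores, kind="stable")


def rank_markers_global(B: CoefficientTensor,
                        feature_ids: Sequence[str]) -> MarkerRanking:
    """Rank all features by the l2 norm of their unfolded coefficient row."""
    Bu = unfold_mode1(B)
    if len(feature_ids) != Bu.shape[0]:
        raise ValueError(
            f"got {len(feature_ids)} feature ids for {Bu.shape[0]} rows")
    scores = np.sqrt((Bu ** 2).sum(axis=1))
    order = _stable_order(scores)
    return MarkerRanking(
        entries=[(str(feature_ids[k]), float(scores[k])) for k in order],
        scope=GLOBAL_SCOPE,
    )


def top_markers_for_snp(B: CoefficientTensor, snp_ids: Sequence[str],
                        feature_ids: Sequence[str], snp_id: str,
                        k: int) -> MarkerRanking:
    """Top-k features for one SNP by |mean over visits| of the coefficient."""
    snp_ids = [str(s) for s in snp_ids]
    if snp_id not in snp_ids:
        raise KeyError(
            f"unknown snp_id {snp_id!r}; available: {', '.join(snp_ids)}")
    d = B.shape[0]
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    j = snp_ids.index(snp_id)
    means = B.values[:, j, :].mean(axis=1)
    scores = np.abs(means)
    order = _stable_order(scores)[:k]
    return MarkerRanking(
        entries=[(str(feature_ids[f]), float(scores[f])) for f in order],
        scope=snp_id,
        signed_means={str(feature_ids[f]): float(means[f]) for f in order},
    )


def support_recovery_score(B_fitted: CoefficientTensor,
                           true_support: Sequence[int], k: int,
                           feature_ids: Sequence[str] | None = None) -> float:
    """Fraction of the true active features found in the global top-k."""
    true_support = set(int(i) for i in true_support)
    if len(true_support) != k:
        raise ValueError(f"true support has {len(true_support)} features, expected k={k}")
    d = B_fitted.shape[0]
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    ids = list(feature_ids) if feature_ids is not None else [str(i) for i in range(d)]
    index_of = {fid: i for i, fid in enumerate(ids)}
    ranking = rank_markers_global(B_fitted, ids)
    top = {index_of[fid] for fid in ranking.feature_ids()[:k]}
    return len(top & true_support) / k
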
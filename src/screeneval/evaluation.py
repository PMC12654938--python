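"""Weighted score matrices, total weighted scores, and hospital rankings.

Given a weight vector W and the awarded-points matrix X, the weighted
matrix has cells ``W_j * X_ij`` and each hospital's total weighted score
(TWS) is its row sum.  Hospitals are ranked by descending score with
competition ranking (ties share the smallest applicable rank); tied rows
are listed in lexicographic hospital order so output is deterministic.

The "original" methodology of the screening programme — a plain sum of
awarded points — is the special case of unit weights (1 per indicator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .indicators import PerformanceMatrix
from .weighting import WeightVector, WeightingError

__all__ = ["RankingTable", "apply_weights", "total_scores", "rank", "evaluate"]


@dataclass(frozen=True)
class RankingTable:
    """Per-hospital total weighted scores and ranks under one methodology."""

    methodology: str
    frame: pd.DataFrame  # index hospital_id; columns score, rank

    def __post_init__(self) -> None:
        if list(self.frame.columns) != ["score", "rank"]:
            raise ValueError("ranking frame must have columns ['score', 'rank']")

    @property
    def hospital_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def scores(self) -> pd.Series:
        return self.frame["score"]

    @property
    def ranks(self) -> pd.Series:
        return self.frame["rank"]

    def top(self, k: int) -> set[str]:
        """Hospitals ranked in the best k positions (by rank value)."""
        return set(self.frame.nsmallest(k, "rank").index)

    def bottom(self, k: int) -> set[str]:
        return set(self.frame.nlargest(k, "rank").index)

    @classmethod
    def from_scores(cls, scores: pd.Series, methodology: str) -> "RankingTable":
        return rank(scores, methodology)


def apply_weights(matrix: PerformanceMatrix, weights: WeightVector) -> pd.DataFrame:
    """Weighted matrix with cells ``W_j * X_ij`` (hospitals x indicators)."""
    if weights.indicator_ids != matrix.indicator_ids:
        raise WeightingError(
            "weight vector indicator order does not match the matrix"
        )
    return matrix.to_frame() * weights.weights


def total_scores(weighted: pd.DataFrame) -> pd.Series:
    """Per-hospital total weighted score: the row sums of a weighted matrix."""
    totals = weighted.sum(axis=1)
    totals.name = "score"
    return totals


def rank(scores: pd.Series, methodology: str = "custom") -> RankingTable:
    """Competition-rank hospitals by descending score.

    Equal scores share the smallest applicable rank; rows are ordered by
    rank, ties broken lexicographically by hospital id.
    """
    s = pd.Series(np.asarray(scores, dtype=float), index=scores.index)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    ranks = s.rank(method="min", ascending=False).astype(int)
    frame = pd.DataFrame({"score": s, "rank": ranks})
    frame.index.name = "hospital_id"
    frame = frame.sort_values(["rank", frame.index.name], kind="mergesort")
    return RankingTable(methodology=methodology, frame=frame)


def evaluate(
    matrix: PerformanceMatrix,
    weights: WeightVector,
    methodology: str | None = None,
) -> RankingTable:
    """Weight, total, and rank in one step."""
    label = methodology or weights.provenance.value
    return rank(total_scores(apply_weights(matrix, weights)), label)
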
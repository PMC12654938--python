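"""Agreement metrics between evaluation methodologies.

Two metrics quantify how much two ranking methodologies agree:

* the **head-tail consistency rate** ``S = (x + y) / (0.4 n)``, where
  ``x`` and ``y`` count hospitals jointly placed in the top-k and
  bottom-k sets (``k = floor(0.2 n)``) by both methodologies.  Membership
  is a set property — order within the head or tail is ignored.  Because
  ``k`` is floored while the denominator ``0.4 n`` is not, the attainable
  maximum is ``2 k / (0.4 n)``, which is below 1 whenever ``0.2 n`` is
  not an integer (e.g. 0.9375 at n = 16);
* the **discrimination degree** ``D``, a scalar per methodology built
  from the squared gaps of affinely standardised scores
  ``V_i = n (1 - |V'_i - V'_1| / (V'_1 - V'_n))`` (best score -> n,
  worst -> 0).  Two algebraic readings of the printed formula are
  supported: the quotient ``(sum_i (V_{i+1} - V_i)^2 + 1) / (2n^2 - 2n - 1)``
  ("no_radical", the default) and the square root of that quotient
  ("radical").  Methodology pairs are compared by ``|D_a - D_b|``, which
  makes the six pairwise deltas mutually consistent as absolute
  differences of per-method scalars.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .evaluation import RankingTable

__all__ = [
    "ComparisonMetrics",
    "ComparisonError",
    "head_tail_consistency",
    "standardize_scores",
    "discrimination_degree",
    "compare_methodologies",
]

Reading = Literal["no_radical", "radical"]


class ComparisonError(ValueError):
    """Invalid input to a comparison operation."""


@dataclass(frozen=True)
class ComparisonMetrics:
    """Agreement between one pair of methodologies (symmetric in the pair)."""

    pair: tuple[str, str]
    head_tail_rate: float
    discrimination_delta: float


def head_tail_consistency(ranking_a: RankingTable, ranking_b: RankingTable) -> float:
    """Fraction of top-20% and bottom-20% hospitals jointly identified.

    ``k = floor(0.2 n)`` hospitals form each head and tail set;
    ``S = (|top_a ∩ top_b| + |bottom_a ∩ bottom_b|) / (0.4 n)``.
    """
    set_a = set(ranking_a.hospital_ids)
    set_b = set(ranking_b.hospital_ids)
    if set_a != set_b:
        raise ComparisonError("rankings cover different hospital sets")
    n = len(set_a)
    if n < 5:
        raise ComparisonError("head-tail consistency requires at least 5 hospitals")
    k = math.floor(0.2 * n)
    x = len(ranking_a.top(k) & ranking_b.top(k))
    y = len(ranking_a.bottom(k) & ranking_b.bottom(k))
    return (x + y) / (0.4 * n)


def standardize_scores(scores: Sequence[float]) -> np.ndarray:
    """Affinely map descending raw scores onto [0, n]: best -> n, worst -> 0.

    ``V_i = n * (1 - |V'_i - V'_1| / (V'_1 - V'_n))`` for raw scores
    ``V'_1 >= ... >= V'_n``.  Input must already be sorted descending.
    """
    v = np.asarray(scores, dtype=float)
    n = v.size
    if n < 2:
        raise ComparisonError("standardisation requires at least 2 scores")
    if (np.diff(v) > 0).any():
        raise ComparisonError("scores must be sorted in descending order")
    spread = v[0] - v[-1]
    if spread == 0:
        raise ComparisonError(
            "all scores are equal; standardisation (and D) is undefined"
        )
    return n * (1.0 - np.abs(v - v[0]) / spread)


def discrimination_degree(
    scores: Sequence[float],
    reading: Reading = "no_radical",
) -> float:
    """Scalar separation power of one methodology's score profile.

    Scores are sorted descending internally, standardised onto [0, n],
    and the squared consecutive gaps are pooled:
    ``D = (sum_{i<n} (V_{i+1} - V_i)^2 + 1) / (2 n^2 - 2 n - 1)``,
    optionally under a square root (``reading="radical"``).  D is
    invariant to positive affine transformations of the raw scores.
    """
    v = np.sort(np.asarray(scores, dtype=float))[::-1]
    V = standardize_scores(v)
    n = V.size
    quotient = (np.diff(V) ** 2).sum() + 1.0
    quotient /= 2.0 * n**2 - 2.0 * n - 1.0
    if reading == "radical":
        return float(np.sqrt(quotient))
    if reading == "no_radical":
        return float(quotient)
    raise ComparisonError(f"unknown discrimination-degree reading {reading!r}")


def compare_methodologies(
    rankings: Sequence[RankingTable],
    reading: Reading = "no_radical",
) -> list[ComparisonMetrics]:
    """All pairwise agreement metrics over a set of methodologies.

    For each unordered pair, reports the head-tail consistency rate and
    the absolute difference of the two per-method discrimination degrees.
    """
    if len(rankings) < 2:
        raise ComparisonError("need at least 2 methodologies to compare")
    D = {
        rt.methodology: discrimination_degree(rt.scores.to_numpy(), reading)
        for rt in rankings
    }
    out = []
    for a, b in itertools.combinations(rankings, 2):
        out.append(
            ComparisonMetrics(
                pair=(a.methodology, b.methodology),
                head_tail_rate=head_tail_consistency(a, b),
                discrimination_delta=abs(D[a.methodology] - D[b.methodology]),
            )
        )
    return out


def comparison_frame(metrics: Sequence[ComparisonMetrics]) -> pd.DataFrame:
    """Tabular view: method_a, method_b, head_tail_rate, discrimination_delta."""
    return pd.DataFrame(
        [
            {
                "method_a": m.pair[0],
                "method_b": m.pair[1],
                "head_tail_rate": m.head_tail_rate,
                "discrimination_delta": m.discrimination_delta,
            }
            for m in metrics
        ]
    )
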
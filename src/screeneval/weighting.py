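"""Subjective, entropy (objective), and combined indicator weighting.

Three weighting routes over an n x m performance matrix:

* **subjective** — each indicator's weight is its expert-assigned score
  divided by the total of all assigned scores, ``W_j = S_j / sum(S)``;
* **objective** — the entropy weight method (EWM): min-max normalise each
  column by attribute, shift by +0.001 to clear zeros, form column
  proportions ``P_ij``, compute information entropy
  ``E_j = -(1/ln n) * sum_i P_ij ln P_ij``, and weight by the entropy
  deficit ``W_j = (1 - E_j) / sum_k (1 - E_k)``.  Columns whose values
  vary more across hospitals carry lower entropy and hence more weight;
* **combined** — multiplicative synthesis with normalisation (MSN):
  per-indicator products of the input weight vectors, renormalised to
  sum 1, so an indicator must matter under *every* route to matter in
  the combination.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .indicators import Attribute, IndicatorDefinition, PerformanceMatrix

__all__ = [
    "Provenance",
    "WeightVector",
    "NormalizedMatrix",
    "EntropyResult",
    "WeightingError",
    "DegenerateDataError",
    "SHIFT",
    "subjective_weights",
    "normalize",
    "shift",
    "entropy_weights",
    "combine_msn",
    "weight_change",
]

#: additive shift applied after normalisation so logarithms stay finite
SHIFT = 0.001

_SUM_TOL = 1e-9


class WeightingError(ValueError):
    """Invalid input to a weighting operation."""


class DegenerateDataError(WeightingError):
    """The data carry no information for the requested weighting."""


class Provenance(str, enum.Enum):
    SUBJECTIVE = "subjective"
    OBJECTIVE = "objective"
    COMBINED = "combined"
    EQUAL = "equal"
    CUSTOM = "custom"


@dataclass(frozen=True)
class WeightVector:
    """m nonnegative indicator weights tagged with their provenance.

    Subjective, objective, combined and equal vectors must sum to 1; a
    ``custom`` vector (e.g. the unit weights of the plain-sum "original"
    methodology) is exempt from the sum constraint.
    """

    indicator_ids: tuple[str, ...]
    weights: np.ndarray
    provenance: Provenance = Provenance.CUSTOM

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.indicator_ids),):
            raise WeightingError("weights length does not match indicator_ids")
        if (w < 0).any():
            raise WeightingError("weights must be nonnegative")
        if self.provenance is not Provenance.CUSTOM and abs(w.sum() - 1.0) > _SUM_TOL:
            raise WeightingError(
                f"{self.provenance.value} weights must sum to 1, got {w.sum()!r}"
            )

    def __getitem__(self, indicator_id: str) -> float:
        return float(self.weights[self.indicator_ids.index(indicator_id)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.indicator_ids),
                         name=self.provenance.value)

    @classmethod
    def equal(cls, indicator_ids: Sequence[str]) -> "WeightVector":
        m = len(indicator_ids)
        return cls(tuple(indicator_ids), np.full(m, 1.0 / m), Provenance.EQUAL)

    @classmethod
    def unit(cls, indicator_ids: Sequence[str]) -> "WeightVector":
        """Weight 1 per indicator: the plain-sum 'original' methodology."""
        return cls(tuple(indicator_ids), np.ones(len(indicator_ids)),
                   Provenance.CUSTOM)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Min-max standardised matrix Y_ij (optionally shifted to Y'_ij)."""

    hospital_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]
    values: np.ndarray
    shifted: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        lo, hi = (SHIFT, 1.0 + SHIFT) if self.shifted else (0.0, 1.0)
        if (v < lo - 1e-12).any() or (v > hi + 1e-12).any():
            raise WeightingError(
                f"normalized values must lie in [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class EntropyResult:
    """Intermediate and final quantities of the entropy weight method."""

    proportions: np.ndarray     # P_ij, columns sum to 1
    entropies: np.ndarray       # E_j in [0, 1]
    weights: WeightVector       # provenance objective


def subjective_weights(scheme: Sequence[IndicatorDefinition]) -> WeightVector:
    """Expert-score weights ``W_j = S_j / sum(S_j)``."""
    if not scheme:
        raise WeightingError("empty scheme")
    scores = np.array([ind.assigned_score for ind in scheme], dtype=float)
    if (scores <= 0).any():
        raise WeightingError("assigned scores must be positive")
    return WeightVector(
        tuple(ind.id for ind in scheme), scores / scores.sum(),
        Provenance.SUBJECTIVE,
    )


def normalize(
    matrix: PerformanceMatrix,
    attributes: Mapping[str, Attribute],
) -> NormalizedMatrix:
    """Min-max standardise each column according to its attribute.

    Positive: ``(X - min) / (max - min)``; negative: ``(max - X) /
    (max - min)``; moderate: ``1 - |X - mean| / max|X - mean|``.  A
    constant column carries no ordering information; its cells are set to
    the midpoint 0.5 with a warning (its entropy weight will be zero
    regardless).
    """
    if matrix.n < 2:
        raise WeightingError("normalisation requires at least 2 hospitals")
    X = matrix.points
    Y = np.empty_like(X)
    for j, ind_id in enumerate(matrix.indicator_ids):
        try:
            attr = attributes[ind_id]
        except KeyError:
            raise WeightingError(f"no attribute given for indicator {ind_id!r}")
        col = X[:, j]
        if attr is Attribute.MODERATE:
            dev = np.abs(col - col.mean())
            span = dev.max()
        else:
            span = col.max() - col.min()
        if span == 0:
            warnings.warn(
                f"{ind_id}: constant column, normalised to midpoint 0.5",
                stacklevel=2,
            )
            Y[:, j] = 0.5
            continue
        if attr is Attribute.POSITIVE:
            Y[:, j] = (col - col.min()) / span
        elif attr is Attribute.NEGATIVE:
            Y[:, j] = (col.max() - col) / span
        else:
            Y[:, j] = 1.0 - dev / span
    return NormalizedMatrix(matrix.hospital_ids, matrix.indicator_ids, Y)


def shift(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Add the constant 0.001 to every cell so all values are positive."""
    if matrix.shifted:
        raise WeightingError("matrix is already shifted")
    return NormalizedMatrix(
        matrix.hospital_ids, matrix.indicator_ids,
        matrix.values + SHIFT, shifted=True,
    )


def entropy_weights(matrix: NormalizedMatrix) -> EntropyResult:
    """Objective weights from the entropy of each indicator column.

    Expects a shifted matrix (all cells strictly positive).  Guards the
    ``p ln p`` term at p = 0 for custom unshifted inputs, defining it as 0.
    """
    Y = matrix.values
    n, m = Y.shape
    if n < 2:
        raise WeightingError("entropy weighting requires at least 2 hospitals")
    if (Y < 0).any():
        raise WeightingError("entropy weighting requires nonnegative cells")
    col_sums = Y.sum(axis=0)
    if (col_sums == 0).any():
        raise DegenerateDataError("a column sums to zero; cannot form proportions")
    P = Y / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    E = -plogp.sum(axis=0) / np.log(n)
    deficit = 1.0 - E
    # entropy can exceed 1 by floating error on near-uniform columns
    deficit = np.clip(deficit, 0.0, None)
    total = deficit.sum()
    if total <= 0:
        raise DegenerateDataError(
            "all columns are uninformative (every entropy is 1); "
            "consider equal weights instead"
        )
    weights = WeightVector(matrix.indicator_ids, deficit / total,
                           Provenance.OBJECTIVE)
    return EntropyResult(proportions=P, entropies=E, weights=weights)


def combine_msn(weight_vectors: Sequence[WeightVector]) -> WeightVector:
    """Multiplicative synthesis with normalisation over L weighting routes.

    The combined weight of indicator j is the product of its weights under
    each route, renormalised so the combination sums to 1.  With a single
    input this is the identity (up to renormalisation).
    """
    if not weight_vectors:
        raise WeightingError("combine_msn requires at least one weight vector")
    ids = weight_vectors[0].indicator_ids
    for wv in weight_vectors[1:]:
        if wv.indicator_ids != ids:
            raise WeightingError(
                "weight vectors disagree on indicator identity/order"
            )
    prod = np.prod([wv.weights for wv in weight_vectors], axis=0)
    total = prod.sum()
    if total <= 0:
        raise DegenerateDataError(
            "every per-indicator weight product is zero; combination undefined"
        )
    return WeightVector(ids, prod / total, Provenance.COMBINED)


def weight_change(baseline: WeightVector, comparison: WeightVector) -> pd.DataFrame:
    """Signed per-indicator percentage change from ``baseline`` to ``comparison``.

    Returns a frame with columns ``baseline``, ``comparison``,
    ``pct_change`` and ``defined``; a zero baseline weight yields
    ``defined = False`` and a NaN change.
    """
    if baseline.indicator_ids != comparison.indicator_ids:
        raise WeightingError("weight vectors disagree on indicator identity/order")
    b = baseline.weights
    c = comparison.weights
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(b > 0, (c - b) / b * 100.0, np.nan)
    return pd.DataFrame(
        {
            "baseline": b,
            "comparison": c,
            "pct_change": pct,
            "defined": b > 0,
        },
        index=pd.Index(list(baseline.indicator_ids), name="indicator_id"),
    )
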
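"""Published reference values for the 2024 Sichuan sixteen-hospital panel.

The CNSSS quality-control evaluation of the sixteen Sichuan base
hospitals (coded A..P) is the canonical worked example for this package.
This module transcribes its published outputs — the subjective, objective
and combined weight vectors (four decimal places) and the four
score/ranking tables — so that downstream computations (multiplicative
weight combination, ranking, head-tail consistency) can be regression
tested without access to the underlying de-identified point matrix.

Values are transcriptions of published results, not computations; every
function here simply packages them into the library's domain types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import RankingTable
from .weighting import Provenance, WeightVector

__all__ = ["ReferenceTables", "reference_tables", "INDICATOR_IDS", "METHODOLOGIES"]

INDICATOR_IDS = ("X1", "X2", "X3", "X4", "X5", "X6", "X7", "X8", "X9", "X10", "X11")

METHODOLOGIES = ("original", "subjective", "objective", "combined")

#: expert-assigned maximum score per indicator (total 112)
ASSIGNED_SCORES = {
    "X1": 35, "X2": 12, "X3": 6, "X4": 6, "X5": 3, "X6": 3,
    "X7": 3, "X8": 8, "X9": 12, "X10": 12, "X11": 12,
}

_SUBJECTIVE = {
    "X1": 0.3125, "X2": 0.1071, "X3": 0.0536, "X4": 0.0536, "X5": 0.0268,
    "X6": 0.0268, "X7": 0.0268, "X8": 0.0714, "X9": 0.1071, "X10": 0.1071,
    "X11": 0.1071,
}

_OBJECTIVE = {
    "X1": 0.0236, "X2": 0.1527, "X3": 0.1176, "X4": 0.0518, "X5": 0.0878,
    "X6": 0.1108, "X7": 0.0936, "X8": 0.1485, "X9": 0.1594, "X10": 0.0286,
    "X11": 0.0256,
}

_COMBINED = {
    "X1": 0.0995, "X2": 0.2207, "X3": 0.0850, "X4": 0.0375, "X5": 0.0318,
    "X6": 0.0401, "X7": 0.0339, "X8": 0.1430, "X9": 0.2303, "X10": 0.0413,
    "X11": 0.0370,
}

# (hospital, total score, rank) per methodology, in published row order
_RANKINGS: dict[str, list[tuple[str, float, int]]] = {
    "original": [
        ("A", 99.0000, 1), ("B", 96.2500, 2), ("C", 91.0000, 3),
        ("D", 90.0000, 4), ("E", 87.0000, 5), ("F", 86.5000, 6),
        ("G", 85.7500, 7), ("H", 84.0000, 8), ("I", 79.7500, 9),
        ("J", 76.0000, 10), ("K", 67.4000, 11), ("L", 66.8000, 12),
        ("M", 63.2000, 13), ("N", 62.8000, 14), ("O", 56.8000, 15),
        ("P", 56.0000, 16),
    ],
    "subjective": [
        ("A", 16.3824, 1), ("B", 15.9006, 2), ("G", 15.4345, 3),
        ("F", 15.3810, 4), ("C", 15.2580, 5), ("E", 15.2578, 6),
        ("I", 15.1131, 7), ("H", 15.0704, 8), ("D", 14.6593, 9),
        ("L", 13.2996, 10), ("K", 13.2569, 11), ("M", 13.2085, 12),
        ("N", 12.9249, 13), ("O", 12.6569, 14), ("P", 12.4106, 15),
        ("J", 12.3149, 16),
    ],
    "objective": [
        ("D", 7.6998, 1), ("B", 7.6021, 2), ("A", 7.3770, 3),
        ("C", 6.7346, 4), ("H", 6.5609, 5), ("F", 6.4842, 6),
        ("E", 6.3922, 7), ("G", 6.3314, 8), ("I", 6.2837, 9),
        ("J", 6.2666, 10), ("K", 2.7206, 11), ("L", 2.5531, 12),
        ("N", 2.4553, 13), ("P", 2.1406, 14), ("M", 2.1389, 15),
        ("O", 2.0551, 16),
    ],
    "combined": [
        ("A", 11.4458, 1), ("B", 11.2582, 2), ("D", 11.0085, 3),
        ("I", 10.3172, 4), ("E", 9.9964, 5), ("G", 9.9930, 6),
        ("H", 9.9650, 7), ("F", 9.8955, 8), ("C", 9.8600, 9),
        ("J", 9.1810, 10), ("K", 4.9734, 11), ("L", 4.8145, 12),
        ("N", 4.7988, 13), ("M", 4.6854, 14), ("O", 4.5789, 15),
        ("P", 4.5001, 16),
    ],
}


def _weight_vector(values: dict[str, float], provenance: Provenance) -> WeightVector:
    w = np.array([values[i] for i in INDICATOR_IDS], dtype=float)
    # printed 4-decimal weights do not sum to exactly 1; renormalisation
    # would distort them, so tag them custom and keep them verbatim
    return WeightVector(INDICATOR_IDS, w, Provenance.CUSTOM)


def _ranking_table(methodology: str) -> RankingTable:
    rows = _RANKINGS[methodology]
    frame = pd.DataFrame(
        {"score": [s for _, s, _ in rows], "rank": [r for _, _, r in rows]},
        index=pd.Index([h for h, _, _ in rows], name="hospital_id"),
    )
    return RankingTable(methodology=methodology, frame=frame)


@dataclass(frozen=True)
class ReferenceTables:
    """Bundle of transcribed published values for the sixteen-hospital panel."""

    assigned_scores: dict[str, int]
    subjective: WeightVector
    objective: WeightVector
    combined: WeightVector
    rankings: dict[str, RankingTable]

    @property
    def n_hospitals(self) -> int:
        return len(self.rankings["original"].hospital_ids)


def reference_tables() -> ReferenceTables:
    """The published weights and score/rank tables of the Sichuan panel."""
    return ReferenceTables(
        assigned_scores=dict(ASSIGNED_SCORES),
        subjective=_weight_vector(_SUBJECTIVE, Provenance.SUBJECTIVE),
        objective=_weight_vector(_OBJECTIVE, Provenance.OBJECTIVE),
        combined=_weight_vector(_COMBINED, Provenance.COMBINED),
        rankings={m: _ranking_table(m) for m in METHODOLOGIES},
    )
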
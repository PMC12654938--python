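"""Indicator scheme and threshold-band scoring.

The evaluation scheme used by the China National Stroke Screening Surveys
(CNSSS) quality-control programme grades each base hospital on eleven
indicators (X1..X11).  Each indicator carries an expert-assigned maximum
score and a ladder of threshold bands that convert a raw performance rate
(a fraction such as a task-completion rate) into awarded points.

Two kinds of band are supported:

* *absolute* bands compare the rate against fixed thresholds
  (e.g. ``0.95 <= P < 1.00`` awards 30 points);
* *relative* bands compare the rate against an externally supplied
  reference standard (a national or provincial target value), expressed
  as a relative shortfall (positive indicators) or relative absolute
  deviation (moderate indicators) from that standard, in steps
  (e.g. within 10 % below the standard awards 9 of 12 points).

The reference standards themselves are programme configuration, not part
of the scheme; scoring a relative band without one raises
:class:`ConfigurationError`.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Attribute",
    "BoundMode",
    "ScoringBand",
    "IndicatorDefinition",
    "PerformanceMatrix",
    "SchemeError",
    "ConfigurationError",
    "CoverageError",
    "CompletenessError",
    "RangeError",
    "score_indicator",
    "build_matrix",
    "default_scheme",
]


class SchemeError(ValueError):
    """Base class for indicator-scheme errors."""


class ConfigurationError(SchemeError):
    """A relative band was used without a reference standard."""


class CoverageError(SchemeError):
    """A rate matched no band of the indicator."""


class CompletenessError(SchemeError):
    """A hospital is missing one or more indicator values."""


class RangeError(SchemeError):
    """A cell exceeds the indicator's maximum points."""


class Attribute(str, enum.Enum):
    """Direction of preference for an indicator."""

    POSITIVE = "positive"   # higher is better
    MODERATE = "moderate"   # closer to the column mean / standard is better
    NEGATIVE = "negative"   # lower is better


class BoundMode(str, enum.Enum):
    ABSOLUTE = "absolute"
    RELATIVE = "relative-to-standard"


@dataclass(frozen=True)
class ScoringBand:
    """One rung of an indicator's scoring ladder.

    For ``BoundMode.ABSOLUTE`` the bounds are rate fractions and the band
    matches when ``lower <= P < upper`` (inclusivity configurable).  For
    ``BoundMode.RELATIVE`` the bounds are *deviation offsets* from the
    reference standard: the band matches when the relative shortfall
    (positive attribute) or relative absolute deviation (moderate
    attribute) ``d`` satisfies ``lower <= d < upper``.  ``exact`` bands
    match a single rate value and take precedence over interval bands.
    """

    points: int
    lower: float = -math.inf
    upper: float = math.inf
    mode: BoundMode = BoundMode.ABSOLUTE
    lower_inclusive: bool = True
    upper_inclusive: bool = False
    exact: float | None = None

    def __post_init__(self) -> None:
        if self.points < 0:
            raise SchemeError(f"band points must be >= 0, got {self.points}")
        if self.exact is None and self.lower > self.upper:
            raise SchemeError(
                f"band lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    def matches(self, value: float) -> bool:
        """Whether ``value`` (a rate or a deviation) falls in this band."""
        if self.exact is not None:
            return math.isclose(value, self.exact, rel_tol=0.0, abs_tol=1e-12)
        lo_ok = value >= self.lower if self.lower_inclusive else value > self.lower
        hi_ok = value <= self.upper if self.upper_inclusive else value < self.upper
        return lo_ok and hi_ok


@dataclass(frozen=True)
class IndicatorDefinition:
    """One evaluation criterion of the scheme.

    Parameters
    ----------
    id:
        Short label (``X1`` .. ``X11``).
    name:
        Human-readable indicator name.
    attribute:
        Direction of preference; drives both band matching (for relative
        bands) and min-max normalisation downstream.
    assigned_score:
        Expert-assigned maximum score S_j; the basis of subjective weights.
    bands:
        Ordered scoring ladder.  Exact-match bands are tried first, then
        interval bands in listed order (first match wins).
    reference_standard:
        External target value required by relative bands; ``None`` until
        configured by the user.
    """

    id: str
    name: str
    attribute: Attribute
    assigned_score: int
    bands: tuple[ScoringBand, ...]
    reference_standard: float | None = None

    def __post_init__(self) -> None:
        if self.assigned_score <= 0:
            raise SchemeError(f"{self.id}: assigned_score must be positive")
        if not self.bands:
            raise SchemeError(f"{self.id}: at least one scoring band required")

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bands)

    @property
    def band_points(self) -> tuple[int, ...]:
        """Sorted distinct point values awardable by this indicator."""
        return tuple(sorted({b.points for b in self.bands}))

    @property
    def has_relative_bands(self) -> bool:
        return any(b.mode is BoundMode.RELATIVE for b in self.bands)

    def with_standard(self, standard: float) -> "IndicatorDefinition":
        return replace(self, reference_standard=standard)


def _relative_deviation(rate: float, indicator: IndicatorDefinition) -> float:
    """Deviation of ``rate`` from the reference standard, as a fraction.

    Positive indicators measure the shortfall below the standard (exceeding
    it counts as zero deviation); moderate indicators measure the absolute
    deviation on either side.
    """
    std = indicator.reference_standard
    if std is None or std <= 0:
        raise ConfigurationError(
            f"{indicator.id} ({indicator.name}): relative scoring bands require "
            "a positive reference_standard"
        )
    if indicator.attribute is Attribute.MODERATE:
        return abs(rate - std) / std
    if indicator.attribute is Attribute.NEGATIVE:
        return max(rate - std, 0.0) / std
    return max(std - rate, 0.0) / std


def score_indicator(rate: float, indicator: IndicatorDefinition) -> int:
    """Convert a raw performance rate into awarded points.

    Exact-equality bands are checked before interval bands; interval bands
    are checked in listed order, the first match winning (this is the tie
    rule for overlapping ladders).

    Raises
    ------
    ConfigurationError
        If a relative band is present but no reference standard is set.
    CoverageError
        If the rate falls outside every band.
    """
    if rate < 0 and indicator.attribute is not Attribute.MODERATE:
        raise SchemeError(f"{indicator.id}: rate must be >= 0, got {rate}")

    deviation: float | None = None
    if indicator.has_relative_bands:
        deviation = _relative_deviation(rate, indicator)

    def band_value(band: ScoringBand) -> float:
        if band.mode is BoundMode.RELATIVE:
            assert deviation is not None
            return deviation
        return rate

    for band in indicator.bands:
        if band.exact is not None and band.matches(band_value(band)):
            return band.points
    for band in indicator.bands:
        if band.exact is not None:
            continue
        if band.matches(band_value(band)):
            return band.points
    raise CoverageError(
        f"{indicator.id}: rate {rate!r} matched no scoring band"
    )


@dataclass(frozen=True)
class PerformanceMatrix:
    """An n-hospital by m-indicator grid of awarded points X_ij."""

    hospital_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]
    points: np.ndarray  # shape (n, m), float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        n, m = len(self.hospital_ids), len(self.indicator_ids)
        if pts.shape != (n, m):
            raise SchemeError(
                f"points shape {pts.shape} does not match labels ({n}, {m})"
            )
        if np.isnan(pts).any():
            raise CompletenessError("performance matrix contains missing cells")
        if (pts < 0).any():
            raise RangeError("performance matrix contains negative points")

    @property
    def n(self) -> int:
        return len(self.hospital_ids)

    @property
    def m(self) -> int:
        return len(self.indicator_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points,
            index=pd.Index(self.hospital_ids, name="hospital_id"),
            columns=list(self.indicator_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PerformanceMatrix":
        return cls(
            hospital_ids=tuple(str(h) for h in frame.index),
            indicator_ids=tuple(str(c) for c in frame.columns),
            points=frame.to_numpy(dtype=float),
        )


def build_matrix(
    records: Mapping[str, Mapping[str, float]],
    scheme: Sequence[IndicatorDefinition],
) -> PerformanceMatrix:
    """Assemble a validated :class:`PerformanceMatrix` from per-hospital records.

    Columns are ordered as in ``scheme``.  Every hospital must supply every
    indicator; values above an indicator's maximum points are rejected.
    Non-integer values are accepted (raw-rate workflows) but a warning is
    emitted when a banded indicator holds values off its point lattice.
    """
    indicator_ids = [ind.id for ind in scheme]
    hospital_ids = sorted(records)
    grid = np.empty((len(hospital_ids), len(indicator_ids)), dtype=float)
    for i, hosp in enumerate(hospital_ids):
        row = records[hosp]
        for j, ind in enumerate(scheme):
            if ind.id not in row or row[ind.id] is None:
                raise CompletenessError(
                    f"hospital {hosp!r} is missing indicator {ind.id!r}"
                )
            grid[i, j] = float(row[ind.id])
    for j, ind in enumerate(scheme):
        col = grid[:, j]
        if (col > ind.max_points).any():
            bad = col[col > ind.max_points].max()
            raise RangeError(
                f"{ind.id}: cell value {bad} exceeds max_points {ind.max_points}"
            )
        lattice = np.array(ind.band_points, dtype=float)
        off = ~np.isclose(col[:, None], lattice[None, :], atol=1e-9).any(axis=1)
        if off.any():
            warnings.warn(
                f"{ind.id}: {int(off.sum())} cell(s) are not on the band-point "
                f"lattice {ind.band_points}",
                stacklevel=2,
            )
    return PerformanceMatrix(tuple(hospital_ids), tuple(indicator_ids), grid)


def _abs_bands(*rungs: tuple[float | None, float | None, int]) -> tuple[ScoringBand, ...]:
    """Absolute ladder from (lower, upper, points) rungs; None = open end."""
    out = []
    for lo, hi, pts in rungs:
        out.append(
            ScoringBand(
                points=pts,
                lower=-math.inf if lo is None else lo,
                upper=math.inf if hi is None else hi,
            )
        )
    return tuple(out)


def _relative_ladder(points: Sequence[int]) -> tuple[ScoringBand, ...]:
    """Relative ladder in 10 % deviation steps: points[0] at zero deviation,
    points[k] for deviation in [10(k-1)%, 10k%), 0 points otherwise."""
    bands = [
        ScoringBand(points=points[0], mode=BoundMode.RELATIVE, exact=0.0),
    ]
    for k, pts in enumerate(points[1:], start=1):
        bands.append(
            ScoringBand(
                points=pts,
                lower=0.10 * (k - 1),
                upper=0.10 * k,
                mode=BoundMode.RELATIVE,
            )
        )
    bands.append(
        ScoringBand(points=0, lower=0.10 * (len(points) - 1), upper=math.inf,
                    mode=BoundMode.RELATIVE)
    )
    return tuple(bands)


def default_scheme() -> list[IndicatorDefinition]:
    """The eleven-indicator CNSSS base-hospital evaluation scheme.

    Assigned scores total 112.  Reference standards for the relative-band
    indicators (X2, X4, X5, X6, X7, X8, X11) are left unset and must be
    supplied by the user before raw rates can be scored; scoring awarded
    points directly (the usual workflow) never needs them.
    """
    task_completion = IndicatorDefinition(
        id="X1",
        name="Task Completion Rate",
        attribute=Attribute.POSITIVE,
        assigned_score=35,
        bands=(
            # an exactly-zero completion rate scores 0, not the 15-point floor
            ScoringBand(points=0, exact=0.0),
            ScoringBand(points=35, lower=1.00, upper=math.inf),
            ScoringBand(points=30, lower=0.95, upper=1.00),
            ScoringBand(points=25, lower=0.90, upper=0.95),
            ScoringBand(points=20, lower=0.85, upper=0.90),
            ScoringBand(points=15, lower=0.00, upper=0.85),
        ),
    )
    risk_factor_control = IndicatorDefinition(
        id="X2",
        name="Risk Factor Control Rate",
        attribute=Attribute.POSITIVE,
        assigned_score=12,
        bands=_relative_ladder([12, 9, 6, 3]),
    )
    high_risk_detection = IndicatorDefinition(
        id="X3",
        name="Stroke High-Risk Detection Rate",
        attribute=Attribute.MODERATE,
        assigned_score=6,
        bands=(
            ScoringBand(points=3, lower=0.26, upper=math.inf,
                        lower_inclusive=False),
            ScoringBand(points=6, lower=0.20, upper=0.26, upper_inclusive=True),
            ScoringBand(points=4, lower=0.15, upper=0.20),
            ScoringBand(points=3, lower=0.10, upper=0.15),
            ScoringBand(points=0, lower=-math.inf, upper=0.10),
        ),
    )
    hypertension_awareness = IndicatorDefinition(
        id="X4",
        name="Hypertension Awareness Rate",
        attribute=Attribute.POSITIVE,
        assigned_score=6,
        bands=_relative_ladder([6, 4, 3, 2, 1]),
    )
    hypertension_detection = IndicatorDefinition(
        id="X5",
        name="Hypertension Detection Rate",
        attribute=Attribute.MODERATE,
        assigned_score=3,
        bands=_relative_ladder([3, 2, 1]),
    )
    diabetes_detection = IndicatorDefinition(
        id="X6",
        name="Diabetes Detection Rate",
        attribute=Attribute.MODERATE,
        assigned_score=3,
        bands=_relative_ladder([3, 2, 1]),
    )
    dyslipidemia_detection = IndicatorDefinition(
        id="X7",
        name="Dyslipidemia Detection Rate",
        attribute=Attribute.MODERATE,
        assigned_score=3,
        bands=_relative_ladder([3, 2, 1]),
    )
    high_risk_intervention = IndicatorDefinition(
        id="X8",
        name="Stroke High-Risk Intervention Rate",
        attribute=Attribute.POSITIVE,
        assigned_score=8,
        bands=_relative_ladder([8, 6, 3, 1]),
    )
    intervention = IndicatorDefinition(
        id="X9",
        name="Intervention Rate",
        attribute=Attribute.POSITIVE,
        assigned_score=12,
        bands=_abs_bands(
            (0.85, None, 12),
            (0.70, 0.85, 10),
            (0.50, 0.70, 7),
            (0.30, 0.50, 5),
            (None, 0.30, 0),
        ),
    )
    followup_completion = IndicatorDefinition(
        id="X10",
        name="Follow-up Completion Rate",
        attribute=Attribute.POSITIVE,
        assigned_score=12,
        bands=_abs_bands(
            (1.00, None, 12),
            (0.85, 1.00, 10),
            (0.70, 0.85, 7),
            (0.50, 0.70, 5),
            (None, 0.50, 0),
        ),
    )
    age_deviation = IndicatorDefinition(
        id="X11",
        name="Age Deviation Degree",
        attribute=Attribute.MODERATE,
        assigned_score=12,
        bands=_relative_ladder([12, 9, 6, 3]),
    )
    return [
        task_completion,
        risk_factor_control,
        high_risk_detection,
        hypertension_awareness,
        hypertension_detection,
        diabetes_detection,
        dyslipidemia_detection,
        high_risk_intervention,
        intervention,
        followup_completion,
        age_deviation,
    ]


def attributes_of(scheme: Iterable[IndicatorDefinition]) -> dict[str, Attribute]:
    """Map indicator id -> attribute for a scheme."""
    return {ind.id: ind.attribute for ind in scheme}
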
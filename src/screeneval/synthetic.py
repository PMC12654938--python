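"""Seeded generator of hospital-performance point matrices.

Emulates the shape of a CNSSS annual quality-control panel — n hospitals
by m banded indicators of awarded points — with controllable dispersion
so every pipeline stage (normalisation, entropy weighting, ranking,
methodology comparison) can be exercised without real programme data.

Cells are drawn on each indicator's band-point lattice (the discrete
point values its scoring ladder can award), because real matrices consist
of awarded points, not raw rates.  Per-indicator dispersion controls how
much hospitals differ on that indicator:

* ``none`` — a constant column (all hospitals at the top band): the
  degenerate ceiling case, which downstream receives the minimal entropy
  weight;
* ``low``  — mass concentrated on the top two bands, emulating the
  ceiling effect typical of process-oriented compliance indicators;
* ``high`` — uniform across all bands, the informative regime.

The generator is fully reproducible: identical configuration and seed
produce identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .indicators import IndicatorDefinition, PerformanceMatrix, default_scheme

__all__ = ["Dispersion", "GeneratorConfig", "generate_matrix"]

Dispersion = Literal["none", "low", "high"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic panel.

    Parameters
    ----------
    n_hospitals:
        Number of rows; the reference panel size is 16.
    scheme:
        Indicator definitions supplying the band-point lattices; defaults
        to the eleven-indicator evaluation scheme.
    per_indicator_spread:
        Dispersion level per indicator id; unlisted indicators default to
        ``"high"``.
    ceiling_fraction:
        Fraction of hospitals pinned at maximum points on every indicator
        before sampling, emulating uniformly compliant sites.
    seed:
        Seed of the pseudo-random stream.
    """

    n_hospitals: int = 16
    scheme: tuple[IndicatorDefinition, ...] = field(
        default_factory=lambda: tuple(default_scheme())
    )
    per_indicator_spread: Mapping[str, Dispersion] = field(default_factory=dict)
    ceiling_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be positive")
        if not 0.0 <= self.ceiling_fraction <= 1.0:
            raise ValueError("ceiling_fraction must lie in [0, 1]")
        unknown = set(self.per_indicator_spread) - {i.id for i in self.scheme}
        if unknown:
            raise ValueError(f"unknown indicator ids in spread map: {sorted(unknown)}")


def _hospital_labels(n: int) -> tuple[str, ...]:
    """A, B, ..., Z, AA, AB, ... — spreadsheet-style row labels."""
    labels = []
    for k in range(n):
        s, k = "", k + 1
        while k:
            k, r = divmod(k - 1, 26)
            s = chr(ord("A") + r) + s
        labels.append(s)
    return tuple(labels)


def _column_probabilities(lattice: np.ndarray, spread: Dispersion) -> np.ndarray:
    if spread == "low":
        # top two point values carry 90% of the mass
        p = np.full(lattice.size, 0.1 / max(lattice.size - 2, 1))
        p[-1], p[-2] = 0.6, 0.3
        if lattice.size <= 2:
            p = p[-lattice.size:]
        return p / p.sum()
    return np.full(lattice.size, 1.0 / lattice.size)


def generate_matrix(config: GeneratorConfig) -> PerformanceMatrix:
    """Draw one reproducible n x m awarded-points matrix."""
    n = config.n_hospitals
    m = len(config.scheme)
    grid = np.empty((n, m), dtype=float)
    n_ceiling = int(round(config.ceiling_fraction * n))
    for j, ind in enumerate(config.scheme):
        # independent stream per column so changing one indicator's spread
        # leaves every other column identical
        rng = np.random.default_rng([config.seed, j])
        lattice = np.array(ind.band_points, dtype=float)
        spread = config.per_indicator_spread.get(ind.id, "high")
        if spread == "none":
            grid[:, j] = lattice[-1]
            continue
        p = _column_probabilities(lattice, spread)
        grid[:, j] = rng.choice(lattice, size=n, p=p)
    if n_ceiling:
        # pin the first hospitals at the top band on every indicator
        for j, ind in enumerate(config.scheme):
            grid[:n_ceiling, j] = ind.max_points
    return PerformanceMatrix(
        hospital_ids=_hospital_labels(n),
        indicator_ids=tuple(ind.id for ind in config.scheme),
        points=grid,
    )
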
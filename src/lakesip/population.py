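"""Morphotype population densities, biomass, and incubation growth.

CARD-FISH counts on membrane filters are scaled to volumetric densities by
the screened share of the filter area and the filtered volume; densities and
per-cell carbon contents combine into population biomass; time series of
densities give log-linear growth rates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import CountRecord

__all__ = [
    "counts_to_density",
    "population_biomass",
    "biomass_shares",
    "growth_curve",
    "GrowthStats",
]


def counts_to_density(rec: CountRecord) -> float:
    """Cells per ml from a filter count.

    density = total cells counted (singletons plus the summed sizes of any
    cell clusters) / (fields screened x fraction of filter area per field)
    / volume filtered (ml).
    """
    screened_fraction = rec.fields_screened * rec.filter_area_fraction
    return rec.total_cells / screened_fraction / rec.volume_filtered_ml


def population_biomass(density_per_ml: float, cell_carbon_fg: float) -> float:
    """Population carbon in ug C per litre.

    cells ml^-1 x 1e3 ml L^-1 x fg C cell^-1 x 1e-9 ug fg^-1.
    """
    if density_per_ml < 0 or cell_carbon_fg < 0:
        raise ValueError("inputs must be non-negative")
    return density_per_ml * 1e3 * cell_carbon_fg * 1e-9


def biomass_shares(biomass_by_morphotype: Mapping[str, float]) -> dict[str, float]:
    """Normalise per-morphotype biomass to shares summing to one."""
    total = float(sum(biomass_by_morphotype.values()))
    if total <= 0:
        raise ValueError("total biomass must be positive")
    return {k: v / total for k, v in biomass_by_morphotype.items()}


@dataclass
class GrowthStats:
    """Log-linear growth fit of a morphotype population during incubation."""

    mu_per_day: float
    doubling_time_d: float
    n_points: int


def growth_curve(times_d: Sequence[float], densities_per_ml: Sequence[float]) -> GrowthStats:
    """Specific growth rate from a density time series.

    Fits ln(density) vs time by OLS; with two points this reduces to
    mu = ln(n1/n0) / (t1 - t0).
    """
    t = np.asarray(times_d, dtype=float)
    n = np.asarray(densities_per_ml, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(n <= 0):
        raise ValueError("densities must be positive")
    if t.size == 2:
        mu = float(np.log(n[1] / n[0]) / (t[1] - t[0]))
    else:
        mu = float(stats.linregress(t, np.log(n)).slope)
    doubling = np.log(2) / mu if mu > 0 else float("inf")
    return GrowthStats(mu_per_day=mu, doubling_time_d=float(doubling), n_points=int(t.size))
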
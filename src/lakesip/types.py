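"""Core data containers for the quantification pipeline.

These are plain dataclasses with validation in ``__post_init__``.  Tabular
collections (ROI tables, count tables, depth profiles) interoperate with
pandas DataFrames through ``to_frame``/``from_frame`` helpers where useful.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import constants

__all__ = [
    "IncubationSeries",
    "RateEstimate",
    "DepthProfile",
    "FluxEstimate",
    "RoiMeasurement",
    "CellModel",
    "CountRecord",
    "StoichiometryResult",
    "MORPHOTYPES",
]

#: Recognised methanotroph morphotypes.  ``nc10_rod`` denotes the short
#: Methylomirabilis-like rods that assimilate inorganic carbon and therefore
#: stay unlabeled in 13CH4 incubations.
MORPHOTYPES = ("coccus", "small_rod", "large_rod", "filament", "nc10_rod")


@dataclass
class IncubationSeries:
    """Time series of one tracer observable from a single incubation bottle.

    ``observable`` is one of ``co2_ratio`` (13CO2/total CO2 as an atom
    fraction), ``n30_headspace`` (headspace 30N2 in umol per litre of
    incubation water) or ``biomass_atpct`` (excess 13C atom *fraction* of
    particulate organic carbon).
    """

    times: np.ndarray          # days, strictly increasing, times[0] == 0
    values: np.ndarray
    observable: str = "co2_ratio"
    dic_uM: Optional[float] = None
    label_fraction: float = 1.0
    headspace_ml: Optional[float] = None
    water_ml: Optional[float] = None
    subsample_ml: float = 0.0
    subsample_times: Optional[np.ndarray] = None
    poc_ug: Optional[float] = None
    filtered_volume_ml: Optional[float] = None
    condition: str = "hypoxic"   # {hypoxic | anoxic}
    depth_m: Optional[float] = None
    truth: Optional[object] = None   # SimTruth when synthetic

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0.0 < self.label_fraction <= 1.0):
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.subsample_times is not None:
            self.subsample_times = np.asarray(self.subsample_times, dtype=float)
            if not np.all(np.isin(self.subsample_times, self.times)):
                raise ValueError("subsample_times must be a subset of times")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class RateEstimate:
    """A slope-derived volumetric rate with its regression statistics.

    ``rate`` is in uM d^-1 (uM N d^-1 for denitrification); ``p_value`` is
    one-sided for slope > 0.  ``significant`` flags p < 0.05 — rates that
    fail this are reported, never dropped.
    """

    rate: float
    sem: float
    p_value: float
    n_points_used: int
    intercept: float = 0.0
    r_squared: float = float("nan")
    lag_omitted: bool = False
    units: str = "uM d-1"

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.n_points_used < 3:
            raise ValueError("a rate estimate needs at least 3 points")

    @property
    def significant(self) -> bool:
        return self.p_value < constants.P_SIGNIFICANT

    def ci95(self) -> tuple[float, float]:
        """95% confidence interval of the rate (t distribution, n-2 df)."""
        from scipy import stats

        half = stats.t.ppf(0.975, self.n_points_used - 2) * self.sem
        return (self.rate - half, self.rate + half)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


@dataclass
class DepthProfile:
    """Concentration vs depth, with depth positive downward in metres."""

    depths: np.ndarray
    concentrations: np.ndarray
    species: str = "CH4"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.depths.size != self.concentrations.size:
            raise ValueError("depths and concentrations must have equal length")
        if self.depths.size >= 2 and np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing (downward)")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class FluxEstimate:
    """Fickian flux for one depth zone.

    Gradient is dC/dz with z positive downward, so a positive gradient
    (more methane at depth) drives an upward flux; ``flux_mmol_m2_d`` keeps
    the gradient's sign.
    """

    z_top: float
    z_bottom: float
    gradient_uM_m: float
    diffusivity_cm2_s: float
    flux_mmol_m2_d: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.z_bottom <= self.z_top:
            raise ValueError("z_bottom must exceed z_top")


@dataclass
class RoiMeasurement:
    """Ion counts and derived quantities for one nanoSIMS region of interest.

    Counts are summed over all pixels and planes of the ROI before any ratio
    is formed (count-weighted aggregation gives correct Poisson statistics).
    """

    roi_id: str
    fov_id: str
    morphotype: str
    counts_12C: int
    counts_13C: int
    counts_12C14N: int = 0
    counts_12C15N: int = 0
    is_background: bool = False
    # derived
    ratio_C: Optional[float] = None            # 13C/(12C+13C)
    ratio_N: Optional[float] = None            # 12C15N/(12C14N+12C15N)
    rel_poisson_error_C: Optional[float] = None
    rel_poisson_error_N: Optional[float] = None
    excess_C_atfrac: Optional[float] = None
    excess_N_atfrac: Optional[float] = None
    background_fallback: bool = False
    flagged: bool = False

    def __post_init__(self) -> None:
        for name in ("counts_12C", "counts_13C", "counts_12C14N", "counts_12C15N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellModel:
    """Morphotype geometry and the derived carbon content of a single cell."""

    morphotype: str
    diameter_um: float
    length_um: Optional[float] = None
    volume_um3: float = field(init=False)
    carbon_fg: float = field(init=False)

    def __post_init__(self) -> None:
        from .single_cell import biovolume, carbon_content

        self.volume_um3 = biovolume(self.morphotype, self.diameter_um, self.length_um)
        self.carbon_fg = carbon_content(self.volume_um3)


@dataclass
class CountRecord:
    """One CARD-FISH count of a morphotype on a membrane filter.

    ``filter_area_fraction`` is the fraction of the filter's effective
    filtration area covered by a single field of view, so that
    ``fields_screened * filter_area_fraction`` is the screened share of all
    filtered cells.  Clustered cocci enter through ``cluster_sizes``.
    """

    morphotype: str
    cells_counted: int
    fields_screened: int
    filter_area_fraction: float
    volume_filtered_ml: float
    depth_m: Optional[float] = None
    time_d: Optional[float] = None
    cluster_sizes: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.cells_counted < 0:
            raise ValueError("cells_counted must be >= 0")
        if self.fields_screened <= 0:
            raise ValueError("fields_screened must be positive")
        if self.filter_area_fraction <= 0 or self.volume_filtered_ml <= 0:
            raise ValueError("scaling factors must be positive")

    @property
    def total_cells(self) -> int:
        extra = sum(self.cluster_sizes) if self.cluster_sizes else 0
        return self.cells_counted + int(extra)


@dataclass
class StoichiometryResult:
    """Whether measured denitrification can support measured CH4 oxidation
    at a 5 CH4 : 8 NO3- coupling stoichiometry."""

    mo_rate: float
    denitrification_rate: float
    required_n_rate: float
    feasible: bool

    def as_dict(self) -> dict:
        return asdict(self)
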
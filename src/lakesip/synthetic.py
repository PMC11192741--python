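"""Synthetic data with the statistical structure the estimators assume.

Every generator records the generating truth so that round-trip tests can
compare estimates against it.  The noise model is additive Gaussian on
instrument-level observables (isotope ratios, excess at.%) and Poisson on
raw ion counts; a single integer seed is threaded through all generators,
with one independent RNG stream spawned per bottle or field of view.

Forward models
--------------
co2_ratio
    ratio(t) = natural abundance + (rate * F / DIC) * max(0, t - lag) + noise
n30_headspace
    undisturbed cumulative 30N2 per litre of water,
    P30 * max(0, t - lag) with P30 = rate * F^2 / 2, attenuated by the
    cumulative headspace retention factor of every sampling event strictly
    between 0 and t (each event replaces ``subsample_ml`` of headspace with
    helium; at t = 0 no product exists yet, so that event removes none).
    The rate estimator's multiplicative dilution correction inverts this
    exactly.
biomass_atpct
    excess 13C fraction of POC, (rate * F / POC_uM) * max(0, t - lag) + noise
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import constants
from .types import DepthProfile, IncubationSeries, RoiMeasurement

__all__ = ["SimTruth", "gen_incubation_series", "gen_roi_table", "gen_depth_profile"]

#: Default instrument noise magnitudes per observable (absolute, on the
#: observable's own scale).  The source study prints no instrument
#: precisions; these are stated defaults, not inferred values.
DEFAULT_NOISE = {
    "co2_ratio": 2e-5,        # CRDS 13CO2/total CO2 fraction
    "n30_headspace": 0.01,    # IRMS umol 30N2 per L water
    "biomass_atpct": 0.002,   # EA-IRMS excess 13C fraction of POC
}


@dataclass
class SimTruth:
    """Generating parameters of one synthetic experiment.

    Incubation geometry defaults mirror the study design: 220 ml water with
    ~30 ml headspace in 250 ml serum bottles, 3 ml subsamples replaced with
    helium, >98% 13CH4 labeling (50% for 15N-nitrate runs), and an optional
    ~2-day lag phase before linear tracer-product accumulation.
    """

    seed: int = 0
    true_rate: float = 1.0          # uM d^-1 (uM N d^-1 for n30 series)
    lag_days: float = 0.0
    noise_sd: Optional[float] = None   # None -> per-observable default
    dic_uM: float = 2500.0
    label_fraction: float = 0.98
    headspace_ml: float = 30.0
    water_ml: float = 220.0
    subsample_ml: float = 3.0
    poc_ug: float = 5.0
    filtered_volume_ml: float = 10.0
    true_enrichment: Union[float, dict] = 0.2   # excess 13C atom fraction
    true_enrichment_n: Union[float, dict] = 0.0
    mean_counts: float = 1e6        # expected total ion counts per ROI pair

    def __post_init__(self) -> None:
        if self.true_rate < 0:
            raise ValueError("true_rate must be >= 0")
        if self.lag_days < 0:
            raise ValueError("lag_days must be >= 0")
        if not (0 < self.label_fraction <= 1):
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.mean_counts <= 0:
            raise ValueError("mean_counts must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rng(truth: SimTruth, stream: int = 0) -> np.random.Generator:
    """One reproducible child stream per bottle/FOV."""
    return np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(stream + 1)[stream])


def gen_incubation_series(
    truth: SimTruth,
    times: Sequence[float],
    observable: str = "co2_ratio",
    condition: Optional[str] = None,
    stream: int = 0,
) -> IncubationSeries:
    """Simulate one bottle's tracer time series (default sampling days
    0, 1, 2, 5, 8, 12 should be passed by the caller).

    The deterministic trend is linear after the lag, expressed on the
    observable's own scale; Gaussian noise with the observable's default (or
    ``truth.noise_sd``) is added on top.  The truth is attached to the
    returned series for recovery tests.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if observable not in DEFAULT_NOISE:
        raise ValueError(f"unknown observable: {observable!r}")

    elapsed = np.maximum(0.0, times - truth.lag_days)
    F = truth.label_fraction

    if observable == "co2_ratio":
        slope = truth.true_rate * F / truth.dic_uM
        trend = constants.NATURAL_ABUNDANCE_13C + slope * elapsed
    elif observable == "n30_headspace":
        p30 = truth.true_rate * F**2 / 2.0
        retention = (truth.headspace_ml - truth.subsample_ml) / truth.headspace_ml
        n_prior = np.array([np.sum((times > 0) & (times < t)) for t in times])
        trend = p30 * elapsed * retention ** n_prior.astype(float)
    else:  # biomass_atpct
        poc_uM = (truth.poc_ug / constants.MOLAR_MASS_C) / (
            truth.filtered_volume_ml / 1000.0
        )
        slope = truth.true_rate * F / poc_uM
        trend = slope * elapsed

    sd = DEFAULT_NOISE[observable] if truth.noise_sd is None else truth.noise_sd
    values = trend + (_rng(truth, stream).normal(0.0, sd, size=times.size) if sd > 0 else 0.0)

    if condition is None:
        condition = "anoxic" if observable == "n30_headspace" else "hypoxic"
    return IncubationSeries(
        times=times,
        values=values,
        observable=observable,
        dic_uM=truth.dic_uM,
        label_fraction=F,
        headspace_ml=truth.headspace_ml,
        water_ml=truth.water_ml,
        subsample_ml=truth.subsample_ml if observable == "n30_headspace" else 0.0,
        subsample_times=times,
        poc_ug=truth.poc_ug,
        filtered_volume_ml=truth.filtered_volume_ml,
        condition=condition,
        truth=truth,
    )


def _enrichment_for(truth: SimTruth, morphotype: str, which: str = "C") -> float:
    enrichment = truth.true_enrichment if which == "C" else truth.true_enrichment_n
    if isinstance(enrichment, dict):
        return float(enrichment.get(morphotype, 0.0))
    return float(enrichment)


def gen_roi_table(
    truth: SimTruth,
    n_rois: int,
    n_background: int = 3,
    morphotype: str = "large_rod",
    fov_id: str = "fov01",
    stream: int = 0,
) -> list[RoiMeasurement]:
    """Simulate one field of view's ROI ion-count table.

    Each ROI's minor/major counts for both isotope pairs are independent
    Poisson draws with expected minor fraction = natural abundance + true
    excess (background ROIs: natural abundance only).  At least three
    background measurements per field of view are generated, mirroring the
    background-subtraction design.
    """
    if n_background < 3:
        raise ValueError("need at least 3 background ROIs per field of view")
    rng = _rng(truth, stream)
    excess_c = _enrichment_for(truth, morphotype, "C")
    excess_n = _enrichment_for(truth, morphotype, "N")
    if excess_c < -constants.NATURAL_ABUNDANCE_13C:
        raise ValueError("excess below -natural abundance")
    if excess_n < -constants.NATURAL_ABUNDANCE_15N:
        raise ValueError("15N excess below -natural abundance")

    def draw(p: float) -> tuple[int, int]:
        minor = int(rng.poisson(truth.mean_counts * p))
        major = int(rng.poisson(truth.mean_counts * (1.0 - p)))
        return minor, major

    rois = []
    for i in range(n_rois + n_background):
        is_bg = i >= n_rois
        p_c = constants.NATURAL_ABUNDANCE_13C + (0.0 if is_bg else excess_c)
        p_n = constants.NATURAL_ABUNDANCE_15N + (0.0 if is_bg else excess_n)
        c13, c12 = draw(p_c)
        n15, n14 = draw(p_n)
        rois.append(
            RoiMeasurement(
                roi_id=f"{fov_id}_{'bg' if is_bg else 'roi'}{i:04d}",
                fov_id=fov_id,
                morphotype="background" if is_bg else morphotype,
                counts_12C=c12,
                counts_13C=c13,
                counts_12C14N=n14,
                counts_12C15N=n15,
                is_background=is_bg,
            )
        )
    return rois


def gen_depth_profile(
    knots: Sequence[tuple[float, float]],
    noise_sd: float = 0.0,
    step_m: float = 1.0,
    species: str = "CH4",
    seed: int = 0,
) -> DepthProfile:
    """Piecewise-linear concentration profile sampled every ``step_m``.

    ``knots`` are (depth, concentration) pairs with depths increasing
    downward; zone fitting recovers the knot slopes exactly when noise is
    zero.  Noisy concentrations are clipped at zero.
    """
    if len(knots) < 2:
        raise ValueError("need at least 2 knots")
    kd = np.array([k[0] for k in knots], dtype=float)
    kc = np.array([k[1] for k in knots], dtype=float)
    if np.any(np.diff(kd) <= 0):
        raise ValueError("knot depths must be strictly increasing")
    if np.any(kc < 0):
        raise ValueError("knot concentrations must be non-negative")
    depths = np.arange(kd[0], kd[-1] + step_m / 2.0, step_m)
    depths = np.unique(np.concatenate([depths, kd]))
    conc = np.interp(depths, kd, kc)
    if noise_sd > 0:
        conc = conc + np.random.default_rng(seed).normal(0.0, noise_sd, depths.size)
        conc = np.clip(conc, 0.0, None)
    elif noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    return DepthProfile(depths=depths, concentrations=conc, species=species)
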
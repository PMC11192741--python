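"""Zone-wise vertical methane fluxes from concentration-depth profiles.

Fluxes follow Fick's first law F = D * dC/dz with a turbulent diffusion
coefficient D (default 0.27 cm^2 s^-1, appropriate for an internally mixed
water column rather than molecular diffusion).  Depth is positive downward;
a positive gradient (concentration increasing with depth) yields a positive
flux, read as upward transport toward the oxycline.

Zone boundaries are user-supplied: they were chosen by eye from slope
changes in the measured profile, and reproducing that manual choice exactly
is preferred over re-detecting it.  An optional least-squares piecewise fit
with a fixed number of interior breakpoints is available but never applied
automatically.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from . import constants
from .types import DepthProfile, FluxEstimate

__all__ = ["Zone", "segment_zones", "fick_flux", "zone_fluxes", "fit_breakpoints"]


@dataclass
class Zone:
    """One contiguous depth interval with its OLS concentration gradient."""

    z_top: float
    z_bottom: float
    gradient_uM_m: float
    intercept_uM: float
    n_points: int


def segment_zones(profile: DepthProfile, breakpoints: Sequence[float]) -> list[Zone]:
    """Split a profile at the given depths and fit a gradient per zone.

    ``breakpoints`` are zone edges (including the outermost ones), e.g.
    ``[120, 135, 160, 180]`` gives three zones.  Boundary points belong to
    both adjacent zones.
    """
    bps = sorted(float(b) for b in breakpoints)
    if len(bps) < 2:
        raise ValueError("need at least two breakpoints (zone edges)")
    lo, hi = profile.depths.min(), profile.depths.max()
    for b in bps:
        if b < lo or b > hi:
            raise ValueError(f"breakpoint {b} outside profile range [{lo}, {hi}]")
    zones = []
    for z_top, z_bottom in zip(bps[:-1], bps[1:]):
        mask = (profile.depths >= z_top) & (profile.depths <= z_bottom)
        z = profile.depths[mask]
        c = profile.concentrations[mask]
        if z.size < 2:
            raise ValueError(f"zone [{z_top}, {z_bottom}] has fewer than 2 points")
        if z.size == 2:
            slope = (c[1] - c[0]) / (z[1] - z[0])
            intercept = c[0] - slope * z[0]
        else:
            res = stats.linregress(z, c)
            slope, intercept = float(res.slope), float(res.intercept)
        zones.append(
            Zone(
                z_top=z_top,
                z_bottom=z_bottom,
                gradient_uM_m=float(slope),
                intercept_uM=float(intercept),
                n_points=int(z.size),
            )
        )
    return zones


def fick_flux(
    gradient_uM_m: float,
    diffusivity_cm2_s: float = constants.DEFAULT_DIFFUSIVITY_CM2_S,
    z_top: float = 0.0,
    z_bottom: float = 1.0,
    n_points: int = 0,
) -> FluxEstimate:
    """F = D * dC/dz, reported in mmol m^-2 d^-1.

    Conversion chain: D [cm^2 s^-1] -> m^2 d^-1 (x 1e-4 x 86400);
    gradient [uM m^-1] = 1e-3 mol m^-4; product in mol m^-2 d^-1 -> x 1e3
    mmol m^-2 d^-1.  The two 1e3 factors cancel, so numerically
    flux = D[m^2 d^-1] * gradient[uM m^-1].
    """
    if diffusivity_cm2_s <= 0:
        raise ValueError("diffusivity must be positive")
    d_m2_d = constants.diffusivity_cm2_s_to_m2_d(diffusivity_cm2_s)
    flux = d_m2_d * gradient_uM_m
    return FluxEstimate(
        z_top=z_top,
        z_bottom=z_bottom,
        gradient_uM_m=gradient_uM_m,
        diffusivity_cm2_s=diffusivity_cm2_s,
        flux_mmol_m2_d=flux,
        n_points=n_points,
    )


def zone_fluxes(
    profile: DepthProfile,
    breakpoints: Sequence[float],
    diffusivity_cm2_s: float = constants.DEFAULT_DIFFUSIVITY_CM2_S,
) -> list[FluxEstimate]:
    """Segment a profile and convert every zone gradient to a flux."""
    return [
        fick_flux(
            z.gradient_uM_m,
            diffusivity_cm2_s,
            z_top=z.z_top,
            z_bottom=z.z_bottom,
            n_points=z.n_points,
        )
        for z in segment_zones(profile, breakpoints)
    ]


def fit_breakpoints(profile: DepthProfile, n_zones: int) -> list[float]:
    """Least-squares piecewise-linear fit with a fixed zone count.

    Exhaustively searches interior breakpoints over the observed depths and
    returns the full edge list (outer edges are the profile ends).  Intended
    as a cross-check of manually chosen zone boundaries, not a replacement.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    depths = profile.depths
    interior_candidates = depths[1:-1]
    if n_zones == 1:
        return [float(depths[0]), float(depths[-1])]

    def sse(edges):
        total = 0.0
        for z in segment_zones(profile, edges):
            mask = (depths >= z.z_top) & (depths <= z.z_bottom)
            pred = z.intercept_uM + z.gradient_uM_m * depths[mask]
            total += float(np.sum((profile.concentrations[mask] - pred) ** 2))
        return total

    best, best_sse = None, np.inf
    for combo in combinations(interior_candidates, n_zones - 1):
        edges = [float(depths[0]), *map(float, combo), float(depths[-1])]
        try:
            val = sse(edges)
        except ValueError:  # a zone with < 2 points
            continue
        if val < best_sse:
            best, best_sse = edges, val
    if best is None:
        raise ValueError("no valid breakpoint combination found")
    return best
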
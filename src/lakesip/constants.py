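"""Physical and methodological constants shared across the pipeline.

All of these may be overridden per run through :mod:`lakesip.config`; the
values here are the defaults used when nothing else is specified.
"""

#: Natural abundance of the minor carbon isotope, as the atom fraction
#: 13C/(12C+13C).  Used as the baseline subtracted from measured ratios.
NATURAL_ABUNDANCE_13C = 0.011

#: Natural abundance of 15N as the atom fraction 15N/(14N+15N), measured on
#: the CN- secondary ion pair 12C15N/(12C14N+12C15N).
NATURAL_ABUNDANCE_15N = 0.0036

#: Molar mass of carbon in g mol^-1 (equivalently fg fmol^-1), used for every
#: fg -> fmol and ug -> umol conversion of biomass carbon.
MOLAR_MASS_C = 12.011

#: Allometric biovolume-to-carbon scaling C_fg = CARBON_A * V**CARBON_B
#: (V in um^3, C in fg).
CARBON_A = 197.0
CARBON_B = 0.46

#: Turbulent diffusion coefficient for the water column, cm^2 s^-1.
DEFAULT_DIFFUSIVITY_CM2_S = 0.27

#: Relative Poisson counting-error threshold above which a nanoSIMS ROI is
#: discarded (applies to both the C and the CN isotope ratios).
POISSON_ERROR_THRESHOLD = 0.05

#: Moles of nitrate-N reduced per mole of CH4 oxidised to CO2 when methane
#: oxidation is coupled to complete denitrification (5 CH4 : 8 NO3-).
NITRATE_PER_METHANE = 8.0 / 5.0

#: Number of regression points used for bulk rate estimation (the later
#: time points are retained in the data but excluded from the fit because
#: tracer-product accumulation turns exponential).
DEFAULT_N_POINTS = 5

#: One-sided significance threshold for slope > 0.
P_SIGNIFICANT = 0.05

SECONDS_PER_DAY = 86400.0


def diffusivity_cm2_s_to_m2_d(d_cm2_s: float) -> float:
    """Convert a diffusivity from cm^2 s^-1 to m^2 d^-1."""
    return d_cm2_s * 1e-4 * SECONDS_PER_DAY


def diffusivity_m2_d_to_cm2_s(d_m2_d: float) -> float:
    """Inverse of :func:`diffusivity_cm2_s_to_m2_d`."""
    return d_m2_d / (1e-4 * SECONDS_PER_DAY)
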
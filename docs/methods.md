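# Methods

## Scope and model overview

`lakesip` implements the quantification chain of a stable-isotope-probing
(SIP) study of methane-oxidizing bacteria (MOB) in a stratified lake water
column.  Three measurement levels are modeled:

1. **Bottle incubations.**  Lake water amended with ¹³CH₄ (and, anoxically,
   ¹⁵NO₃⁻) accumulates tracer product linearly in time, optionally after a
   lag phase while the community adapts.  The observables are the
   ¹³CO₂/ΣCO₂ atom fraction (cavity ring-down spectrometry), headspace ³⁰N₂
   (isotope-ratio MS), and the excess ¹³C atom fraction of bulk particulate
   organic carbon (EA-IRMS).
2. **Water-column profiles.**  Under a steady-state assumption, changes of
   slope in the methane concentration profile delimit consumption zones;
   the vertical flux through each zone is Fickian with a turbulent
   diffusivity.
3. **Single cells.**  nanoSIMS ion counts per region of interest (ROI) give
   per-cell isotope ratios, filtered by counting statistics, converted to
   excess enrichment against in-field backgrounds, and to per-cell carbon
   assimilation and growth via morphotype geometry and a bacterial
   biovolume-to-carbon allometry.

## Bulk rate estimation

All three rates are OLS slopes over the **first five** sampling time points
(default schedule 0, 1, 2, 5, 8, 12 days).  The day-12 point is retained in
the data but excluded from fits by default, because tracer-product
accumulation turns exponential late in the incubations.  Significance is a
one-sided *t*-test of slope > 0 at p < 0.05; non-significant rates are
reported with a flag rather than dropped.  Lag handling is an explicit
opt-in (`omit_lag_until`): the user states the lag end, points before it are
discarded, and the estimate is flagged `lag_omitted`.  No automatic
changepoint detection is attempted — the original depth-by-depth judgement
is an input, not something to re-derive.

Unit conversions:

- **Methane oxidation**: `slope(¹³CO₂ fraction) · DIC / F_CH₄`, in µM CH₄
  d⁻¹.  DIC is assumed constant per bottle.  The ¹³CH₄ labeling fraction
  F_CH₄ (default 0.98) is honoured in the conversion; setting it to 1.0
  reproduces the convention of treating a >98% label as pure.
- **Denitrification**: measured headspace ³⁰N₂ (referenced to the water
  volume) is first corrected for subsampling dilution (below), then
  `rate = 2 · slope / F²`, in µM N d⁻¹.  The factor 2 counts both N atoms
  per N₂; F² is the isotope-pairing assumption that ³⁰N₂ forms from two
  independent draws out of a nitrate pool with ¹⁵N atom fraction F (default
  0.5).  ²⁹N₂ is read but never converted to a rate, since it can arise
  from N transformations other than denitrification.  N₂O observables
  produce no rate: its concurrent microbial consumption makes a volumetric
  production rate underdetermined.
- **Assimilation**: `slope(excess ¹³C fraction of POC) · POC_µM / F_CH₄`,
  in µM C d⁻¹, with POC converted from µg to µmol by the molar mass of
  carbon, 12.011 g mol⁻¹ (used for every carbon mass conversion in the
  package; using the ¹³C mass instead would misstate the per-cell rates
  derived downstream).

**Headspace dilution.**  Each sampling event withdraws `v` ml of headspace
and replaces it with helium, retaining a fraction `d = (V_h − v)/V_h` of the
gaseous tracer product.  The measured value at time *t* is modeled as the
undisturbed cumulative production attenuated by `d^k`, where *k* counts the
sampling events strictly between 0 and *t* (the day-0 event removes no
product because none exists yet).  The estimator inverts this exactly by
multiplying each point by `d^(−k)`.  This cumulative multiplicative form is
a modeling choice: a strictly sequential dilute-then-accumulate bookkeeping
would attenuate recent production less than old production and admits no
exact per-point correction.  The difference is at most a few percent per
point at the default geometry (3 ml from 30 ml); we prefer the form that the
standard correction inverts exactly.  Water–headspace re-equilibration
between samplings is ignored.

**Derived summaries.**  The assimilated fraction is
`a / (a + o)` — assimilation over total methane consumed (biomass + CO₂);
this denominator reproduces all four reported depth/condition percentages
(52, 64, 56, 60%).  The stoichiometric feasibility check asks whether
measured denitrification can supply the nitrate demand of the measured
methane oxidation at 5 CH₄ : 8 NO₃⁻ (complete oxidation to CO₂ coupled to
denitrification to N₂): `required_N = (8/5) · MO`, feasible iff the measured
N rate meets it.

## Fluxes

`F = D · dC/dz` with D defaulting to 0.27 cm² s⁻¹ — a *turbulent* diffusion
coefficient, reflecting internal currents rather than molecular diffusion.
Depth is positive downward, so a positive gradient (more methane at depth)
yields a positive flux read as upward transport; the convention is applied
once, here.  Unit chain: D in m² d⁻¹ (×1e-4×86400) times gradient in
mol m⁻⁴ (µM m⁻¹ × 1e-3), reported in mmol m⁻² d⁻¹.  Zone edges are
user-supplied; `fit_breakpoints` offers a least-squares piecewise fit with a
fixed zone count as a cross-check but is never applied automatically.

## Single-cell quantification

ROI ion counts are summed over all pixels and planes *before* ratios are
formed (count-weighted aggregation is what makes the Poisson error formula
applicable).  For a minor/major count pair the relative counting error of
the isotope ratio is `sqrt(1/N_minor + 1/N_major)`; by the delta method this
is exact to O(1/N) for the minor/major ratio.  For the atom *fraction*
minor/(minor+major) the same expression overstates the error by a factor
1/(1 − p), negligible at natural abundance but not at tracer-level
enrichment — the filter is therefore defined, and tested, on the
minor/major ratio.  ROIs whose C or N ratio error exceeds 5% are excluded;
ROIs with a zero minor count are flagged and always excluded.

Excess atom fractions subtract the mean ratio of ≥3 background ROIs from
the same field of view; without backgrounds the constants 0.011 (¹³C) and
0.0036 (¹⁵N) are used and the ROI is marked `background_fallback`.

Geometry: cocci are spheres (πd³/6); rods are cylinders with hemispherical
caps (π(d/2)²(l − d) + πd³/6, length tip to tip); filaments are plain
cylinders.  Carbon per cell follows `C_fg = 197 · V^0.46`.  This allometry
was derived for smaller cells than some of the morphotypes here; it is used
for lack of a bacterial alternative and its concavity means large cells'
carbon is likely conservative.  Per-cell assimilation is
`C_fg · excess / 12.011 / t` in fmol ¹³C cell⁻¹ d⁻¹.

**Growth rates.**  Under exponential growth on a substrate with effective
label atom fraction A, the cell's excess enrichment after time t satisfies
`excess = A(1 − e^(−µt))`, giving `µ = ln(A/(A − excess))/t`.  A linear
(non-compounding) variant `µ = (x/(1−x))/t`, x = excess/A, is available.
The effective A of a labeling experiment is rarely reported — cells draw
part of their carbon from unlabeled pools — so `calibrate_label_fraction`
fits A by least squares to observed (excess, µ) pairs.  Default A is 1.0
(fully labeled substrate); the calibrated value for the bundled morphotype
table is ≈0.74 and is reported as a calibration output, never hard-coded as
a constant.  Excess ≥ A signals label exhaustion and raises.

`percell_from_bulk` apportions a bulk volumetric rate over a population
count (fmol cell⁻¹ d⁻¹ = µM d⁻¹ / (cells ml⁻¹ · 10³) · 10⁹); both a
consumption-based and an oxidation-based numerator are meaningful, and the
caller chooses which rate to pass.

## Populations

Filter-count scaling: `cells / (fields · filter_area_fraction) / volume`,
with clustered cocci contributing the sum of their cluster sizes.  The
field/filter geometry is explicit configuration (nominal 25 mm filters with
10–20 ml filtered in the fixtures), since it is instrument-specific.
Biomass is density × per-cell carbon; morphotype shares normalise to a
probability vector.  Growth is a log-linear OLS fit of density vs time,
reducing to `ln(n₁/n₀)/Δt` for two points.

## Synthetic data generator

The generator produces every input the pipeline consumes, with the study's
incubation design as defaults: 220 ml water and ~30 ml headspace in 250 ml
serum bottles, 3 ml helium-replaced subsamples at days 0, 1, 2, 5, 8, 12,
¹³CH₄ labeling 0.98, ¹⁵NO₃⁻ labeling 0.5, an optional ~2-day lag phase
modeled as a hard changepoint (zero slope, then constant slope — the
simplest shape consistent with the observed adaptation period).  DIC
defaults to 2500 µM (typical of a hard-water peri-alpine lake hypolimnion)
and POC to 5 µg per 10 ml filtered (≈0.5 mg C L⁻¹).

Noise is additive Gaussian on instrument-level observables and Poisson on
raw ion counts, matching the error structure of the two measurement levels.
The instrument noise magnitudes are stated defaults (CRDS ratio sd 2×10⁻⁵,
IRMS ³⁰N₂ sd 0.01 µmol L⁻¹, EA-IRMS excess-fraction sd 0.002), not values
taken from any published precision.  A single integer seed is threaded
through all generators with one spawned RNG stream per bottle or field of
view.

What the generator does **not** emulate: instrument drift and detector
dead time, headspace–water re-equilibration kinetics, non-linear late-phase
tracer accumulation, within-morphotype biovolume variance, and community
heterogeneity of the POC pool.  Passing recovery tests therefore
demonstrate the estimators are correct inverses of the stated measurement
models — not that those models capture every feature of field data.

## Numerical choices and degenerate inputs

- OLS via `scipy.stats.linregress`; a perfect fit (zero residual) returns
  SEM 0 and one-sided p → 0 (0.5 for an exactly flat series).
- Rate conversions rescale slope, SEM and intercept by the same positive
  factor; t statistics, p values and R² are scale-invariant.
- Fits require ≥3 points after lag omission; zero time variance raises.
- `calibrate_label_fraction` is a bounded scalar minimisation on
  (max excess, 1] with xatol 1e-10.
- Breakpoint search in `fit_breakpoints` is exhaustive over observed depths
  (the profiles are small); zones with <2 points are skipped.
- Report JSON is serialised with sorted keys and `allow_nan=False`;
  identical config + seed is byte-identical by construction.

## Problem sizes

Monte-Carlo validations use 200 replicate bottles per scenario for recovery
and coverage, 5×10⁴–10⁵ Poisson draws for the counting-error oracle, and
200–3000 ROIs per synthetic field of view; these sizes give Monte-Carlo
standard errors well below the tolerances being checked while keeping the
full suite in the seconds range.

## Known limitations

- No Michaelis–Menten or kinetic modeling of methane oxidation, no isotope
  fractionation corrections, no ²⁹N₂-based anammox partitioning.
- CARD-FISH treatment can isotopically dilute cellular ratios; no
  correction factor is applied, so per-cell rates of hybridised cells may
  be conservative relative to unhybridised filaments.
- The assimilated-fraction denominator assumes assimilation + oxidation to
  CO₂ exhausts methane consumption (no fatty-acid excretion pool is
  tracked separately).
- Zone fluxes inherit the steady-state assumption; no reaction–diffusion
  inversion of consumption rates is attempted.
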
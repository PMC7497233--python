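# Methods

## The problem

Substrate-independent measurement of soil microbial growth traces ¹⁸O from
labeled soil water into newly synthesized genomic DNA. The standard protocol
introduces the label as liquid water, which on dry soil triggers the Birch
effect — a burst of respiration and (delayed) growth caused by rewetting —
so the measured physiology reflects the response to rewetting, not the dry
state. The vapor-equilibration alternative places the labeled water in the
vial *next to* the soil: oxygen isotopes redistribute between the two liquid
pools through the vapor phase, labeling the soil water without changing its
content. The price is that the soil-water enrichment is no longer constant
over the incubation, and the growth calculus must account for its kinetics.

## Equilibration model

Soil-water enrichment (atom% ¹⁸O) under vapor equilibration follows a
negative exponential relaxation

    at(t) = at24 + (at_in − at24)·exp(−b·t)

with `at_in` the initial enrichment (natural abundance ≈ 0.2005 atom%
unless measured), `at24` the plateau, and `b` (h⁻¹) a soil-specific rate
coefficient. Fitting is nonlinear least squares (trust-region reflective via
lmfit) with deterministic starting values: `at24⁰` = last observation,
`at_in⁰` = first observation, and `b⁰` from an ordinary regression of
log|(y − at24⁰)/(at_in⁰ − at24⁰)| on t. Replicates are fitted as individual
observations, never pre-averaged. Non-convergence is reported as a flag on
the result and propagates to a non-zero pipeline exit code; it is never
silently replaced by the best iterate. A series with fewer than three
distinct time points (two when `at_in` is fixed), or with zero spread, is
rejected as degenerate.

Because DNA synthesis integrates label over the incubation, growth uses the
**time-averaged** enrichment, computed in closed form as

    ⟨at⟩ = at24 + (at_in − at24)·(1 − e^(−bT))/(bT),

evaluated with `expm1` so small `bT` is numerically safe; it agrees with
adaptive quadrature of the curve to better than 1e−8 relative (measured:
~1e−15). The average can also be expressed as a fraction of the enrichment a
direct liquid addition achieves; by default both numerator and denominator
are taken in excess of natural abundance so an unlabeled soil yields exactly
0 (a raw-ratio mode exists behind a flag, since the convention is a genuine
choice).

The default horizon is 24 h but is configurable: the kinetics depend on vial
geometry, so the coefficient must be re-measured when a different headspace
volume is used.

### Indirect route

In the closed two-pool system both pools relax with the *same* rate `b`, so
fitting the exponential to the easily sampled external label pool (which
decays) yields `b` and the shared plateau without cryodistilling soil water.
The returned soil model takes `at_in` from the known initial soil value and
the plateau either from the external fit (default) or from a measured 24-h
soil value (`plateau_source: measured_24h`); the choice is logged. A rising
external series is physically inconsistent with this geometry and is
flagged. **Limitation:** the precision of the indirect route depends on the
decay amplitude of the external pool. When the external pool is much larger
than the soil pool its enrichment changes little, and at realistic water
measurement noise (σ ≈ 0.3 atom%) the inferred `b` becomes imprecise; the
route is at its best with comparably sized pools.

## Isotope arithmetic

All internal computation is in atom fraction; atom% appears only at I/O
boundaries. Pool mixing is a mole-of-oxygen balance, not a mass balance,
because at 20–99 atom% the molar mass of water (18.015 + 2·x g/mol) differs
appreciably from natural water; volumes convert to moles via a 0–40 °C
density table. Cryodistillation fractionation is corrected by a linear
calibration (measured vs known atom% of standards carried through the same
extraction), one curve per extraction batch; with five standards a straight
line is the minimal defensible form, and an offset-only mode is available.
Corrected values outside [0, 100] atom% are clipped and flagged.

## Endpoint calculus

Respiration: Δppm CO₂ over the incubation × ideal-gas moles of headspace
(default 25.8 ml effective volume = 27 ml vial − 1.2 ml inner vial, solids
neglected; 25 °C, 101.325 kPa, all configurable) × 12.011 g/mol, per g dry
soil, with dry mass = fresh/(1 + gwc) and gwc on a dry-mass basis. Negative
accumulations are allowed (noise) but flagged; no blank correction is
applied by default.

Growth: DNA produced = O_DNAextr · (at%_DNA,L − at%_DNA,n.a.)/at%_soilwater
· 100/31.21, where 31.21% is the mean oxygen content of DNA. The soil-water
term is the time average for vapor arms and the constant mixing value for
liquid arms, used as raw atom% exactly as the calculus is conventionally
written (an excess mode exists for sensitivity analysis). Negative DNA label
excess is clipped to zero with a flag — negative growth is unphysical, but
the event must stay visible. DNA converts to biomass C through the
soil-specific ratio f_DNA = microbial biomass C / DNA stock, which must be
supplied per soil (chloroform-fumigation MBC and fluorimetric DNA); the
synthetic generator supplies it for simulated soils.

Uptake = growth + respiration; CUE = growth/uptake, undefined (flagged) when
both fluxes are zero. Fluxes are reported per incubation and per hour;
method comparisons use per-incubation group means and report ratios and
percent differences only — inferential statistics are left to downstream
tools.

## Synthetic generator

The generator emulates the full comparison design: three soils × dry/moist ×
{vapor, liquid-high, liquid-low, control} × replicates. Choices and their
rationale:

- **Two-pool model, massless vapor.** The headspace vapor holds ≪1% of the
  oxygen moles at these scales, so it is treated as a conduit; the observed
  kinetics then have a single rate, matching the fitted model exactly.
  Liquid–vapor equilibrium fractionation cancels between two liquid pools at
  equal temperature and is omitted by default (an α hook exists for
  sensitivity runs). The numeric integrator (LSODA, rtol 1e−12) is kept only
  as a cross-check against the analytic solution.
- **Soil presets.** "fast", "medium", "slow" soils with b = 0.6, 0.3,
  0.12 h⁻¹ span the qualitative range observed across contrasting soil
  types; WHC 0.55/0.50/0.45 g/g and f_DNA 25/20/15 are generator choices in
  the realistic range for grassland/forest/arable soils.
- **Vial geometry.** 400 mg soil, 25.8 ml effective headspace; dry soils at
  gwc 0.05, moist at 35% of WHC. The full water addition brings the soil to
  60% WHC; the label enrichment is solved (fixed-point on the mixing
  balance) so the equilibrated/mixed soil water hits 20 atom%; the
  low-volume arm adds 30 µl of correspondingly more enriched water to reach
  the same 20 atom%.
- **Fluxes.** Defaults: unstimulated dry-soil growth 6 and respiration
  8 µg C g⁻¹ per 24 h (CUE 0.429, in the upper range expected for dry
  conditions); moist soils scale both by 2.5 (CUE unchanged). Rewetting
  multipliers (dry liquid arms only) default to 4.5 (respiration) and 2.8
  (growth), inside the three-to-six-fold respiration burst reported for
  rewetted dry soils; the low-volume arm receives 60% of the multiplier
  excess. The control (no-water) arm emits respiration only.
- **Noise.** Water atom% observations: σ 0.3 atom% (cryodistillation +
  equilibration IRMS). DNA ¹⁸O: σ 0.01 atom% — TC/EA-IRMS on DNA is far more
  precise than the water route, and the DNA label excess is itself only a
  few tenths of an atom%, so a single shared noise scale would be
  unphysical. Headspace CO₂: σ 5 ppm. All noise comes from one seeded
  generator; a fixed seed reproduces every output byte-for-byte.
- **Growth timing.** Growth is uniform over the incubation, which is exactly
  the assumption the time-average correction encodes. A `late_burst` mode
  concentrates growth in the final hours (default 6 h window): DNA then sees
  a higher-than-average enrichment and the uniform-growth pipeline
  *overestimates* growth — the mode exists precisely to probe that bias.

What the generator does **not** emulate: pore-scale water diffusion and
texture effects on b; time-resolved Birch dynamics (the respiration burst
and delayed growth are collapsed into scalar multipliers); abiotic CO₂
exchange (carbonates); DNA extraction efficiency below 1. Passing recovery
tests therefore show the calculus and fitting are self-consistent under
these idealized conditions, not that field measurements reach the same
precision.

## Numerical and degenerate-input policy

Fits use xtol = ftol = gtol = 1e−15 so noiseless data converge to machine
precision; b is bounded below at 1e−9 h⁻¹ and enrichments to [0, 100] atom%.
Pipeline validation lists every offending row with its number; rows are
never silently dropped (a vial that cannot be computed keeps its row, with
flags). Exit codes: 0 success, 1 validation failure, 2 computational failure
(any required fit failed or was degenerate).

## Problem sizes

The simulation-based checks use 1,000 parameter draws for the quadrature
identity, 100 random systems for the two-pool oracle, 200 Monte-Carlo seeds
for noisy recovery (kinetics, indirect equivalence, CUE — the CUE loop uses
the single medium soil per seed), and a 3×3 multiplier grid for the
direction property; these sizes give stable medians while keeping the whole
battery around ten seconds.
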
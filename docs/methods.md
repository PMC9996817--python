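# Methods

## Passive-sampler model

Uptake into a silicone-rubber sheet is isotropic first-order exchange:

    dN/dt = Rs·Cw(t) − ke·N,      Rs = ke·Kpw·m

with polymer mass *m* (kg), partition coefficient *K*ₚw (L kg⁻¹), exchange
coefficient *k*ₑ (d⁻¹) and sampling rate *R*ₛ (L d⁻¹). For a deployment of
length *T*,

    N(T) = ∫ Rs·Cw(t)·e^(−ke(T−t)) dt,

integrated exactly over piecewise-constant concentration histories
(`synth.gen_pas_uptake`), which for constant *C*w reduces to
*K*ₚw·*m*·*C*w·(1 − e^(−*k*ₑT)). Inversion (`pas.water_concentration`)
divides by the same factor; *k*ₑ = 0 falls back to the kinetic form
*N*/(*R*ₛ·t). The two forms differ by ≈ *k*ₑ·t/2 relative, so the simple
1/t duration rescaling (`pas.rescale_kinetic`) is accurate to 1% only
while *k*ₑ·t ≲ 0.02; the default field kinetics sit at *k*ₑ·t ≈ 10⁻⁴,
firmly in the kinetic regime.

Calibration:

* **Cosolvent regression** — apparent log *K*ₚw is linear in methanol mole
  fraction (the simplest of the defensible cosolvent models); the OLS
  intercept is the pure-water log *K*ₚw. Defaults (deltamethrin 5.86 AlteSil,
  5.45 SSP; cypermethrin 5.45/4.82; diflubenzuron 2.32/2.00; teflubenzuron
  3.33/2.95) are the laboratory values shipped with `PolymerSampler`.
* **PRC kinetics** — *k*ₑ = −ln(fraction retained)/days per PRC, pooled by
  arithmetic mean over PRCs with retention inside (0.05, 0.95) (outside
  that window the estimate is dominated by analytical noise or full
  dissipation). Transfer to the analyte assumes a compound-independent
  *R*ₛ by default, so *k*ₑ scales by the *K*ₚw ratio; an
  *R*ₛ ∝ M^p molar-mass rule is selectable where PRC and analyte differ
  strongly in size. Regime labels: kinetic below *k*ₑT = 0.2, equilibrium
  above 3.

Field defaults are back-derived from the paired detection limits
(0.04 ng g⁻¹ polymer ≡ 4 ng L⁻¹ at 0.5 days): sheet mass 10 g and
*R*ₛ/m = 20 L d⁻¹ kg⁻¹ (`pas.field_kinetics`). Reported concentrations are
rounded half-away-from-zero to integers (LODs to one decimal); the raw
values are always retained alongside (`ScenarioTable.raw`), since exact
half values make the rounding convention visible in reported tables. Every
water estimate carries the ±50% analytical uncertainty band as metadata.

## Dispersal model

A 2-D depth-integrated surrogate for a full coastal hydrodynamic run: the
headline outputs (maximum-concentration map, exposure-time map) are
horizontal fields, and a desk-scale solver makes them reproducible without
an ocean model. Released mass is mixed over the cage footprint (default
radius 25 m) down to the mixing depth (default 10 m, the pen depth during
treatment), then advected/diffused as a passive tracer:

* flux-form donor-cell upwind advection (positivity over accuracy — the
  maps feed threshold metrics where undershoots would corrupt areas),
  operator-split per axis;
* centred 5-point diffusion, default horizontal diffusivity 1 m² s⁻¹
  (a plausible sub-100-m-scale coastal value; configurable);
* optional first-order decay, **off by default**: the ~18-day seawater
  half-life is slow next to dilution over the simulated week;
* stability enforced, not assumed: max(|u|,|v|)·Δt/Δx ≤ 1 and
  D·Δt/Δx² ≤ 0.25, violations raise naming the offending ratio;
* boundaries: zero-gradient outflow by default; closed (zero-flux) for
  conservation checks, where the flux form conserves mass to rounding.

Default run: 12×12 km at Δx = 50 m, Δt = 120 s, 7 days, hourly snapshots;
seven pens deloused sequentially 12 h apart (3 days of releases) at
2000 ng L⁻¹ over 10 m depth. Per-pen volume defaults to 19 286 m³ so the
seven releases sum to ≈270 g of active ingredient, matching a documented
full-site treatment. Releases are instantaneous (tarpaulin lifted), the
simplest defensible profile. Test-suite runs use coarser grids
(Δx = 100 m, 40–80 cells per side, ≤1.5 simulated days) purely to keep the
suite quick; the numerics are resolution-checked against closed forms
(discrete heat kernel within 2% L2 of the 2-D Gaussian after 100 steps;
unit-Courant advection is exact translation).

## Synthetic currents

Velocity = residual drift + rotating tidal ellipse + AR(1) gusts,
spatially uniform (the domain is small against coastal current scales).
Defaults: residual (5, 0) cm s⁻¹, tidal amplitude 8 cm s⁻¹ at the M2
period (12.42 h), gust sd 1.5 cm s⁻¹ with a 30-min decorrelation time —
instantaneous speeds stay within the 0–20 cm s⁻¹ band reported for exposed
farm sites in ≥99% of samples, and currents "vary and change direction"
over a deployment. What this does **not** emulate: bathymetric steering,
vertical shear and stratification, wind events, spatial eddies. Passing
tests therefore demonstrate correct *mechanics* (conservation, dilution,
threshold logic) and plausible magnitudes, not site-specific plume
geometry — real-site numbers require real current fields through the same
interfaces.

## Impact metrics

Areas count full cells above threshold (no sub-cell interpolation);
`contour_polygons` (marching squares on a sub-threshold-padded field, so
edge-touching plumes close) provides the smooth alternative, and the two
agree within a contour-perimeter cell ring. Extent is the farthest
exceeding cell centre from the release point. Sediment margins divide the
reference (PNEC 0.33, LC50 16 ng g⁻¹ dw) by the measurement; censored
values propagate as "≤ LOD" upper bounds — giving *lower* bounds on the
margin, flagged as censored — never as LOD/2 substitutions. Alpha Max
strength is fixed at 10 g active ingredient per litre, back-derived from
paired volume↔mass figures (27 L ↔ 270 g; 17.5 L ↔ 175 g), overridable.

## Effects analysis

The unit of analysis is genuinely ambiguous (tanks are the randomized
unit, shrimp the observational one), so both are reported: the primary
test pools shrimp across tanks into a 2×2 dead/alive table and computes
the two-sided Fisher exact p by full hypergeometric enumeration (all
tables no more probable than the observed); the alternative permutes tank
labels and compares pooled-mortality differences. The lethal threshold is
the lowest dose with p < α and positive excess mortality, α = 0.05 by
default with a strict 0.005 mode. Excess mortality is the absolute
difference in proportions versus control. Under a shared nonzero baseline
mortality at all doses (0.1 per shrimp), the threshold rule's simulated
false-declaration rate over 10 000 replicates stays ≤ 6% at α = 0.05 —
the discrete exact test is conservative; a zero-mortality null is vacuous
for this check because every table is degenerate.

## Synthetic data: what it fixes and what it cannot

Generators draw from a single study seed fanned out per generator
(CRC-tagged `SeedSequence` spawns), so any stage can be regenerated alone;
everything is bit-reproducible under a fixed seed. Mortality uses the
four-dose design (0, 0.0008, 0.04, 2 ng L⁻¹; 5 tanks × 8 shrimp; three 1-h
pulses; 14 recovery days) with mortality only at the top dose (0.8 per
shrimp). PRC/cosolvent noise is multiplicative (lognormal) — analytical
chemistry noise is scale-proportional. Sediment deposition is an
exponential-with-distance median (decay length 250 m, peak 7×10⁻⁴ ng g⁻¹
per g used — chosen so a 270 g treatment yields detected grabs in the
0.03–0.19 ng g⁻¹ dw band out to ~500 m) with lognormal patchiness
(σ = 0.2) and LOD censoring at 0.02 ng g⁻¹ dw; no real deposition model
stands behind it, it exists to exercise censoring and margin logic.

## Numerical conventions and limitations

Ties in reported rounding go half-away-from-zero. Degenerate inputs raise
typed errors (insufficient calibration points, fully dissipated PRCs,
releases off-grid, CFL violations) rather than returning NaN. Known
limitations: no 3-D water column or sediment–water exchange during
transport; spatially uniform currents; instantaneous releases; the
exact-test pooling treats shrimp within a tank as independent; the
cosolvent model is deliberately the simple linear one.
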
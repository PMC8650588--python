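# Methods

## The system

A closed hydroponic unit: one well-mixed nutrient tank (default
V0 = 0.3 m³) feeding `n_plants` (default 84) plants of one species over
a 54-day cultivation (t = 0 at transplanting).  Six macronutrient ions
are tracked — NO₃⁻, H₂PO₄⁻, SO₄²⁻ (anions) and K⁺, Ca²⁺, Mg²⁺
(cations) — with absolute valences (1, 1, 2, 1, 2, 2).  The state is
water volume V (m³) and per-ion nutrient mass M (mol):

    dV/dt = Q_in − n·Q_trs
    dM/dt = Q_in·C_in − n·J(C),        C = M/V

Transpired water carries no nutrients, so concentration rises whenever
transpiration outpaces uptake.  We integrate *mass*, not concentration:
the commonly written shorthand V·dC/dt = Q_in·C_in − J drops the
C·dV/dt dilution term and does not conserve mass; it is kept as
`ode_form="concentration_literal"` for comparison only (its uptake ledger is
not maintained).

### Plant submodels

* Root length: logistic, P_RL = Rmax / (1 + K1·e^(−k1·t)); root surface
  area P_RSA = 2π·r0·P_RL (smooth-cylinder assumption).
* Leaf area index: Boltzmann sigmoid, LAI = a_LAI / (1 + e^((x0−t)/b_LAI)).
* Uptake: Michaelis–Menten per ion, J^I = P_RSA·Jmax^I·C^I/(Km^I + C^I)
  (mol h⁻¹ plant⁻¹).  Jmax in mol m⁻² h⁻¹; Km in mol m⁻³ (the
  dimensionally consistent choice).
* Transpiration: reduced Penman–Monteith (Baille form),
  Q_trs = a_trs·(1 − e^(−k_ext·LAI))·K⁺ + b_trs·LAI·VPD, with K⁺ the
  shortwave irradiance (W m⁻²) and VPD in kPa.  A flag moves VPD inside
  the exponent for comparison with the alternative printed form.

### Integrator

Explicit fixed-step RK4 (default dt = 0.1 h; ensemble work uses 0.5–1 h,
where RK4's O(dt⁴) error is far below every tolerance used).  Dosing and
replacement are instantaneous events at grid times; the dosing interval
must be a grid multiple.  Cumulative per-plant uptake and transpiration
are accumulated with the same RK4 stage weights as the state, so the
mass- and water-balance residuals of any run are at machine precision
(~1e-15; the acceptance bound is 1e-6).  Negative masses from overshoot
are clipped to zero with the clipped amount charged back to the uptake
ledger; clipping beyond 1% of initial mass aborts the run (it signals a
too-large dt).  A dry tank (V ≤ 0) aborts with a diagnostic.

The batch integrator (`integrate_batch`) carries a leading replicate
axis so a 50-replicate weather ensemble is one vectorised run.

## Environment

*Controlled room* (used for estimation, mirroring the growth-room
experiment): square-wave 14 h light / 10 h dark; PPFD 120 µmol m⁻² s⁻¹
converted to irradiance by k_conv = 4.6 µmol J⁻¹ (warm-white source
class; configurable); day 23 °C / 60% RH, night 20 °C / 73% RH converted
to VPD via the Tetens curve es(T) = 0.6108·e^(17.27T/(T+237.3)) kPa,
giving 1.124 kPa (day) and 0.631 kPa (night).

*Stochastic weather* (used for the dosing analysis): Kasten–Czeplak
clear-sky irradiance scale·max(0, A·sin h − B), A = 910, B = 30 W m⁻²,
on standard solar-declination geometry (default latitude 37.8°, day
172), attenuated by total cloud cover N as (1 − 0.75·(N/8)^3.4).
N moves as a Gaussian random walk reflected into [0, 8] okta
(0.5 okta·h^−½); VPD as an independent reflected walk in [0.5, 2.0] kPa
(0.05 kPa·h^−½).  Increments scale with √dt so trajectories are
grid-refinement consistent, and reflection (rather than clamping)
avoids boundary sticking.  Because the plants are calibrated to a dim
growth room, clear-sky irradiance is scaled down (default 0.05);
`calibrate_irradiance_scale` solves the linear matching problem so the
stochastic-weather mean transpiration equals the controlled-room mean
(the calibrated value for the default pakchoi-like preset is ≈0.056).

## Dosing controllers

All three run on a fixed interval (default 24 h) and never remove
solution (emission-free).  EC is carried as total ionic equivalent
concentration Σ|z|·C (eq m⁻³ ≡ meq L⁻¹); a display conversion of
0.1 dS m⁻¹ per meq L⁻¹ is provided for reporting only.

* volume: top up to V0 with the standard feed — nutrient input tracks
  the stochastic water draw.
* time: a fixed nutrient dose per event.  Water is topped to V0 by
  default (`top_up_water`): the controllers differ in nutrient logic,
  water-level control being common to a working system — with a literal
  fixed water dose the replicate volume trajectories diverge and the
  method loses exactly the reproducibility that distinguishes it.  The
  default fixed dose is calibrated so cumulative dosed equivalents match
  an EC+volume reference run (input-matched comparisons).
* ec_volume: restore total equivalents to V0·EC0 exactly (the feed sets
  only the ratio; additions are scaled on the equivalent scale) and top
  water to V0.

## Estimation

Weekly closed-tank depletion records (N/W bookkeeping: per-plant uptake
(C_i·V_i − C_f·V_f)/n; transpiration (V_i − V_f)/n) feed a two-stage
progress-curve fit minimising the RMSE of weekly *accumulated*
quantities:

1. a_trs, b_trs, a_LAI, b_LAI, x0 against accumulated transpiration
   (transpiration is independent of tank nutrient state);
2. per-ion (Jmax, Km) against accumulated uptake with stage-1 frozen,
   each ion an independent 2-parameter problem given the volume
   trajectory.

Root geometry (Rmax, K1, k1, r0) is treated as known (destructive
measurement): only P_RSA·Jmax is identifiable from depletion data.
The optimiser is multi-start Nelder–Mead in log-parameter space
(Latin-hypercube starts plus the bounds midpoint; deterministic per
seed).  Default bounds are broad except Km ∈ [0.05, 2.0] mol m⁻³: the
transporter half-saturation range; an uninformative Km ceiling leaves
the Jmax–Km ridge unconstrained and Jmax unidentifiable whenever the
tank concentration stays well above Km.  A per-ion flatness probe
(double Km, rescale Jmax to match uptake at the mean concentration; if
the RMSE barely moves the ion is flagged `km_flat`) reports weak Km
identifiability instead of silently returning a bound.

## Synthetic data

Stand-ins for the undeposited raw measurements.  Three species presets
ordered pakchoi > lacinato > curly in Jmax and transpiration
coefficients (capacity scales 1.0 / 0.8 / 0.65), with sulfate the
exception (higher in both kales), and NO₃ the largest Jmax in every
preset.  Magnitudes are synthetic, sized so that (a) weekly per-plant
transpiration is 1e-4–1e-3 m³ and the tank never runs dry, and (b)
late-season weekly depletion is a clearly measurable 10–40% of the fill
per ion — a depletion experiment whose signal resolves uptake, matching
the order of magnitude of the reported accumulated-quantity RMSEs.

Weekly fresh fills are Gaussian draws around (7.5, 3.0, 2.5, 4.0, 1.9,
1.4) mol m⁻³ with SDs (1.0, 1.4, 1.1, 0.4, 0.4, 0.2) — 26.1 eq m⁻³ in
the mean, Steiner-proportioned — floored at 5% of the mean.  Measurement
noise: each recorded concentration is the mean of 3 repeated assays at
3% relative sd (the analytical protocol averaged triplicates); volumes
get 1% relative sd, with the final volume kept ≤ the initial (water only
leaves by transpiration).  Ground-truth sampling applies a seeded,
damped log-normal jitter (10%) to Jmax that preserves the cross-species
ordering.

What the generator does **not** emulate: ion interactions and
electro-neutral co-uptake, pH- or temperature-dependent kinetics,
root-zone heterogeneity, efflux, microbial consumption, and any
biomass feedback on parameters.  Passing recovery tests therefore show
the estimator is correct *under the model*, not that the model captures
every feature of real measurements.

## Reproducibility metrics and optimization

%CV across replicates is computed per ion at each output time (t = 0
excluded) and averaged over time; n = 50 replicates by default.  The
dose-rate signature statistics classify an event series as constant
(%CV < 1%), increasing (Kendall τ > 0.5 and increment noise-to-trend
ratio < 1), or irregular; the noise-to-trend ratio — std of increments
over |mean increment| — separates a jagged weather-tracking series from
a smooth growth-tracking one even when both rise.  Signatures are
evaluated per replicate, never on the ensemble mean (averaging erases
the jitter being detected).

The composition deviation objective converts concentration trajectories
to percentage molar ratios within each charge group (molar basis by
default; an equivalent-basis switch exists since the historical standard
ratios are equivalent-based) and takes the RMS deviation from the
standard ratio over hourly samples, ions, and a fixed weather seed set
(default 5; configurable to mean-absolute or final-time).  The search
runs Nelder–Mead on softmax coordinates of the two 3-simplices
(non-negativity and 100% sums by construction), multi-start with the
standard ratio always included, so the reported optimum is never worse
than the baseline.  Absolute feeds are electroneutral by construction:
each charge group carries half the feed EC.

## Problem sizes used in the shipped checks

Accuracy checks use the full 54-day horizon at dt = 0.5–1 h; the
recovery study uses 10 synthetic campaigns (8 weeks, dt = 1 h) with
4-start fits; the dosing comparison uses 50 replicates; optimization
checks use 240–336 h scenarios with 1–2 weather seeds, where the
deviation signal is already well resolved.  These sizes were chosen so
the whole suite runs comfortably on one CPU.

## Known limitations

* Jmax recovery at the default noise is accurate in aggregate (median
  ≈18% over seeds × ions) but SO₄ and Mg individually exceed 25% —
  their weekly signals are the smallest relative to assay noise and the
  Km ridge is widest for low-concentration divalents.  `km_flat` flags
  the affected ions.
* The time-based controller's drift relative to EC+volume dosing is
  modest when its dose is input-matched; the paper-style "overall
  decrease" grows as the dosing interval or the capacity mismatch grows.
* The stochastic weather generator is a driver for reproducibility
  analysis, not a meteorological model (no energy balance, no humidity
  feedback).
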
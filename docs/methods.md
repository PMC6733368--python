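# Methods

`fbgtwin` is a digital twin of a batch fluid-bed granulation (FBG)
process. It predicts the time course of granule moisture — loss-on-drying
(LOD), in percent of wet mass — and the bed, chamber-air and wall
temperatures, and wraps that simulator in the industrial workflow built
around it: calibration against batch LOD samples with RMSE acceptance
gates, scenario-based input-variability ("risk fingerprint") analysis,
and quasi-Monte-Carlo propagation of parameter uncertainty.

## The model

The granulator is described as two perfectly mixed compartments. The
*bed* holds all solids (the dry charge `m_bed_s`, constant, plus the
binder solids `m_bed_b` deposited by the spray) and the liquid water
`m_bed_w`. The *chamber air* holds a fixed dry-air mass `m_air` and the
water vapor `m_air_w`. A thermal wall exchanges heat with both
compartments and the environment. Six states are integrated:

```
dm_bed_w/dt = (1 - w_s) F_spray - m_evap
dm_bed_b/dt = w_s F_spray
dm_air_w/dt = F_air (x_in - x) + m_evap ,   x = m_air_w / m_air

C_bed  dT_bed/dt  = H_spray - H_evap - Q_bed,wall - Q_bed,air
                    - (T_bed - T0)(dm_bed_w/dt cp_wl + dm_bed_b/dt cp_b)
C_air  dT_air/dt  = H_air,in - H_air,out + H_evap + Q_bed,air - Q_air,wall
                    - (T_air - T0) dm_air_w/dt cp_wg
C_wall dT_wall/dt = Q_bed,wall + Q_air,wall - Q_wall,env
```

with `C_bed = m_bed_s cp_s + m_bed_w cp_wl + m_bed_b cp_b`,
`C_air = m_air cp_a + m_air_w cp_wg`, `C_wall = m_wall cp_steel`.
`w_s` is the binder solids weight fraction, `x_in`/`x` the inlet/outlet
(= chamber) air mixing ratios, and the trailing terms account for the
time-varying heat capacity of each compartment. Stream enthalpies `H`
are sensible heats relative to the reference `T0`; `H_evap` carries the
latent heat `lambda0` plus the vapor sensible heat from bed to air.
Heat-transfer terms are lumped constant-conductance closures
`Q_x,y = UA_xy (T_x - T_y)`; radiation and geometry-resolved convection
are deliberately absorbed into the `UA` constants, with the global
energy-closure property (below) as the consistency arbiter.

### Evaporation

The core closure, and the home of the two product-specific parameters:

```
m_evap = k(theta_e, theta_p) * A_p(theta_p) * (c_w,sat(T_bed) - c_w)
A_p    = 6 m_solid / (rho_particle * theta_p)        # monodisperse spheres
k      = k0(theta_p) * eta,   k0 = Sh * D_w / theta_p
Sh     = 2 + 0.6 Re^(1/2) Sc^(1/3)                   # Ranz–Marshall
eta    = min(exp(LOD / theta_e) - 1, 1)              # drying efficiency
```

`c_w,sat` is the saturation concentration at the (wet) particle surface,
taken at the bed temperature via a Buck/Magnus-form saturation-pressure
curve and the ideal-gas law; `c_w = m_air_w / V_chamber` is the chamber
concentration. Evaporation is floored at zero: condensation is outside
the model's drying-dominated scope, and a dry bed (`eta = 0` at LOD = 0)
cannot evaporate. `theta_p` is an *effective* particle size: it sets
both the transfer area and the Reynolds/Sherwood scale, is assumed
monodisperse and time-invariant, and in practice absorbs the (small)
wetted/active fraction of the idealized sphere area — fitted values are
therefore much larger than a sieved granule size. `theta_e` (in LOD %)
sets how quickly mass transfer shuts down as the bed dries. Setpoint
biases of the spray and air mass-flow meters are absorbed by per-product
linear correction factors `F_i = alpha_i F_i_set`, default 1, fitted
only on demand and then frozen for the product.

### Numerics

Setpoints are piecewise constant per recipe phase; the solver (LSODA,
`rtol 1e-8`, `atol` 1e-10 on masses and 1e-8 on temperatures) restarts at
each phase boundary with the state carried over, so boundaries are exact
grid points. The chamber vapor state relaxes within seconds against
phase-scale dynamics — the system is stiff by construction and a
non-stiff solver is impractical. A typical 70-minute pilot recipe
integrates in ~30 ms. With `track_balances=True` the solver
co-integrates the net water inflow, the net stream enthalpy and the
evaporated mass, making two conservation residuals solver-accurate
rather than output-grid-quadrature-limited:

* water: `Δ(m_bed_w + m_air_w) = ∫ [F_spray(1-w_s) + F_air(x_in - x)] dt`
  (relative residual ~1e-16, tested < 1e-6 of throughput);
* energy: the sensible enthalpy accumulated by bed + air + wall equals
  `∫ (H_spray + H_air,in - H_air,out - Q_wall,env) dt` (relative residual
  ~1e-8, tested < 1e-4).

## Calibration

`(theta_p, theta_e)` — optionally with the two `alpha` factors — are
estimated by bounded trust-region nonlinear least squares on
log-parameters, pooling residuals between simulated and measured LOD at
the recorded sampling times over all training batches. Five candidate
starts with log-spaced `theta_p` are screened by objective value and the
best two polished, so adding starts can never worsen the fit. Finite
difference steps for the Jacobian are fixed at 1e-4 in log-space —
comfortably above the ODE-solver noise floor; with solver-default steps
the optimizer stalls on spurious gradient noise near the optimum. The
parameter covariance is the Gauss-Newton estimate `s^2 (J^T J)^{-1}` in
natural parameter space (`s^2` the residual variance), which is what the
uncertainty module consumes. Sampling-time uncertainty is not modelled
in the objective; it is exercised through the synthetic generator's time
jitter instead.

Fit quality is gated on the RMSE in LOD percent: 0.279 for calibration
and 0.664 for validation/verification. These thresholds come from a
historical multi-product study (mean historical error plus two standard
deviations) and are treated as configurable constants — this package
does not re-derive them. The cross-validation workflow runs three
exercises: (a) train on batch A, predict batch B; (b) the reverse; (c)
train on A + B, predict the independent pilot batch C (validation) and
the commercial-scale batch D (verification).

## Input-variability analysis

Three process parameters can deviate — inlet air temperature, inlet air
flow rate, spray rate — with magnitudes expressed in units of one
per-parameter "typical standard deviation" (`sigma_T_in` 1 °C,
`sigma_F_air` 0.01 kg/s, `sigma_F_spray` 4e-4 kg/s at pilot scale).
Coordinated deviations are either *wet* (spray up, temperature and air
flow down — all pushing the maximum LOD up) or *dry* (the negation).
Inlet humidity is treated as an environmental level, not a deviated
parameter: every scenario is run at 1, 5 and 10 g/kg. Four scenario
sets are enumerated:

| set | pattern | magnitude |
|-----|---------|-----------|
| I   | every nonempty parameter subset × every nonempty spray-subphase subset | fixed 2σ |
| II  | one parameter × one subphase | searched 1..30σ |
| III | six 5-min pulses across the spray phase, 1–3 parameters | searched 1..20σ |
| IV  | one parameter, whole spray phase | searched 1..20σ |

Set I is summarized as the fraction of runs whose maximum LOD leaves the
design space, per *deviation score* = (#parameters) × (#subphases
affected); pulse scenarios score the number of parameters. Score
non-monotonicity is reported as-is — it is a genuine warning sign for
sensitive products. Sets II–IV report the maximum tolerable deviation
σ\*: the ascending integer grid is scanned and the magnitude before the
first out-of-range point returned (0 if the first fails; the capped grid
top if none fail); an undisturbed run already outside the design space
yields a flagged result rather than an error, since exactly this happens
for sensitive products at extreme humidity. Subphase subsets in set I
are unrestricted (not only contiguous blocks), and set III pulses are
spaced uniformly over the spray phase with deterministic offsets. A
`center_recipe` helper rescales the spray rate (durations inversely, so
total binder solution is conserved) to put the maximum LOD at the
design-space center.

## Parameter-uncertainty propagation

The multivariate Normal defined by the estimate and its covariance is
sampled with a scrambled Sobol sequence (inverse-Normal transform
through the covariance matrix square root; a fixed scramble seed keeps
runs reproducible, and plain Sobol is available). Samples with any
non-positive component are unphysical and removed; the set is topped up
with the next Sobol points until at least the requested count — never
fewer than 500 — remains. Every retained sample is simulated and
pointwise empirical quantiles (central 95% by default; the coverage is a
configuration choice) form the band. Convergence is the largest
pointwise envelope change between the bands built from the two halves of
the sample set; the default tolerance is 0.1 LOD%, the scale of the LOD
assay noise, below which band changes are immaterial.

The *overall* band combines input variability and parameter uncertainty
in the two-step screening procedure: simulate all configured
input-variability scenarios at the point estimate, pick the input sets
giving the highest and lowest maximum LOD, propagate the parameter band
for the nominal and both extremes, and envelope the three bands
pointwise. The screening is heuristic — no guarantee exists that an
intermediate input set is not more extreme — and the band metadata
records that caveat; no brute-force cross-product is run by default.

## Synthetic data

No public granulation batch data exist, so fixtures are generated by the
twin itself from known ground truth. The standard pilot recipe charges
60 kg (commercial: 216 kg, flows scaled linearly, exchange areas by the
2/3 power): 5 min premix, five 6-min spray subphases at 0.010 kg/s
binder solution (8% solids), two 15-min drying subphases at 70 °C.
Wet/target/dry condition variants scale the spray rate ±10% at constant
total binder. Batches carry `Normal(0, 0.1 LOD%)` measurement noise and
`Normal(0, 30 s)` recorded-time jitter, the two error sources that
dominate real records; the sampling plan pulls 2 premix, 5 spray and 4
drying samples.

Ground truth is `theta_p = 12 mm`, `theta_e = 5 LOD%`, `alpha = 1`.
The effective size was chosen so that bed-side transfer resistance is
comparable to the air-side moisture-removal capacity
(`F_air V / m_air` ≈ 0.3 m³/s against `k0 A_p η` of the same order).
At a sieve-scale size (hundreds of µm) the spec'd closures give
`k0 A_p η` three orders of magnitude larger, the chamber saturates
instantly, drying is purely air-limited, and the LOD trace carries no
`theta_p` information — calibration would be a degenerate exercise. The
chosen regime keeps single-batch recovery at 0.1 LOD% noise
well-conditioned (Gauss-Newton relative sd ≈ 2.5% for `theta_p`, ≈ 10%
for `theta_e`).

Two product archetypes mirror the industrial case studies. The *robust*
product uses the default ground truth and a wide design space spanning
the extreme coordinated 2σ wet/dry deviations at the extreme humidities
(plus 0.3 LOD% buffer); every set-I scenario stays inside it. The
*sensitive* product is a fine, well-wetted formulation (`theta_p = 2 mm`)
whose evaporation is air-capacity-limited and hence strongly
humidity-coupled; its design space is the wet/dry batch-maxima range at
target humidity, and the 1 and 10 g/kg extremes fall outside it with no
deviation at all.

### What the generator does and does not emulate

It reproduces the structure of real campaigns — multi-phase recipes,
scale transfer, assay noise, sampling-time jitter, humidity seasons —
but not: equilibrium (bound) moisture, so simulated beds dry toward 0%
LOD where real powders plateau near their ambient equilibrium;
particle-size evolution and its effect on transfer area; spray-zone
inhomogeneity; drifting (rather than stepwise) setpoints; or assay-bias
differences between LOD instruments. Passing tests therefore
demonstrate the correctness and internal consistency of the workflow on
model-generated data, not predictive accuracy for any real formulation.

## Problem sizes used in the test and acceptance runs

Conservation is checked on 20 randomized recipes; parameter recovery on
20 seeded single-batch fits; σ\*-search correctness against exhaustive
grid simulation on 12-point grids; uncertainty convergence at 512 vs
1024 Sobol samples and the overall band at 512 samples per constituent.
These sizes give stable statistics while keeping a full run of the suite
in the minutes range on one core.

## Known limitations

* The appendix-level heat-transfer correlations of the original
  equipment are not public; constant-`UA` closures stand in for them, so
  absolute temperature trajectories are only as good as the lumped
  conductances supplied in the equipment table.
* `theta_p` and `theta_e` are correlated through the drying tail; at
  high noise or sparse drying-phase sampling the single-batch estimate
  can slide along that ridge even though the fitted trace (and thus the
  RMSE gates) remain good.
* Condensation is floored away; recipes that would condense (cold bed,
  very humid inlet) are outside the model's validity.
* Disturbances act on setpoints only; phase durations are never
  disturbed.
* The design space is an interval on maximum LOD only; no other quality
  attribute is modelled.
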
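# Methods

## Model and assumptions

`soilleach` simulates the concentration of a pesticide in the solid phase
(mg/kg dry soil) and the soil solution (mg/L) of a stack of homogeneous
soil layers on a daily time step. The design trades mechanism for
measurability: there is no water-flow or solute-transport PDE. Instead,

- **instantaneous linear sorption**: on entry to a layer, a fixed fraction
  f_ads of the compound binds to the solid phase. This is justified when
  the measured adsorption percentage is insensitive to the initial
  concentration (near-linear isotherms), which is exactly the regime the
  batch assays are meant to verify;
- **first-order degradation in both phases at the same rate** k. The rate
  is a per-layer laboratory incubation value; degradation in solution is
  assumed equal to degradation on solids, which field column data support
  to within the half-life uncertainty;
- **daily desorption of a fixed fraction** f_des of the (decayed) solid
  pool, driven by the daily irrigation input;
- **advective routing by conservative-tracer travel time**: desorbed mass
  stays in a layer's own solution until the day a conservative tracer
  (bromide, RF = 1) is first detected at the layer's bottom boundary; from
  that day on, the day's desorbed flux (mg/kg × ρ_b = mg/L) becomes the
  daily aqueous input of the layer below, where it is re-partitioned by
  that layer's f_ads. Steady-state flow makes the arrival days constants
  of the site rather than outputs of a flow model;
- **linearity**: every update is linear in concentration, so trajectories
  scale exactly with dose and superpose across applications. The simulator
  is fully deterministic.

Because exponentials compose (e^(−kt) = (e^(−k))^t), the uniform one-day
stepping is exact for the pure-decay parts of the recursion, not a
discretisation approximation.

### Regime hand-off and boundary conventions

The switch between "desorbed mass feeds the layer's own water" and
"desorbed mass leaves to the layer below" happens at the tracer arrival day
at that layer's bottom boundary, uniformly for every layer. With the field
arrival day of 1 at the first boundary, the topsoil aqueous phase reduces
to pure first-order decay of its running reference concentration, which is
reset (decayed remnant + new input) at each application. For the deepest
layer, `tracer_arrival_day=None` keeps desorbed mass in-layer; when an
arrival day is supplied, flux past that day leaves the modelled profile and
is not tracked (groundwater is out of scope).

The solid-phase recursion adds new input (application or routed flux)
*after* decay and desorption of the previous day's pool, so the input of a
given day is not decayed or desorbed on that day. Its third displayed line
in the source literature is self-referential; the implementation uses the
previous-day pool, matching the pattern of the first two lines. The
"application" term is added only on application days (topsoil) or as the
routed daily input (subsurface) — adding it every day would grow without
bound from a single dose.

Layers are half-open depth intervals [top, bottom) in metres, positive
downward. Soil-route and foliar-route events on the same day are processed
soil-first (an arbitrary but documented order; totals are unaffected
because updates are additive).

### Total concentration

The reported total is mass-consistent: `total = c_solid + c_aqueous / ρ_b`
(mg/kg), so that partitioning followed by totalling is the identity. The
raw sum `c_solid + c_aqueous`, which mixes units, is available via
`SimulationResult.total_at(..., convention="raw_sum")` for comparison with
plots that do not state their convention.

### Constant-flux mode

Field practice sometimes assumes desorption is constant over time. With
`flux_mode="constant"` each receiving layer's daily input is frozen at the
flux value of its first delivery day; the default (`"time-varying"`)
routes the actual daily desorbed flux. The constant mode also provides the
geometric-series closed form I/(1 − e^(−k)) used as a convergence check.

## Parameter estimation

**Isotherms.** The linear fit is least squares through the origin (the
isotherm has no intercept); its R² is computed against the zero-intercept
model (total sum of squares about zero), recorded in the fit metadata. An
unconstrained mode exists for diagnostics. The Freundlich fit is nonlinear
least squares on the untransformed model, initialised from the log–log
linearisation; a pure log–log mode is selectable. Untransformed NLS is the
default because log transforms reweight errors toward the low-concentration
tail.

**Single-point desorption.** The pellet retains pore solution at the
adsorption equilibrium concentration; this carryover is assumed fully
mixed with the fresh background electrolyte before the desorption shake,
and its dissolved mass is credited before computing the mass released from
the solid. Negative computed desorption percentages (noise) are clamped to
0 with a logged warning.

**Kinetics.** C(t) = C0·e^(−kt) is fitted by untransformed NLS with k ≥ 0
(zero and near-LOQ concentrations break log transforms; a log-linear mode
is available). Below-LOQ values are excluded, not substituted, and logged.
The reported p-value is an F-test of the exponential model against the
constant-mean model (1 numerator degree of freedom): it measures evidence
of *decay*, so a flat series of any level gives a large p-value. R² is
computed about the mean and clipped to [0, 1].

**Speciation.** For a weak base the protonated (cationic) fraction is
1/(1 + 10^(pH − pKa)); the weak-acid branch returns the complementary
dissociated share.

## Calibration

The objective is the mean of squared simulated-observed differences over
matched (layer, day) pairs, in mg²/kg². Observations are matched to
same-day simulator output with no interpolation (sampling days must be
simulated days); below-LOQ records are excluded and counted. Calibration
is an exhaustive grid sweep over any of {p_dp_soil, p_dp_foliar, f_soil,
per-layer k}: deterministic, auditable, with first-in-grid-order
tie-breaking, and a failed grid point is flagged rather than fatal.
Gradient methods are deliberately avoided — the MSE surface over a
handful of physically bounded parameters is cheap to enumerate and the
sweep doubles as a sensitivity table.

## Synthetic data

The generators are exact forward models of the package's own equations
plus seeded noise. Multiplicative lognormal noise is the default for
concentrations (strictly positive data); identical seeds reproduce
identical tables. The batch-assay generator solves the implicit mass
balance c_eq + K_y·c_eq^n·(m/V) = c_init by bisection (the left side is
strictly increasing in c_eq), to 1e-10 or better; defaults mirror the
standard design of 10 g dry soil in a 20 mL aliquot, with five initial
levels spanning half to seven times a field dose. Incubation series
default to sampling days (0, 1, 3, 7, 14, 31, 45, 60, 76, 102) and 10 %
relative noise, consistent with the R² range of published incubation fits;
assay noise defaults used in the recovery studies are 2–5 %. Field
campaigns sample the simulator's totals on the requested days, add noise,
and flag below-LOQ values as censored.

What the generators do *not* emulate: within-layer heterogeneity,
preferential flow, rainfall/irrigation stochasticity, analytical recovery
bias, or plant uptake. Passing recovery tests therefore show that the
estimation and calibration machinery is correct and well-conditioned under
the stated noise model — not that the model captures every field process;
field MSEs are expected to exceed the synthetic ones.

## Problem sizes and numerical choices

The recovery studies use 5-level assays over 100 seeds, 10-point
incubation series over 200 seeds, and a 3×3 calibration grid over a
365-day, 5-layer campaign — sizes chosen to estimate medians and coverage
stably while keeping the full suite in the seconds range. Bisection
tolerances are 1e-14 (absolute) in the assay mass balance; optimiser
starts come from the linearised fits; tie-breaks and degenerate inputs
(single-layer profiles, one-point grids, all-censored campaigns) are
defined behaviours with tests rather than errors.

## Known limitations

- No transient flow, runoff, volatilisation, plant uptake or
  preferential-flow pathways; the tracer-time routing subsumes all
  transport.
- Degradation rates measured in the laboratory tend to understate field
  dissipation; calibrating per-layer k against field data (the provided
  grid axis) is the intended remedy.
- Sorption is a fixed fraction, not a concentration-dependent isotherm,
  inside the simulator; the Freundlich machinery exists to *verify* that
  the fixed-fraction approximation is acceptable for a given data set.
- The desorption fraction is applied to the decayed pool daily; multi-step
  desorption isotherms and biphasic kinetics are out of scope.
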
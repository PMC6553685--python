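# Methods

## Model overview

`socioclim` couples two well-studied minimal models through a two-way
feedback:

1. **Behaviour.** A well-mixed population holds one of two strategies,
   *mitigator* or *non-mitigator*. Individuals sample others at a social
   learning rate κ (1/yr) and imitate the higher-payoff strategy with
   probability proportional to the payoff difference, which yields the
   replicator equation

       dx/dt = κ x (1 − x) [ −β + f(T_f) + δ (2x − 1) ],

   where x is the mitigator fraction, β the net cost of mitigating (cost of
   mitigation minus the levy on non-mitigation), δ the utility bonus for
   conforming to the majority, and f the perceived cost of climate change,

       f(T) = f_max / (1 + e^{−ω (T − T_c)}),

   a sigmoid with ceiling f_max, steepness ω and midpoint T_c. The cost is
   evaluated not at the current anomaly but at a linear extrapolation of the
   recent trend,

       T_f(t) = T(t) + (t_f / t_p) [ T(t) − T(t − t_p) ],

   i.e. the last t_p years extrapolated t_f years forward. This makes the
   system a delay differential equation with a single discrete delay t_p.
   Internally the reduced parameters (β, f_max) are authoritative; a
   constructor from the raw utility parameters (α, γ, c, f̃_max) enforces
   β = α − γ and f_max = (c + 1) f̃_max, and the test suite verifies that the
   reduced replicator equals the net switching rate built from the raw
   utilities.

2. **Earth system.** A four-pool carbon cycle (atmosphere, vegetation, soil,
   ocean; all state variables are deviations from pre-industrial values, in
   GtC) plus a zero-dimensional energy balance. Atmospheric carbon obeys

       dC_at/dt = ε(t) (1 − x) − P + R_veg + R_so − F_oc,

   so the anthropogenic emission rate ε(t) is scaled by the non-mitigating
   fraction — this is the only place behaviour touches the climate, and the
   rising anomaly feeding the cost sigmoid is the only place climate touches
   behaviour.

## Earth-system functional forms

The flux forms are standard reduced-complexity choices, parameterised so the
pre-industrial (all-zero deviation) state is an **exact** fixed point by
construction:

- **Photosynthesis** P = P₀ · (C_v/C_v⁰) · cap(C_v) · MM(pCO₂) · (1 + a_P T),
  with Michaelis–Menten CO₂ fertilisation MM normalised to 1 at 280 ppm
  (half-saturation k_half = 300 ppm) and a linear carrying-capacity factor
  cap(C_v) = (K − C_v)/(K − C_v⁰) that makes the land sink self-limiting
  (without it, any persistent fertilisation grows vegetation without bound,
  because respiration and litterfall scale with the same pool).
- **Respiration** R_veg, R_so: first order in their pool with Q10
  temperature response (Q10 = 2.0 vegetation, 2.2 soil) — the warming-driven
  carbon-cycle feedback.
- **Litterfall** L: first order in vegetation, closing the land loop
  (P − R_veg − L into vegetation, L − R_so into soil).
- **Ocean uptake** F_oc = k_oc (pCO₂_atm − pCO₂_oc), with ocean pCO₂ rising
  with ocean carbon content through a Revelle buffer factor (12.5) and with
  temperature through a solubility term (3.5 %/°C). The flux goes into an
  explicit ocean pool, so the carbon-conservation test is exact: the sum of
  all pool derivatives equals ε(t)(1 − x).
- **Energy balance**, run on absolute temperature T_abs = T_pre + T:

      c dT_abs/dt = F_d − σ T_abs⁴   (per unit area),

  with F_d = (S/4)(1 − a) + A₀ + B ln(pCO₂/pCO₂⁰) + w·T. The printed form of
  the temperature equation applies σT⁴ to a deviation variable; only the
  absolute form is physical, so we integrate the absolute temperature and
  report the deviation. A₀ is calibrated against a *reference* solar flux so
  the pre-industrial state is an exact radiative equilibrium; varying the
  solar parameter away from the reference then acts as a genuine forcing
  (otherwise recalibration would silently cancel it). B = 5.35 W/m² is the
  standard logarithmic CO₂ forcing coefficient; the linear term w·T stands
  for fast feedbacks (water vapour, lapse rate). With the bare σT⁴ restoring
  term the equilibrium climate sensitivity would be ≈ 0.7 °C per doubling,
  far below any CMIP-consistent value; w = 4.13 W/m²/K sets it to ≈ 3 °C.
  Earth's surface area is folded out by per-area bookkeeping with one
  effective areal heat capacity.

## Calibration of the defaults

Pool sizes and pre-industrial fluxes are textbook values (550/1500/38000 GtC;
photosynthesis 120, plant respiration 60 GtC/yr). Three transient constants —
ocean exchange k_oc, vegetation capacity K and areal heat capacity c — were
calibrated once so that the 1800–2014 spin-up forced with the stylised
historical emission record reproduces the observed 2014 state: 397 ppm CO₂,
anomaly 0.92 °C, cumulative land uptake ≈ 205 GtC and ocean uptake ≈ 160 GtC
(k_oc = 0.035 GtC/yr/ppm, K = 1300 GtC, c = 1.4 × 10⁹ J/K/m², i.e. an
effective thermal lag of roughly 35 years). This mirrors how the underlying
reduced Earth-system modelling tradition fixes its constants — against
historical carbon and temperature trends — and it is done once, against
observations, not against any test outcome. Forced with RCP-style emission
pathways the climate core gives 2100 anomalies of ≈ 1.6 / 2.2 / 2.7 / 3.3 °C
for the RCP 2.6 / 4.5 / 6.0 / 8.5 shapes: correctly ordered, RCP 2.6 below
2 °C, RCP 8.5 somewhat below the CMIP5 mean (the single-feedback energy
balance has no slow feedbacks).

## Emission forcing

ε(t) interpolates the annual historical series linearly up to 2014, then
follows ε_2014 + (t − 2014) ε_max / ((t − 2014) + s): continuous at 2014,
monotone, saturating at ε_2014 + ε_max (defaults ε_max = 15 GtC/yr, s = 50 yr,
chosen so the no-mitigation pathway resembles a high-emission RCP 8.5-style
future). The packaged default historical series is *stylised*: monotone-cubic
interpolation through decadal anchor values of global fossil + land-use
emissions (cumulative ≈ 580 GtC over 1800–2014, matching the published
total). A CDIAC-style CSV reader is provided for the real record, including
least-squares linear extrapolation (20-year window, configurable) of a
land-use column that ends before the fossil column, and a parametric
seeded generator produces fully synthetic monotone histories for tests.

## Simulation protocol

- **Spin-up 1800–2014**: all climate deviations start at exactly zero; the
  social component is frozen and the emission term enters un-scaled
  (equivalently x = 0), so the full historical record forces the carbon
  cycle. The spin-up also provides the initial history function for the
  delay.
- **Coupled phase 2014 onward**: x is reset to x0 = 0.05 (an accepted state
  reset) and the full delay system is integrated by the **method of steps**:
  chunks of length t_p, with T(t − t_p) served from the dense solution
  already accumulated. Within each chunk the system is a plain ODE solved
  with LSODA (rtol 1e−8, atol 1e−10 defaults); x is clamped to [0, 1] at
  chunk boundaries to absorb floating drift at the replicator's invariant
  boundaries. Halving the tolerances moves the baseline peak anomaly by
  well under 0.01 °C.
- **Peak anomaly**: coarse scan of the dense output (4 samples/yr) followed
  by bounded scalar refinement. The default window is [1800, 2200]; the
  simulation end year is a declared convention (two centuries past the
  behaviour start), exposed in the config.

## Experiments

- **Ensembles**: every distributed parameter is drawn from a triangular
  distribution peaking at its baseline; summaries are pointwise medians with
  95% percentile bands (2.5/97.5), which is our concrete reading of
  "confidence intervals" for an ensemble. Realisation seeds are spawned from
  the master seed, so results do not depend on execution order; the
  historical spin-up is recomputed per realisation because climate and
  forcing parameters are among the sampled set.
- **Tornado**: one deterministic run per parameter per bound, all others at
  baseline; lower- and upper-bound deviations are reported separately
  because the response is strongly asymmetric; rows ordered by maximum
  absolute impact.
- **Contour / steepest descent**: peak anomaly on a (β, κ) grid; the descent
  path follows the negative gradient of a bivariate spline interpolant with
  axes rescaled to [0, 1] — the metric that makes "steepest" comparable
  across parameters with different units is a documented convention — with
  unit-normalised steps, stopping at the hull or when the gradient norm
  vanishes.
- **Horizon sweep**: ensembles with the forecast horizon t_f pinned per
  value (t_f = 0, decisions on the current anomaly only, is legal).
- **Presets**: `worst` (κ=0.02, β=1.5, δ=1.5, f_max=4, x0=0.01) and `best`
  (κ=0.2, β=0.5, δ=0.5, f_max=6, t_f=50) — the bounds that most/least favour
  non-mitigative behaviour.

## Parameter table

Baselines and triangular bounds ship in `socioclim/data/baseline.yaml`.
Social parameters are speculative by nature and get wide bounds:
κ ∈ [0.02, 0.2] (mode 0.05 — behaviour change on a generational timescale),
β ∈ [0.5, 1.5], δ ∈ [0.5, 1.5], f_max ∈ [4, 6] (mode 5: perceived climate
cost is allowed to dominate the net mitigation cost, consistent with
cost-of-inaction arguments), ω = 3 /°C, T_c = 2.5 °C, t_p = 10 yr,
t_f = 25 yr (bounds ±10 yr), x0 = 0.05. Climate bounds are ±20% on the
transient-response constants and ±0.5% on the solar parameter.

## What the synthetic data do and do not show

The stylised emission record reproduces the level, shape and cumulative
total of the historical series but not year-to-year variability (wars,
recessions); nothing in the model responds to interannual wiggles, so
conclusions are insensitive to this. The RCP-style series are stylised
decadal shapes for ordering checks, not the published tables. Passing tests
therefore demonstrate the mechanisms — norm entrenchment, learning-rate
dependence, horizon dependence, the coupled solar non-monotonicity — under
realistic forcing magnitudes, not quantitative agreement with any specific
historical dataset.

## Numerical and degenerate-input notes

- The cost sigmoid is evaluated with `scipy.special.expit` (no overflow).
- ω → 0 makes f ≈ f_max/2 regardless of temperature; this limit is used to
  recover the logistic closed form in tests.
- κ = 0 freezes behaviour exactly; x0 ∈ {0, 1} are invariant boundary
  equilibria and integrate to themselves.
- Degenerate triangular distributions (lower = mode = upper) are legal and
  always return the mode.
- The emission saturating branch uses a guarded denominator so vectorised
  evaluation never divides by zero.
- A vegetation pool driven above its carrying capacity gets zero
  photosynthesis (floor), never a negative flux.

## Known limitations

Homogeneous, well-mixed population (no heterogeneity, networks or
hierarchy); linear temperature extrapolation only; single-feedback energy
balance (no ice-albedo or slow feedbacks, so high-forcing anomalies are
conservative); reduced ocean without circulation; CO₂ only. The absolute
numbers depend on the stylised forcing and the calibrated defaults; the
qualitative structure (which the test suite checks) does not.
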
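# Methods

## Minimal ecosystem model

The model is dY/dt = a − bY + r·f(Y) with f(Y) = Yᵖ/(Yᵖ + hᵖ): a scalar
state promoted by a driver *a*, decaying at rate *b*, and replacing itself
at rate *r* through a sigmoidal feedback whose steepness *p* is the
feedback strength. All analyses use the reference configuration
b = r = h = 1 unless stated; parameters are in inverse unit-time (b, r),
state units (h), and dimensionless (p).

**Forcing.** The driver moves piecewise-linearly from `a_low` to `a_high`
and back over `total_steps` unit timesteps (`down_first` starts at the
top). Integration is classical fixed-step RK4 with 10 substeps per unit
time and the driver evaluated continuously at the RK nodes; halving the
substep changes a fast strong-feedback trajectory by < 1e−6 (tested), so
results are integrator-insensitive at this resolution. States are clipped
at 0, which only matters transiently at the absorbing boundary Y = 0.
The initial state is "auto": the lowest stable equilibrium at the starting
driver value, so an up-sweep starts on the lower branch and a down-first
sweep on the branch stable at `a_high`.

**f at p = 0.** 0⁰ is taken as 1, i.e. f ≡ 1/2 for p = 0 at every Y —
the continuous limit in Y > 0 — making the p = 0 system the linear ODE
dY/dt = a + 1/2 − Y. For large p, f is evaluated through the ratio
(Y/h)ᵖ on whichever side of 1 is numerically safe.

**Equilibria.** At fixed driver, roots of g(Y) = a − bY + r f(Y) are found
on [0, (a+r)/b + 1] by a 10⁴-point sign scan refined with Brent's method
to |g| < 1e−10; stability is the sign of g′, with a one-sided flow check
when |g′| < 1e−8 (this classifies the semi-stable origin at a = 0, p = 1
correctly as attracting from the admissible side).

**Bistable driver interval.** Multiple equilibria exist exactly where the
equilibrium curve a(Y) = bY − r f(Y) is non-monotone, so the fold driver
values are computed from the critical points of a(Y) (dense scan of
a′(Y) = b − r f′(Y) plus Brent refinement). A scan over driver values
cannot do this job: near the critical exponent the bistable window
narrows like (p − p\*)^(3/2) and slips between any driver grid points,
which would bias the detected onset upward by ~0.1. The fold-based scan
agrees with the closed form to 3e−5.

**Critical feedback exponent.** For b = r = h = 1, bistability first
appears when max_Y f′(Y) = 1; the maximizer satisfies Yᵖ = (p−1)/(p+1),
giving the closed-form condition
((p−1)/(p+1))^((p−1)/p)·(p+1)²/(4p) = 1 solved on (2, 10); the root is
p\* = 3.7174, and the tangency driver 0.50 lies inside [0, 1], so the
in-range onset coincides with the tangency. The general-parameter path
bisects the fold-scan predicate instead.

## Response statistics

**Nonlinearity** is the RMS difference between the fitted values of an
ordinary least-squares line and of a penalized cubic regression spline,
computed per forcing phase on unstandardized data, hence in state units
(an absolute, not relative, measure). The smoother uses a cubic B-spline
basis of dimension 10 (reduced automatically when fewer distinct driver
values exist) on uniform knots spanning the data, the exact
∫s″(x)² dx curvature penalty (2-point Gauss per knot interval, exact for
the piecewise-quadratic integrand), and smoothing chosen by minimizing
GCV(λ) = n·RSS/(n − edf)² over an 81-point grid of λ ∈ [1e−8, 1e8]. The
penalty null space is exactly the straight lines, so noise-free affine
data yield zero nonlinearity for every λ; both statistics are therefore
shift-invariant and positively homogeneous (up to the λ-grid resolution,
since GCV reselects on rescaled data). Basis dimension and λ are exposed
as options.

**Hysteresis** is the mean absolute difference between ascending- and
descending-phase states paired at equal driver values. Pairing averages
within-phase repeats of a driver level first, then exact-matches common
levels, excluding the two extreme levels of the path (the peak is visited
once; the start/end level pairs a fresh initial condition with a relaxed
final one and is dropped for symmetry). When no interior exact matches
exist — as in the stepped temperature schedule, whose ascending levels
15.7, 16.4, … interleave the descending ones — the descending path is
linearly interpolated onto the ascending levels strictly interior to its
range, giving one pair per level below the plateau. Exact matching is the
default dialect; interpolation is the fallback.

For the microcosm schedule the phase split is the schedule midpoint:
sampling days ≤ 33 are ascending, later days descending, so the 25 °C
plateau week is shared between phases and its repeated measurements are
averaged within each phase before pairing.

## Feedback-strength sweep

`run_sweep` crosses p ∈ {0, 0.5, …, 10} (grid configurable) with ramp
lengths {200, 20 000} and forcing directions, computing both statistics
per cell plus the maximum stable-equilibrium count over the swept driver
range (driver grid of 101 values plus the midpoint of the detected
bistable interval, so windows narrower than the grid spacing are still
counted). All p values at one rate are integrated jointly as a vector of
independent scalar ODEs sharing the driver, which keeps the slow ramp
cheap; results are identical regardless of evaluation order (tested).

## Synthetic microcosm experiment

The generator emulates a 67-day experiment: 5 gas-exchange treatments ×
6 replicates, sampled every 2 days (34 samples per jar), under the
stepped temperature protocol above. State per jar: liquid and headspace
oxygen on the optode sensor scale (21 = equilibrium with the atmosphere),
bacteria (cells/ml), two ciliate prey pools and one predator (ind/ml).
Dynamics are Euler–Maruyama with dt = 0.05 day:

- bacteria grow logistically (r_B = 2/day, K_B = 5e6/ml) and are grazed
  by prey feeding on a saturating term B/(B + 2e6);
- prey grow at r_N = 1.1/day times Gaussian thermal performance (optima
  24 and 26 °C, width 6) times a shared crowding factor (1 − N/1500),
  die at 0.08/day, and are eaten by predators with a Holling type-II
  response (attack 42 prey/predator/day, half-saturation 300 prey/ml);
- predation is multiplied by a Hill-2 oxygen limitation O²/(O² + 20²):
  hypoxia shelters prey. The predator converts intake with efficiency
  0.03, dies at 0.11/day, has thermal optimum 19 °C (below the prey
  optima, so warming favors prey), and survives starvation as a cyst
  pool that re-emerges at 1 ind/ml once prey exceed 200/ml;
- community respiration (4e−8, 8e−3, 2e−2 %O₂/day per bacterium, prey,
  predator at 15 °C) scales with Q10 = 2 and Michaelis factor
  O/(O + 1), draining liquid oxygen; liquid and headspace relax toward
  each other at 4/day (headspace capacity ≈ 3.3× the liquid's); the
  headspace relaxes toward 21 at 30/day when open and at a 0.06/day leak
  otherwise; the pulsed treatments additionally refresh 0.8/0.5/0.3 of
  the headspace (and half that fraction of the liquid, via bubbling)
  toward atmospheric every 2 days (200/100/50 ml into a ~150 ml
  headspace);
- multiplicative lognormal environmental noise (σ = 0.15/√day) perturbs
  all four biotic pools each step; extinction floors (10³ bacteria,
  1 prey, 0.2 predators per ml) are absorbing except for the predator's
  cyst pool.

Observation adds lognormal noise (σ = 0.08) to densities, draws 10
individuals' (width, length) per species from species-specific normals,
and reports total biomass as Σ density × mean ellipsoid biovolume
(4/3)π(w/2)²(ℓ/2) of that sample's draws (oxygen is reported without
noise — optode precision is high relative to the dynamics). Each jar has
an independent RNG substream keyed by (seed, treatment, replicate), so
the table is byte-identical across runs and adding replicates never
perturbs existing ones.

**Emergent regimes.** The oxygen limitation of predation creates a
positive feedback: if prey escape the mid-experiment predation bottleneck,
their respiration drives the jar hypoxic, which disables the predator and
locks the community in a persistent low-oxygen regime; if they do not,
the predator starves after the prey collapse and oxygen recovers
(functional extinction). In the open jar continuous exchange keeps oxygen
high, so escapes are re-crashed by re-emerging predators and the low-DO
regime is essentially absent; the weaker the exchange, the lower the
bottleneck oxygen and the likelier the escape. The generator records each
jar's realized regime — hidden from the observed table's noise — as
`regime = low_do` iff the latent liquid oxygen falls below 8 %O₂ at any
sampled day from day 10 on (bimodal under the defaults: persistent jars
reach < 4, extinct ones stay > 10). Under the defaults, 20 seeds give
low-DO frequencies ≈ 0 / 0.12 / 0.13 / 0.25 / 0.90 from open to closed.

All biological values are choices made once to produce this qualitative
phenomenology — divergent within-treatment fates, treatment-graded regime
frequencies, similar warming-phase dynamics everywhere — not estimates of
any real system. Accordingly, passing tests show that the analysis
pipeline recovers structure of this kind when it is present; they say
nothing about effect sizes in real microcosms, and the generator omits
real-data features such as measurement dropout, species-specific oxygen
tolerances, volume loss from sampling (~1%/event), and non-Gaussian
morphology.

## Regime analysis

Per-series standardization (mean 0, sd 1; constant series map to zeros)
precedes DTW by default — a flag, since shape rather than level then
drives the clustering. DTW is the classic unconstrained dynamic program
with absolute local cost and symmetric steps; an optional Sakoe–Chiba
band is off by default. Hierarchical clustering applies the Ward
criterion to squared DTW distances (the modern dialect; the plain-distance
dialect is a flag), cut at k = 2 per the two-regime hypothesis (k is an
option). Because DTW violates the triangle inequality, the "Ward on a
non-Euclidean dissimilarity" step is a heuristic, as in standard practice.
Cluster 1 is anchored to the cluster with the higher mean series level for
oxygen (lower for biomass), making labels reproducible; the two
clusterings combine to codes A = (1,1), B = (2,1), C = (2,2), with the
residual combination reported as "other".

The cluster–treatment association uses the likelihood-ratio test of a
logistic regression on the treatment factor; with a single categorical
predictor the group-saturated Bernoulli likelihood is closed-form
(0·log 0 ≡ 0), deviance = 2(ℓ_group − ℓ_null), df = levels − 1, χ²
p-value. Metric group comparisons use one-way ANOVA, or an additive
two-factor linear model (treatment + cluster) with type-II F tests —
equivalent to nested residual-sum-of-squares comparisons; the
treatment × cluster interaction is fitted only on request.

## Problem sizes and numerical choices

Default analyses use ramps of 200 and 20 000 steps, a 21-point p grid,
30-jar experiments, and 20-seed replication for distributional claims —
sizes at which every documented behavior is stable under seed changes.
Tolerances: root refinement 1e−10, fold location 1e−14 in Y, critical-
exponent scan 1e−4, GCV grid 81 points per fit. Degenerate inputs
(constant drivers, constant series, aliased factors, single treatment
levels, empty phases) raise informative errors rather than guessing.

## Known limitations

- The smoother mirrors "default GAM fit" behavior but is not
  bit-compatible with any particular GAM implementation; nonlinearity
  values agree with an unpenalized spline oracle to ~1e−7 on smooth data
  but can differ in the third decimal from other smoother dialects.
- DTW+Ward labels at k = 2 are only meaningful when two regimes actually
  exist; with a single regime the cut is arbitrary (anchoring keeps it
  deterministic).
- The microcosm generator is one mechanistic story (oxygen-limited
  predation) among those compatible with the qualitative phenomenology;
  it is a test harness, not an inference target.
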
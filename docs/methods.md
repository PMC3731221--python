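# Methods

## Model class and assumptions

The framework targets ODE models of the form

    dx/dt = S · f(x, θ, u),   x(0) = x0,   y = g(x, θ, u)

with strictly positive kinetic parameters θ, a fixed stoichiometry S and
output functions g mapping states (and fluxes) onto measured
observables. Three assumptions carry the whole procedure:

1. **Steady state before treatment.** The untreated phenotype is a
   steady state of the model; `x0` is never a free quantity but the
   steady state implied by the baseline parameters.
2. **Progressive adaptation.** Treatment-induced regulation is slow and
   smooth relative to the step size; highly fluctuating parameter
   trajectories are considered unphysiological and are penalized.
3. **Undermodeling is absorbed into θ(t).** Regulatory interactions that
   the model does not describe mechanistically are represented as
   time-dependence of the kinetic parameters. A parameter trajectory is
   therefore a *description of required change*, not a mechanistic
   estimate of any single molecular quantity.

Within a step, parameters are piecewise-constant; nothing in the data
(snapshots days apart) could distinguish sub-step parameter shapes.

## Data interpolants

Snapshot series (time, mean, SD) per observable are turned into
continuous targets `d(t)` by cubic smoothing splines minimizing

    p · Σ_i w_i (y_i − f(t_i))² + (1 − p) · ∫ f''(t)² dt

with inverse-variance weights normalized to mean one (so `p` keeps a
consistent meaning across observables and scales). For fewer than five
points the same objective is solved directly in the natural-spline basis
(Green–Silverman form). Monte Carlo replicates redraw every snapshot
mean from N(mean, SD) — the *replicate* SD, matching how cross-sectional
phenotype snapshots scatter — and refit the spline; positive observables
clamp draws at a small floor rather than resampling (resampling would
bias the mean upward). The SD envelope `σ(t)` is piecewise-linear in the
measured SDs, floored at `max(σ_abs, σ_rel·|d(t)|)`, and is built once
from the original (un-resampled) SDs.

**Smoothing default `p = 0.01`.** Because resampling uses the replicate
SD (≈10% in the benchmark), raw interpolants wiggle by that amount
between design days. A mid-range `p` lets the stepwise estimator chase
this noise into the parameter trajectories; `p = 0.01` (penalty
`λ = (1−p)/p = 99` on the normalized-weight scale) suppresses it while
leaving week-scale treatment trends intact — with seven design points
over 21 days, a genuine monotone drift survives heavy smoothing, while
day-to-day noise does not. `p` is per-run configurable, and
generalized cross-validation can be had by calling scipy's
`make_smoothing_spline` with `lam=None` where automatic selection is
preferred.

## Baseline collection

Multistart weighted least squares on the steady-state misfit
`Σ_j ((y_j^ss − d_j(0))/σ_j(0))²`, optimized over log-parameters
(positivity by construction) with a trust-region reflective solver.
Starts draw log-uniformly from `nominal · 10^[−3, 3]` by default
(configurable), and each start pairs with a different interpolant draw.
Far-off starts that fail to reach the misfit gate simply lower the
acceptance rate; that is the intended filtering role of the multistart.
Acceptance: cost ≤ χ²(0.95, dof = number of observables), overridable by
an absolute threshold. The accepted collection deliberately keeps the
non-identifiability spread — e.g. parameters constrained only through
ratios or products populate the corresponding manifold — because that
spread is exactly the prediction uncertainty the ensemble propagates.

## Stepwise estimation

At step n the candidate θ advances the state from the stored end state
of step n−1 over `[t_{n−1}, t_n]`; the objective is the weighted output
misfit at the step endpoint (substep averaging available) plus

    λ₁ · Σ_i ((θ_i[n] − θ_i[n−1]) / (Δt · ref_i))²

with `ref = θ̂₀` (the member's own baseline) by default. Normalizing by
the baseline gives every parameter the same *relative* scale and keeps
the penalty interpretable as a squared relative rate of change per day;
normalizing by `θ[n−1]` (provided as `previous_step` mode) makes the
penalty scale drift along the trajectory, which slightly favors
parameters that have already moved. Optimization is warm-started at
`θ[n−1]` in log space, so with uninformative data the regularization
pins parameters exactly.

**Regularization default `λ₁ = 10`.** Chosen (together with the
smoothing default, on the synthetic benchmark) as the smallest
magnitude that keeps constant-truth trajectories flat to well under 20%
drift while leaving the treatment response essentially unbiased — the
"minimal bias" philosophy: the λ₁-grid trade-off (roughness falls,
misfit rises monotonically in λ₁) is shallow below 10 for these noise
levels. Both knobs are run-configuration, not hard-coded.

Trajectory acceptance: total data cost ≤ χ²(0.95, dof = N_ts · n_obs),
and no flagged (non-converged) steps. `N_ts = 50` over a 21-day horizon
is the default; doubling it changes ensemble-median outputs by less than
the inter-member spread.

## Time-constant falsification

The control re-fit with a single constant θ applies the same
steady-state assumption to the constant model: each candidate starts in
its *own* steady state, so (without external inputs) it predicts a flat
response. This is the hypothesis actually being falsified — "the
phenotype did not adapt" — and on the treatment benchmark its best cost
is several-fold the stepwise ensemble median. Initializing the constant
model away from its steady state would instead test "one relaxation
transient explains the data", a different (and weaker) claim.

## MPSA

At each time step, members are classified acceptable iff the chosen
output lies strictly below the ensemble mean (ties go to unacceptable;
the KS distance is label-swap invariant, so the convention is cosmetic
but fixed for reproducibility). The sensitivity of a quantity is
`K = sup|S_a − S_u|` over the quantity-sorted cumulative class
fractions, evaluated at the upper edge of tied-value groups so ties
never split a CDF step. `K` is rank-based: invariant under strictly
monotone transforms of the quantity. Significance uses the asymptotic
two-sample critical value `c(α)·sqrt((n_a+n_u)/(n_a·n_u))`,
`c(α) = sqrt(−ln(α/2)/2)` — adequate at the ensemble sizes the pipeline
produces (tens to thousands); exact small-sample tables are not
implemented. Batching (default without replacement when the ensemble is
large enough; with replacement otherwise, recorded in provenance) gives
a per-step spread on K. Steps where one class is empty (e.g. an exactly
conserved output) are reported as K = 0 with a degenerate flag, never
dropped silently.

## Trajectory analytics

Rise/fall periods follow the control-theoretic 10–90% convention:
trajectories are segmented at interior extrema (with a relative
prominence filter, default 1% of the global range, to ignore
noise-spawned segments), and crossing times of the low/high fractions
of each monotone segment's span are located by linear interpolation.
Ensemble summaries report median ± median absolute deviation of the
dominant event per member, with members lacking an event counted, not
imputed. Densities are per-step histograms over globally shared bins;
envelopes are pointwise empirical quantiles at `(1 ± coverage)/2`
(default coverage 0.95) — a pointwise band, not a joint one.

## Intervention design

Per member and step, the target parameter is found by root-solving the
held output onto the member's own t = 0 setpoint (Brent's method when
the residual brackets zero across the parameter bounds, bounded scalar
minimization otherwise), with all other parameters frozen to their
original trajectories. A flat search objective raises an explicit
"no influence" error. Steps whose achieved relative residual exceeds
the tolerance are flagged and reported, never hidden. Using each
member's own baseline as setpoint (rather than an ensemble average)
keeps every modified trajectory self-consistent with its own untreated
phenotype.

## Synthetic benchmark

A linear three-pool mass-transfer model (hepatic x1, plasma x2,
peripheral x3; production k1 → x1, secretion k2·x1, peripheral uptake
k3·x2, peripheral efflux k4·x3, hepatic clearance k5·x2, excretion
k6·x1; outputs: the three pools and the excretion flux) emulates the
structure of a multi-compartment metabolic study: snapshots at days
0, 1, 2, 4, 7, 14, 21; eight replicates per time point; Gaussian noise
with CV 0.1. Scenario "constant" holds all rate constants at nominal
(k = 1, 0.8, 0.5, 0.3, 0.4, 0.5); scenario "treatment" raises k4 along
an anchored logistic to 2× nominal (midpoint day 3, width 1 day — the
anchoring makes θ_true(0) exactly nominal so the steady-state invariant
holds) and lowers k5 exponentially to 0.5× nominal with a 7-day time
constant. The ground-truth drift is integrated directly (the solver
sees θ_true(t)), decoupling the truth from any estimation grid.

What the benchmark does *not* emulate: nonlinear (saturable) kinetics,
composition/size observables, non-Gaussian noise, missing design days,
inter-animal variance structure beyond an SD, or model misspecification
(the fitted model class contains the truth). Passing tests therefore
demonstrate that the estimation machinery recovers directional,
timescale and sensitivity structure under the stated noise — not that
any real dataset is equally benign. Linearity is deliberate: steady
states, identifiability manifolds and conservation properties are
analytically checkable.

## Numerical choices

- Integration: LSODA, rtol 1e-8 / atol 1e-10 for user-facing
  simulation; 1e-7 / 1e-9 inside per-step optimization loops (the
  misfit tolerance dominates there). States below −atol abort with an
  error; no silent clipping.
- Steady states: hybrid-Newton root of `S·f = 0`, falling back to
  relaxation integration with doubling horizons until
  ‖dx/dt‖/‖x‖ < 1e-9; divergence and non-convergence are distinguished
  in the error.
- All optimization in log-parameter space with bound constraints
  inherited from the model (default nominal × 10^±6).
- Determinism: every pipeline stage is a pure function of its inputs
  and a `numpy.random.Generator` seed; two runs with the same
  configuration and seed are bit-identical.
- Problem sizes in the shipped tests and the acceptance script
  (ensembles of 10–30 members, N_ts = 50, 8–10 members for the
  falsification and intervention sub-studies) were chosen to exercise
  the full pipeline at the benchmark's study scale while keeping a
  complete run in the minutes range on one core.

## Known limitations

- Piecewise-constant θ within a step; no sub-step interpolation.
- No global single-shot optimization of all N_ts × n_params parameters
  (a complementary approach for small models).
- Uniform time grids only.
- The χ²-based acceptance thresholds treat residuals as independent
  Gaussians, which smoothing-spline targets only approximate.
- Single-parameter interventions; no simultaneous multi-target or
  optimal-control formulation.
- No SBML/CellML import; models are specified programmatically.
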
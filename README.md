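# adapt-ode

**ADAPT** — Analysis of Dynamic Adaptations in Parameter Trajectories — is a
framework for estimating *time-varying* parameters of an ODE model from
longitudinal phenotype-snapshot data, and for analyzing the resulting
trajectory ensembles.

## The problem

Long-term pharmacological interventions (or disease progression) modulate
metabolic networks through regulatory layers — proteome, transcriptome —
for which mechanistic equations are rarely available. A kinetic model of
the metabolic level alone is therefore *undermodeled*: its rate constants
cannot stay constant while the system transitions between phenotypes.
Given cross-sectional snapshots (means ± SDs of metabolite concentrations
and fluxes at a handful of treatment days), ADAPT infers which model
parameters *must* change in time, in which direction and on which
timescale, to connect the snapshots.

## The method

The model is `dx/dt = S·f(x, θ, u)`, `y = g(x, θ, u)` with stoichiometry
`S`, kinetic fluxes `f`, outputs `y`, parameters `θ` and optional inputs
`u`.

1. **Data interpolants.** Cubic smoothing splines `d(t)` are fitted
   through the snapshot means; a Monte Carlo collection is built by
   resampling each snapshot from `N(mean, SD)` and refitting, propagating
   data uncertainty into everything downstream. The SD envelope `σ(t)` is
   interpolated between measurement times.
2. **Untreated baseline.** Before treatment the system is assumed to be
   in steady state. Multistart weighted least squares on
   `Σ_j ((y_j^ss − d_j(0))/σ_j(0))²` yields a collection `Θ₀` of parameter
   sets describing the untreated phenotype (including its
   non-identifiability spread).
3. **Stepwise trajectory estimation.** The horizon `[0, T]` is divided
   into `N_ts` uniform steps. At each step, starting from the previous
   end state, `θ[n]` is re-estimated by minimizing the data misfit plus a
   regularization term
   `λ₁·Σ_i ((θ_i[n] − θ_i[n−1])/(Δt·θ̂₀_i))²`
   that makes parameter change costly — parameters move only when the
   data demand it. Repeating over `Θ₀` × interpolant draws gives a
   trajectory *ensemble* whose spread quantifies prediction uncertainty.
4. **Analysis.** Rise/fall periods (10–90% traversal of monotone
   segments), trajectory density histograms with central quantile
   envelopes, relative adaptations normalized to the untreated level, and
   time-resolved multi-parametric sensitivity analysis: at each time step,
   ensemble members are classified by comparing an output of interest
   against its ensemble mean, and each quantity is scored by the
   Kolmogorov–Smirnov distance `K = sup|S_a − S_u|` between the
   parameter distributions of the two classes, with an asymptotic
   two-sample critical value at significance α.
5. **Intervention design.** A single target parameter is re-estimated
   step by step (all others frozen to their trajectories) so a chosen
   output holds its untreated level; side effects on the other outputs
   are quantified against the original ensemble.

A linear three-compartment benchmark (hepatic, plasma and peripheral
pools) with known ground-truth parameter drifts is bundled, so every
stage is testable end to end without external data.

## Worked example

```python
import numpy as np
import adapt

model = adapt.make_toy_model()
scenario = adapt.make_scenario("treatment")      # k4 rises 2x, k5 falls to 0.5x
dataset = adapt.generate_dataset(scenario, np.random.default_rng(0))

config = adapt.TrajectoryConfig(n_steps=25, horizon=21.0)
ensemble = adapt.run_ensemble(model, dataset, config, 12, np.random.default_rng(1))
print(f"accepted {len(ensemble)}/{ensemble.n_attempted} trajectories")

table = adapt.recovery_metrics(ensemble, scenario)
print(table.to_string(index=False))
```

prints

```
accepted 12/12 trajectories
parameter  true_direction  sign_agreement    nrmse
       k1               0        0.166667 0.042872
       k2               0        0.083333 0.060617
       k3               0        0.000000 0.177249
       k4               1        1.000000 0.163511
       k5              -1        0.916667 0.109788
       k6               0        0.416667 0.047226
```

Nearly every ensemble member moves the peripheral-efflux constant `k4`
up and the hepatic clearance capacity `k5` down — the directions of the
true drifts — even though the baseline is structurally non-identifiable
(members spread along the unidentifiable `k2/k5` and `k3/k4` manifolds;
their *direction of change* is still consistent). Continuing,

```python
prof = adapt.timecourse_sensitivity(ensemble, "param:k5", "output:hepatic_pool")
print(f"time-averaged KS distance of k5 w.r.t. hepatic pool: {prof.mean_ks:.3f}")

result = adapt.design_hold_constant(model, ensemble, "k5", "hepatic_pool", 1e-3)
print(f"max tracking residual: {result.tracking_residuals.max():.2e}")
```

prints

```
time-averaged KS distance of k5 w.r.t. hepatic pool: 0.391
max tracking residual: 2.82e-08
```

i.e. the hepatic pool is sensitive to the clearance-capacity trajectory,
and re-estimating `k5` alone holds the hepatic pool at its untreated
level to near machine precision at every step.

A command-line interface mirrors the library (`adapt benchmark`,
`adapt run-adapt`, `adapt mpsa`, `adapt analyze`, `adapt intervene`,
`adapt fit-baseline`) driven by a YAML configuration; see
`adapt --help`.

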
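"""Parameterization of the untreated phenotype.

Before treatment onset the system is assumed to rest in steady state.
A collection of parameter sets Theta_0 describing that phenotype is
obtained by Monte Carlo multistart weighted least squares: each start
draws initial parameters log-uniformly over a wide range, pairs with a
different spline interpolant from the Monte Carlo collection, and
minimizes the weighted squared error between the steady-state model
outputs and the interpolants evaluated at t = 0,

    SSE(theta) = sum_j ((y_j^ss(theta) - d_j(0)) / sigma_j(0))^2.

The spread of the accepted collection expresses both data noise and
structural non-identifiability, which ADAPT deliberately propagates
into the trajectory ensemble rather than collapsing to a point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2

from .data import InterpolantSet
from .model import ModelSpec, SteadyStateError, find_steady_state

__all__ = ["BaselineMember", "BaselineCollection", "steady_state_cost", "fit_untreated"]


@dataclass(frozen=True)
class BaselineMember:
    params: np.ndarray
    x_ss: np.ndarray
    cost: float
    provenance: dict


@dataclass
class BaselineCollection:
    members: list[BaselineMember]
    threshold: float
    n_starts: int
    best_costs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def acceptance_rate(self) -> float:
        return len(self.members) / self.n_starts if self.n_starts else 0.0

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def _observables_on_model(model: ModelSpec, interp: InterpolantSet) -> list[str]:
    unknown = [o for o in interp.observables if o not in model.output_names]
    if unknown:
        raise KeyError(
            f"observables {unknown} have no matching model output "
            f"(outputs: {model.output_names})"
        )
    return list(interp.observables)


def steady_state_cost(
    model: ModelSpec,
    params: np.ndarray,
    interp: InterpolantSet,
    *,
    x_guess: np.ndarray | None = None,
) -> float:
    """Weighted SSE between steady-state outputs and interpolants at t=0.

    Returns ``inf`` when no steady state can be found for ``params`` (the
    infinite-cost sentinel lets multistart optimizers discard the draw).
    """
    obs = _observables_on_model(model, interp)
    if x_guess is None:
        x_guess = np.ones(model.n_states)
    try:
        x_ss = find_steady_state(model, params, x_guess)
    except SteadyStateError:
        return np.inf
    y = model.outputs(0.0, x_ss, np.asarray(params, dtype=float))
    cost = 0.0
    for name in obs:
        j = model.output_index(name)
        r = (y[j] - interp.value(name, 0.0)) / interp.sd(name, 0.0)
        cost += float(r) ** 2
    return cost


def fit_untreated(
    model: ModelSpec,
    interps: list[InterpolantSet],
    n_starts: int,
    init_range: tuple[float, float] = (-3.0, 3.0),
    rng: np.random.Generator | None = None,
    *,
    threshold: float | None = None,
    acceptance_quantile: float = 0.95,
    max_nfev: int = 200,
) -> BaselineCollection:
    """Monte Carlo multistart steady-state fit of the untreated phenotype.

    Initial parameters are drawn log-uniformly from
    ``nominal * 10**init_range`` and each start is paired with an
    interpolant set cycled from ``interps``. Optimization runs on
    log-parameters (positivity by construction) with a trust-region
    least-squares solver. A start is accepted when its cost does not
    exceed ``threshold`` (default: chi-square quantile with one degree of
    freedom per observable).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if not interps:
        raise ValueError("need at least one interpolant set")
    if rng is None:
        rng = np.random.default_rng()
    if model.nominal_params is None:
        raise ValueError("model needs nominal_params for initialization")

    obs = _observables_on_model(model, interps[0])
    n_obs = len(obs)
    if threshold is None:
        threshold = float(chi2.ppf(acceptance_quantile, df=n_obs))

    log_nominal = np.log(model.nominal_params)
    bounds = model.bounds()
    lb, ub = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    lo, hi = init_range
    if hi <= lo:
        raise ValueError("init_range must be increasing (low, high) exponents")

    members: list[BaselineMember] = []
    best_costs = np.full(n_starts, np.inf)
    for i in range(n_starts):
        interp = interps[i % len(interps)]
        z0 = np.clip(
            log_nominal + np.log(10.0) * rng.uniform(lo, hi, size=model.n_params),
            lb,
            ub,
        )
        state_cache = {"x": np.ones(model.n_states)}

        def residuals(z):
            theta = np.exp(z)
            try:
                x_ss = find_steady_state(model, theta, state_cache["x"])
            except SteadyStateError:
                return np.full(n_obs, 1e6)
            if np.all(x_ss > 0):
                state_cache["x"] = x_ss
            y = model.outputs(0.0, x_ss, theta)
            return np.array(
                [
                    (y[model.output_index(name)] - interp.value(name, 0.0))
                    / interp.sd(name, 0.0)
                    for name in obs
                ],
                dtype=float,
            )

        sol = least_squares(
            residuals, z0, bounds=(lb, ub), method="trf", max_nfev=max_nfev
        )
        cost = float(np.sum(sol.fun**2))
        best_costs[i] = cost
        if cost <= threshold:
            theta = np.exp(sol.x)
            try:
                x_ss = find_steady_state(model, theta, state_cache["x"])
            except SteadyStateError:
                continue
            members.append(
                BaselineMember(
                    params=theta,
                    x_ss=x_ss,
                    cost=cost,
                    provenance={"start_index": i, "interpolant": interp.provenance},
                )
            )
    if not members:
        raise RuntimeError(
            "no baseline fit met the acceptance threshold "
            f"({threshold:.3g}); best costs: {np.sort(best_costs)[:5]}"
        )
    return BaselineCollection(members, threshold, n_starts, best_costs)
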
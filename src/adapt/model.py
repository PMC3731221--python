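"""ODE model representation and simulation.

A model is a set of molecular species (states) ``x`` whose dynamics are
given by a stoichiometry matrix ``S`` acting on a vector of kinetic fluxes
``f(x, theta, u)``::

    dx/dt = S @ f(x, theta, u),    y = g(x, theta, u)

where ``theta`` are kinetic parameters and ``u`` optional external inputs.
Model outputs ``y`` map states (and fluxes) onto measured quantities.
Prior to a treatment intervention the system is assumed to rest in a
steady state, which anchors the untreated phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ModelSpec",
    "SimulationResult",
    "SimulationError",
    "SteadyStateError",
    "simulate",
    "find_steady_state",
]


class SimulationError(RuntimeError):
    """Numerical integration failed (stiffness, divergence, negative states).

    Carries the time at which integration broke down in ``failure_time``.
    """

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


class SteadyStateError(RuntimeError):
    """No steady state found. ``reason`` is 'divergence' or 'non-convergence'."""

    def __init__(self, message: str, reason: str = "non-convergence"):
        super().__init__(message)
        self.reason = reason


def _zero_input(t: float) -> np.ndarray:
    return np.empty(0)


@dataclass(frozen=True)
class ModelSpec:
    """Programmatic specification of an ODE model.

    Parameters are strictly positive by default (kinetic rate constants);
    per-parameter bounds are multiplicative around ``nominal_params`` unless
    given explicitly in ``param_bounds`` (absolute, shape ``(n_params, 2)``).
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    flux_names: tuple[str, ...]
    output_names: tuple[str, ...]
    stoichiometry: np.ndarray
    flux_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    output_fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    input_fn: Callable[[float], np.ndarray] = _zero_input
    nominal_params: np.ndarray | None = None
    param_bounds: np.ndarray | None = None
    positive_params: tuple[bool, ...] | None = None

    def __post_init__(self):
        S = np.asarray(self.stoichiometry, dtype=float)
        object.__setattr__(self, "stoichiometry", S)
        if S.shape != (self.n_states, self.n_fluxes):
            raise ValueError(
                f"stoichiometry shape {S.shape} does not match "
                f"({self.n_states} states, {self.n_fluxes} fluxes)"
            )
        if self.nominal_params is not None:
            object.__setattr__(
                self, "nominal_params", np.asarray(self.nominal_params, dtype=float)
            )
        if self.param_bounds is not None:
            pb = np.asarray(self.param_bounds, dtype=float)
            if pb.shape != (self.n_params, 2):
                raise ValueError("param_bounds must have shape (n_params, 2)")
            object.__setattr__(self, "param_bounds", pb)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_fluxes(self) -> int:
        return len(self.flux_names)

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    def bounds(self, spread: float = 1e6) -> np.ndarray:
        """Absolute parameter bounds; defaults to nominal / spread .. nominal * spread."""
        if self.param_bounds is not None:
            return self.param_bounds
        if self.nominal_params is None:
            raise ValueError("model has neither param_bounds nor nominal_params")
        return np.column_stack(
            [self.nominal_params / spread, self.nominal_params * spread]
        )

    def rhs(self, t: float, x: np.ndarray, params: np.ndarray) -> np.ndarray:
        u = self.input_fn(t)
        return self.stoichiometry @ self.flux_fn(x, params, u)

    def fluxes(self, t: float, x: np.ndarray, params: np.ndarray) -> np.ndarray:
        return np.asarray(self.flux_fn(x, params, self.input_fn(t)), dtype=float)

    def outputs(self, t: float, x: np.ndarray, params: np.ndarray) -> np.ndarray:
        return np.asarray(self.output_fn(x, params, self.input_fn(t)), dtype=float)

    def output_index(self, name: str) -> int:
        try:
            return self.output_names.index(name)
        except ValueError:
            raise KeyError(f"unknown output {name!r}; model outputs: {self.output_names}")


@dataclass
class SimulationResult:
    """Trajectories of states, fluxes and outputs on an evaluation grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    fluxes: np.ndarray  # (n_times, n_fluxes)
    outputs: np.ndarray  # (n_times, n_outputs)

    def __post_init__(self):
        for arr in (self.times, self.states, self.fluxes, self.outputs):
            if not np.all(np.isfinite(arr)):
                raise ValueError("simulation result contains non-finite values")
        n = len(self.times)
        if not (self.states.shape[0] == self.fluxes.shape[0] == self.outputs.shape[0] == n):
            raise ValueError("row counts disagree with time grid")


DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def simulate(
    model: ModelSpec,
    params: np.ndarray,
    x0: np.ndarray,
    t_start: float,
    t_end: float,
    eval_times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    params_fn: Callable[[float], np.ndarray] | None = None,
) -> SimulationResult:
    """Integrate the model over ``[t_start, t_end]`` and evaluate on a grid.

    ``params_fn`` optionally supplies time-varying parameters theta(t)
    (used by the synthetic benchmark to simulate ground-truth drifts);
    ``params`` is used for all times when it is None.

    Raises
    ------
    SimulationError
        On integrator failure or when states dip below ``-atol``
        (mass concentrations must stay non-negative).
    ValueError
        On malformed inputs or non-finite flux evaluations at ``x0``.
    """
    params = np.asarray(params, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    eval_times = np.asarray(eval_times, dtype=float)
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    if eval_times.size == 0:
        raise ValueError("eval_times is empty")
    if eval_times.min() < t_start - 1e-12 or eval_times.max() > t_end + 1e-12:
        raise ValueError("eval_times must lie within [t_start, t_end]")

    theta_of = params_fn if params_fn is not None else (lambda t: params)
    f0 = model.flux_fn(x0, theta_of(t_start), model.input_fn(t_start))
    if not np.all(np.isfinite(f0)):
        raise ValueError("flux function non-finite at initial state")

    def rhs(t, x):
        return model.stoichiometry @ model.flux_fn(x, theta_of(t), model.input_fn(t))

    sol = solve_ivp(
        rhs,
        (t_start, t_end),
        x0,
        method=method,
        t_eval=eval_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t_start
        raise SimulationError(
            f"integration failed at t={t_fail:.6g}: {sol.message}", failure_time=t_fail
        )
    states = sol.y.T
    if states.min(initial=0.0) < -atol:
        i, j = np.unravel_index(np.argmin(states), states.shape)
        raise SimulationError(
            f"state {model.state_names[j]!r} went negative "
            f"({states[i, j]:.3e}) at t={eval_times[i]:.6g}",
            failure_time=float(eval_times[i]),
        )
    fluxes = np.empty((len(eval_times), model.n_fluxes))
    outputs = np.empty((len(eval_times), model.n_outputs))
    for i, t in enumerate(eval_times):
        th = theta_of(t)
        fluxes[i] = model.fluxes(t, states[i], th)
        outputs[i] = model.outputs(t, states[i], th)
    return SimulationResult(eval_times, states, fluxes, outputs)


def find_steady_state(
    model: ModelSpec,
    params: np.ndarray,
    x_guess: np.ndarray,
    *,
    tol: float = 1e-10,
    max_horizon: float = 1e5,
) -> np.ndarray:
    """Solve ``S f(x, theta, u) = 0`` for a non-negative steady state.

    Newton-type root finding from ``x_guess``; if that fails or lands on a
    negative state, falls back to relaxation by long-horizon integration
    until ``||dx/dt|| / ||x||`` drops below 1e-9.
    """
    params = np.asarray(params, dtype=float)
    x_guess = np.asarray(x_guess, dtype=float)
    if np.any(x_guess <= 0):
        raise ValueError("x_guess must be strictly positive")

    def residual(x):
        return model.rhs(0.0, x, params)

    sol = root(residual, x_guess, method="hybr")
    if sol.success and np.all(sol.x >= -tol):
        x_ss = np.clip(sol.x, 0.0, None)
        if np.linalg.norm(residual(x_ss)) <= max(tol, 1e-8 * np.linalg.norm(params)):
            return x_ss

    # relaxation fallback: integrate in doubling horizons
    x = x_guess.copy()
    horizon, elapsed = 10.0, 0.0
    while elapsed < max_horizon:
        res = solve_ivp(
            lambda t, xx: model.rhs(t, xx, params),
            (0.0, horizon),
            x,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not res.success:
            raise SteadyStateError(
                f"integration failed while relaxing to steady state: {res.message}",
                reason="divergence",
            )
        x = res.y[:, -1]
        if not np.all(np.isfinite(x)) or np.linalg.norm(x) > 1e12:
            raise SteadyStateError("states diverge; no steady state", reason="divergence")
        dx = residual(x)
        if np.linalg.norm(dx) / max(np.linalg.norm(x), 1.0) < 1e-9:
            if np.any(x < -tol):
                raise SteadyStateError("steady state has negative components")
            return np.clip(x, 0.0, None)
        elapsed += horizon
        horizon *= 2.0
    raise SteadyStateError(
        f"no steady state within horizon budget {max_horizon}", reason="non-convergence"
    )
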
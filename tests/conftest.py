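import numpy as np
import pytest

import adapt
from adapt.model import ModelSpec
from adapt.trajectory import ParameterTrajectory, TrajectoryConfig, TrajectoryEnsemble


@pytest.fixture(scope="session")
def toy_model():
    return adapt.make_toy_model()


@pytest.fixture(scope="session")
def decay_model():
    """One-state model dx/dt = p - d*x with outputs x and the efflux flux.

    Fully identifiable from steady-state data: x_ss = p/d and the efflux
    flux equals p.
    """
    return ModelSpec(
        name="decay1",
        state_names=("x",),
        param_names=("p", "d"),
        flux_names=("inflow", "outflow"),
        output_names=("x", "outflow_flux"),
        stoichiometry=np.array([[1.0, -1.0]]),
        flux_fn=lambda x, k, u: np.array([k[0], k[1] * x[0]]),
        output_fn=lambda x, k, u: np.array([x[0], k[1] * x[0]]),
        nominal_params=np.array([2.0, 0.5]),
    )


def make_synthetic_ensemble(model, params, outputs=None, states=None, fluxes=None,
                            horizon=21.0):
    """Assemble a TrajectoryEnsemble directly from arrays (tests only).

    ``params``: (M, N+1, n_params). Other fields are filled with ones when
    not supplied; shapes follow the model.
    """
    params = np.asarray(params, dtype=float)
    n_members, n_grid, _ = params.shape
    cfg = TrajectoryConfig(n_steps=n_grid - 1, horizon=horizon)
    times = cfg.time_grid
    if outputs is None:
        outputs = np.ones((n_members, n_grid, model.n_outputs))
    if states is None:
        states = np.ones((n_members, n_grid, model.n_states))
    if fluxes is None:
        fluxes = np.ones((n_members, n_grid, model.n_fluxes))
    members = [
        ParameterTrajectory(
            times=times,
            params=params[m],
            states=np.asarray(states)[m].astype(float),
            fluxes=np.asarray(fluxes)[m].astype(float),
            outputs=np.asarray(outputs)[m].astype(float),
            data_costs=np.zeros(n_grid - 1),
            reg_costs=np.zeros(n_grid - 1),
        )
        for m in range(n_members)
    ]
    return TrajectoryEnsemble(model=model, config=cfg, members=members,
                              n_attempted=n_members)


@pytest.fixture(scope="session")
def scenario_b():
    return adapt.make_scenario("treatment")


@pytest.fixture(scope="session")
def scenario_b_dataset(scenario_b):
    return adapt.generate_dataset(scenario_b, np.random.default_rng(21))


@pytest.fixture(scope="session")
def small_ensemble_b(scenario_b, scenario_b_dataset):
    """Small but real scenario-B ensemble shared across module tests."""
    cfg = TrajectoryConfig(n_steps=12, horizon=21.0)
    return adapt.run_ensemble(
        scenario_b.model, scenario_b_dataset, cfg, 10, np.random.default_rng(23)
    )
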
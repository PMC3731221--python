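import numpy as np
import pytest

from adapt.baseline import BaselineMember
from adapt.data import build_interpolant_collection
from adapt.model import find_steady_state, simulate
from adapt.trajectory import (
    TrajectoryConfig,
    data_cost_step,
    estimate_step,
    estimate_trajectory,
    regularization_cost,
    run_ensemble,
)

from test_baseline import dataset_for


class TestRegularizationCost:
    def test_no_change_costs_zero(self):
        th = np.array([1.0, 2.0])
        assert regularization_cost(th, th, th, 0.5, 10.0) == 0.0

    def test_zero_lambda_costs_zero(self):
        assert regularization_cost([3.0], [2.0], [2.0], 0.5, 0.0) == 0.0

    def test_hand_computed_value(self):
        # theta_hat0=2, theta_prev=2, theta_n=3, dt=0.5, lam=10
        assert regularization_cost([3.0], [2.0], [2.0], 0.5, 10.0) == pytest.approx(10.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError, match="index 0"):
            regularization_cost([1.0], [1.0], [0.0], 0.5, 1.0)


@pytest.fixture()
def interp_flat(decay_model):
    ds = dataset_for(decay_model, [2.0, 0.5], lambda k: np.array([k[0] / k[1]]))
    return build_interpolant_collection(
        ds, 1, 1.0, np.random.default_rng(0), resample=False
    )[0]


class TestDataCostStep:
    def test_exact_outputs_cost_zero(self, decay_model, interp_flat):
        assert data_cost_step(
            decay_model, [4.0], [2.0, 0.5], interp_flat, 1.0
        ) == pytest.approx(0.0, abs=1e-12)

    def test_single_observable_hand_value(self, decay_model):
        # y = (x, flux); choose state so x-output misfit is (3-1)/2 -> 1.0
        # with flux matched exactly
        ds = dataset_for(decay_model, [2.0, 2.0], lambda k: np.array([1.0]), sd=2.0)
        interp = build_interpolant_collection(
            ds, 1, 1.0, np.random.default_rng(0), resample=False
        )[0]
        # state=3: x residual (3-1)/2=1; flux residual (6-2)/2=2 -> 1+4
        cost = data_cost_step(decay_model, [3.0], [2.0, 2.0], interp, 1.0)
        assert cost == pytest.approx(5.0, rel=1e-6)

    def test_doubling_sigma_quarters_cost(self, decay_model):
        ds1 = dataset_for(decay_model, [2.0, 0.5], lambda k: np.array([4.0]), sd=1.0)
        ds2 = dataset_for(decay_model, [2.0, 0.5], lambda k: np.array([4.0]), sd=2.0)
        kw = dict(resample=False)
        i1 = build_interpolant_collection(ds1, 1, 1.0, np.random.default_rng(0), **kw)[0]
        i2 = build_interpolant_collection(ds2, 1, 1.0, np.random.default_rng(0), **kw)[0]
        c1 = data_cost_step(decay_model, [5.0], [2.0, 0.5], i1, 1.0)
        c2 = data_cost_step(decay_model, [5.0], [2.0, 0.5], i2, 1.0)
        assert c1 == pytest.approx(4.0 * c2, rel=1e-9)


@pytest.fixture(scope="module")
def toy_flat_interp(toy_model):
    """Interpolants generated by the toy model resting at its nominal steady
    state: the self-consistent target for fixed-point checks."""
    x_ss = find_steady_state(toy_model, toy_model.nominal_params, np.ones(3))
    ds = dataset_for(
        toy_model, toy_model.nominal_params, lambda k: x_ss,
        times=(0.0, 1.0, 2.0, 4.0, 7.0, 14.0, 21.0), sd=0.2,
    )
    return build_interpolant_collection(
        ds, 1, 1.0, np.random.default_rng(0), resample=False
    )[0]


class TestEstimateStep:
    def test_self_consistent_data_is_fixed_point(self, toy_model, toy_flat_interp):
        cfg = TrajectoryConfig(n_steps=10, horizon=21.0, lam1=1.0)
        theta0 = toy_model.nominal_params
        x_ss = find_steady_state(toy_model, theta0, np.ones(3))
        theta, x_end, info = estimate_step(
            toy_model, x_ss, theta0, theta0, toy_flat_interp, 0.0, 2.1, cfg
        )
        assert np.allclose(theta, theta0, rtol=1e-4)
        assert info["data_cost"] < 1e-6

    def test_huge_lambda_pins_parameters(self, toy_model, toy_flat_interp):
        cfg = TrajectoryConfig(n_steps=10, horizon=21.0, lam1=1e12)
        theta0 = toy_model.nominal_params * 1.3  # deliberate misfit
        x0 = find_steady_state(toy_model, toy_model.nominal_params, np.ones(3))
        theta, _, _ = estimate_step(
            toy_model, x0, theta0, theta0, toy_flat_interp, 0.0, 2.1, cfg
        )
        assert np.allclose(theta, theta0, rtol=1e-5)

    def test_infeasible_data_returns_finite(self, toy_model):
        # target far outside what the dynamics can reach within one step
        ds = dataset_for(
            toy_model, toy_model.nominal_params, lambda k: np.array([500.0, 500.0, 500.0]),
            times=(0.0, 1.0, 2.0, 4.0), sd=1.0,
        )
        interp = build_interpolant_collection(
            ds, 1, 1.0, np.random.default_rng(0), resample=False
        )[0]
        cfg = TrajectoryConfig(n_steps=10, horizon=4.0, lam1=1.0)
        x0 = find_steady_state(toy_model, toy_model.nominal_params, np.ones(3))
        theta, x_end, info = estimate_step(
            toy_model, x0, toy_model.nominal_params, toy_model.nominal_params,
            interp, 0.0, 0.4, cfg,
        )
        assert np.all(np.isfinite(theta))
        assert info["data_cost"] > 0


class TestEstimateTrajectory:
    def test_state_continuity_and_frozen_params_match_one_shot(
        self, toy_model, toy_flat_interp
    ):
        cfg = TrajectoryConfig(n_steps=20, horizon=21.0, lam1=1e12)  # pin params
        theta0 = toy_model.nominal_params * np.array([1.1, 1, 1, 0.9, 1, 1])
        x0 = find_steady_state(toy_model, toy_model.nominal_params, np.ones(3))
        member = BaselineMember(theta0, x0, 0.0, {"start_index": 0})
        traj = estimate_trajectory(toy_model, member, toy_flat_interp, cfg)
        # parameters pinned at theta0 by the huge penalty
        assert np.allclose(traj.params, theta0[None, :], rtol=1e-6)
        one_shot = simulate(
            toy_model, theta0, x0, 0.0, 21.0, traj.times[1:], rtol=1e-10, atol=1e-12
        )
        rel = np.abs(traj.states[1:] - one_shot.states) / np.abs(one_shot.states)
        assert rel.max() < 1e-6

    def test_flat_truth_yields_flat_trajectories(self, toy_model, toy_flat_interp):
        cfg = TrajectoryConfig(n_steps=8, horizon=21.0)
        theta0 = toy_model.nominal_params
        x0 = find_steady_state(toy_model, theta0, np.ones(3))
        member = BaselineMember(theta0, x0, 0.0, {"start_index": 0})
        traj = estimate_trajectory(toy_model, member, toy_flat_interp, cfg)
        assert np.allclose(traj.params, theta0[None, :], rtol=1e-3)
        assert traj.total_data_cost < 1e-4


class TestRunEnsemble:
    def test_same_seed_bit_identical(self, scenario_b, scenario_b_dataset):
        cfg = TrajectoryConfig(n_steps=6, horizon=21.0)
        e1 = run_ensemble(
            scenario_b.model, scenario_b_dataset, cfg, 3, np.random.default_rng(42)
        )
        e2 = run_ensemble(
            scenario_b.model, scenario_b_dataset, cfg, 3, np.random.default_rng(42)
        )
        assert len(e1) == len(e2)
        for m1, m2 in zip(e1, e2):
            assert np.array_equal(m1.params, m2.params)
            assert np.array_equal(m1.states, m2.states)

    def test_single_iteration_gives_at_most_one(self, scenario_b, scenario_b_dataset):
        cfg = TrajectoryConfig(n_steps=6, horizon=21.0)
        ens = run_ensemble(
            scenario_b.model, scenario_b_dataset, cfg, 1, np.random.default_rng(1)
        )
        assert len(ens) <= 1

    def test_invalid_iterations_rejected(self, scenario_b, scenario_b_dataset):
        cfg = TrajectoryConfig(n_steps=6, horizon=21.0)
        with pytest.raises(ValueError):
            run_ensemble(
                scenario_b.model, scenario_b_dataset, cfg, 0, np.random.default_rng(1)
            )

    def test_members_share_grid_and_start_at_baseline(self, small_ensemble_b):
        grid = small_ensemble_b.times
        for m in small_ensemble_b:
            assert np.array_equal(m.times, grid)
            # theta[0] equals the member's baseline parameter set
            assert np.all(m.params[0] > 0)


class TestConfigValidation:
    def test_bad_steps(self):
        with pytest.raises(ValueError):
            TrajectoryConfig(n_steps=1, horizon=21.0)

    def test_negative_lambda(self):
        with pytest.raises(ValueError):
            TrajectoryConfig(n_steps=5, horizon=21.0, lam1=-1.0)
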
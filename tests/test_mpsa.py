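import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adapt.mpsa import (
    batch_sensitivity,
    classify_by_mean,
    critical_value,
    ks_distance,
    timecourse_sensitivity,
)

from conftest import make_synthetic_ensemble


def ks_brute_force(x, labels):
    """Independent oracle: scan every distinct value as a CDF threshold."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    a, u = x[labels], x[~labels]
    if a.size == 0 or u.size == 0:
        return 0.0
    best = 0.0
    for t in np.unique(x):
        fa = np.mean(a <= t)
        fu = np.mean(u <= t)
        best = max(best, abs(fa - fu))
    return best


class TestClassifyByMean:
    def test_split_at_mean(self):
        labels = classify_by_mean(np.array([1.0, 2.0, 3.0, 4.0]))
        assert list(labels) == [True, True, False, False]

    def test_all_equal_is_degenerate(self):
        labels = classify_by_mean(np.array([2.0, 2.0, 2.0]))
        assert not labels.any()  # one empty class

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            classify_by_mean(np.array([1.0]))


class TestKSDistance:
    def test_enumerated_example(self):
        k = ks_distance(np.array([1.0, 2.0, 3.0, 4.0]),
                        np.array([True, True, False, False]))
        assert k == pytest.approx(1.0)

    def test_perfect_separation(self):
        x = np.concatenate([np.arange(10), np.arange(100, 110)])
        labels = np.array([True] * 10 + [False] * 10)
        assert ks_distance(x, labels) == pytest.approx(1.0)

    def test_empty_class_returns_zero(self):
        assert ks_distance(np.array([1.0, 2.0]), np.array([True, True])) == 0.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False  # both classes non-empty
        assert ks_distance(x, labels) == pytest.approx(ks_distance(x, ~labels))

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(2, 51)
            x = rng.normal(size=n)
            if rng.random() < 0.3:  # exercise ties
                x = np.round(x, 1)
            labels = rng.random(n) < rng.uniform(0.2, 0.8)
            assert ks_distance(x, labels) == pytest.approx(
                ks_brute_force(x, labels), abs=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(st.integers(-1000, 1000), min_size=4, max_size=60),
        seed=st.integers(0, 1000),
    )
    def test_monotone_transform_invariance(self, data, seed):
        # integer-valued samples keep x -> x^3 exactly monotone in float64,
        # so the transform preserves the tie structure as well as the ranks
        x = np.asarray(data, dtype=float)
        rng = np.random.default_rng(seed)
        labels = rng.random(len(x)) < 0.5
        k1 = ks_distance(x, labels)
        k2 = ks_distance(x**3, labels)
        assert k1 == pytest.approx(k2, abs=1e-12)
        assert 0.0 <= k1 <= 1.0

    def test_null_calibration(self):
        # labels independent of x: K should rarely clear the critical value
        rng = np.random.default_rng(7)
        n = 10_000
        exceed = 0
        for _ in range(200):
            x = rng.normal(size=n)
            labels = rng.random(n) < 0.5
            n_a = int(labels.sum())
            if n_a in (0, n):
                continue
            k = ks_distance(x, labels)
            if k > critical_value(n_a, n - n_a, 0.05):
                exceed += 1
        assert exceed <= 12  # <= 6% of 200


class TestCriticalValue:
    def test_c_alpha_closed_form(self):
        c = np.sqrt(-0.5 * np.log(0.05 / 2))
        assert c == pytest.approx(1.3581, abs=1e-3)

    def test_equal_counts_closed_form(self):
        assert critical_value(500, 500, 0.05) == pytest.approx(0.0859, abs=1e-3)

    def test_monotone_in_counts(self):
        assert critical_value(1000, 1000, 0.05) < critical_value(500, 500, 0.05)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            critical_value(10, 10, alpha)


class TestTimecourseSensitivity:
    def test_perfect_dependence_gives_k_one(self, toy_model):
        rng = np.random.default_rng(3)
        M, N = 40, 5
        params = np.ones((M, N + 1, toy_model.n_params))
        params[:, :, 4] = rng.normal(10.0, 1.0, size=(M, N + 1))
        outputs = np.ones((M, N + 1, toy_model.n_outputs))
        outputs[:, :, 0] = params[:, :, 4]  # output IS the parameter
        ens = make_synthetic_ensemble(toy_model, params, outputs=outputs)
        prof = timecourse_sensitivity(ens, "param:k5", "output:hepatic_pool")
        assert np.all(prof.ks[~prof.degenerate] == 1.0)

    def test_independent_quantity_mostly_below_critical(self, toy_model):
        rng = np.random.default_rng(4)
        M, N = 400, 10
        params = np.ones((M, N + 1, toy_model.n_params))
        params[:, :, 2] = rng.normal(1.0, 0.1, size=(M, N + 1))
        outputs = rng.normal(5.0, 1.0, size=(M, N + 1, toy_model.n_outputs))
        ens = make_synthetic_ensemble(toy_model, params, outputs=outputs)
        prof = timecourse_sensitivity(ens, "param:k3", "output:plasma_pool")
        frac_below = np.mean(prof.ks <= prof.critical_values)
        assert frac_below >= 0.9

    def test_member_order_invariance(self, toy_model):
        rng = np.random.default_rng(5)
        M, N = 30, 4
        params = rng.lognormal(0, 0.3, size=(M, N + 1, toy_model.n_params))
        outputs = rng.lognormal(1, 0.2, size=(M, N + 1, toy_model.n_outputs))
        ens1 = make_synthetic_ensemble(toy_model, params, outputs=outputs)
        perm = rng.permutation(M)
        ens2 = make_synthetic_ensemble(toy_model, params[perm], outputs=outputs[perm])
        p1 = timecourse_sensitivity(ens1, "param:k1", "output:hepatic_pool")
        p2 = timecourse_sensitivity(ens2, "param:k1", "output:hepatic_pool")
        assert np.allclose(p1.ks, p2.ks)

    def test_unknown_selector_raises(self, toy_model):
        rng = np.random.default_rng(6)
        ens = make_synthetic_ensemble(
            toy_model, rng.lognormal(size=(12, 4, toy_model.n_params))
        )
        with pytest.raises(KeyError):
            timecourse_sensitivity(ens, "param:nope", "output:hepatic_pool")

    def test_small_ensemble_rejected(self, toy_model):
        ens = make_synthetic_ensemble(
            toy_model, np.ones((5, 4, toy_model.n_params))
        )
        with pytest.raises(ValueError):
            timecourse_sensitivity(ens, "param:k1", "output:hepatic_pool")


class TestBatchSensitivity:
    def _ens(self, toy_model, M=60, N=6, seed=8):
        rng = np.random.default_rng(seed)
        params = rng.lognormal(0, 0.3, size=(M, N + 1, toy_model.n_params))
        outputs = params[:, :, [0, 1, 2, 3]] + rng.normal(0, 0.1, size=(M, N + 1, 4))
        return make_synthetic_ensemble(toy_model, params, outputs=outputs)

    def test_single_full_batch_equals_timecourse(self, toy_model):
        ens = self._ens(toy_model)
        full = timecourse_sensitivity(ens, "param:k1", "output:hepatic_pool")
        batched = batch_sensitivity(
            ens, "param:k1", "output:hepatic_pool", 1, len(ens),
            np.random.default_rng(0),
        )
        assert np.allclose(batched.ks, full.ks)
        assert np.allclose(
            batched.critical_values, full.critical_values, equal_nan=True
        )

    def test_batch_mean_converges_to_full(self, toy_model):
        ens = self._ens(toy_model, M=200)
        full = timecourse_sensitivity(ens, "param:k2", "output:plasma_pool")
        small = batch_sensitivity(
            ens, "param:k2", "output:plasma_pool", 40, 50, np.random.default_rng(1)
        )
        large = batch_sensitivity(
            ens, "param:k2", "output:plasma_pool", 40, 190, np.random.default_rng(1)
        )
        err_small = np.mean(np.abs(small.ks - full.ks))
        err_large = np.mean(np.abs(large.ks - full.ks))
        assert err_large < err_small

    def test_reproducible_batches(self, toy_model):
        ens = self._ens(toy_model)
        b1 = batch_sensitivity(ens, "param:k1", "output:hepatic_pool", 10, 30,
                               np.random.default_rng(5))
        b2 = batch_sensitivity(ens, "param:k1", "output:hepatic_pool", 10, 30,
                               np.random.default_rng(5))
        assert np.array_equal(b1.batch_ks, b2.batch_ks)

    def test_small_batch_warning_recorded(self, toy_model):
        ens = self._ens(toy_model, M=20)
        prof = batch_sensitivity(ens, "param:k1", "output:hepatic_pool", 2, 5,
                                 np.random.default_rng(2))
        assert prof.provenance["warnings"]
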
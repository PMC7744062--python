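"""Finite-pool product form, marginals, steady states, pool comparisons."""

import math

import numpy as np
import pytest

from depograd import (
    JointLengthDistribution,
    KineticModel,
    NoSteadyStateError,
    PoolMode,
    finite_vs_infinite_difference,
    joint_stationary_distribution,
    log_stationary_weight,
    marginal_distribution,
    pool_fraction_in_filaments,
    steady_state_length_finite,
    steady_state_length_large_pool,
)


def finite_model(qn, lam, kind="linear", n=2_000_000, m=2):
    return KineticModel.from_dimensionless(qn, lam, kind, n, m, "finite")


class TestLogStationaryWeight:
    def test_all_zero_state(self, small_finite_model):
        from scipy.special import gammaln

        w0 = log_stationary_weight(small_finite_model, [0, 0])
        assert w0 == pytest.approx(-gammaln(small_finite_model.n_total + 1))

    @pytest.mark.parametrize("kind", ["linear", "exponential"])
    @pytest.mark.parametrize("state", [(0, 0), (3, 7), (10, 10), (19, 0)])
    def test_detailed_balance_ratio(self, kind, state):
        # weight(L1+1, L2)/weight(L1, L2) = k+(N - L1 - L2)/gamma(L1+1)
        m = finite_model(3.0, 5.0, kind, n=25)
        l1, l2 = state
        lhs = log_stationary_weight(m, [l1 + 1, l2]) - log_stationary_weight(m, [l1, l2])
        rhs = math.log(m.polymerization_rate([l1, l2])) - math.log(
            m.depolymerization_rate(l1 + 1)
        )
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_pool_overflow_rejected(self, small_finite_model):
        with pytest.raises(ValueError):
            log_stationary_weight(small_finite_model, [15, 15])

    def test_arbitrary_filament_count(self):
        # the product form is exposed for any M even though enumeration is M=2
        m = KineticModel.from_dimensionless(2.0, 4.0, "linear", 30, 3, "finite")
        w = log_stationary_weight(m, [2, 3, 4])
        assert np.isfinite(w)


class TestJointDistribution:
    def test_matches_oracle(self, small_finite_model):
        from depograd.oracle import joint_matrix, stationary_from_generator

        p, space = stationary_from_generator(small_finite_model)
        ref = joint_matrix(p, space)
        joint = joint_stationary_distribution(small_finite_model, tail_tol=1e-15)
        full = np.zeros_like(ref)
        full[joint.l1[0] : joint.l1[-1] + 1, joint.l2[0] : joint.l2[-1] + 1] = joint.probs
        assert np.max(np.abs(full - ref)) < 1e-10

    def test_exchange_symmetry(self):
        joint = joint_stationary_distribution(finite_model(5.0, 6.66e3))
        assert np.max(np.abs(joint.probs - joint.probs.T)) < 1e-15

    def test_finite_pool_shrinks_mean(self):
        joint = joint_stationary_distribution(finite_model(5.0, 6.66e4))
        assert joint.moments(0).mean < 2.664e5

    def test_normalization(self):
        joint = joint_stationary_distribution(finite_model(5.0, 6.66e3))
        assert joint.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert joint.truncation_mass < 1e-10

    def test_m3_refused(self):
        m = KineticModel.from_dimensionless(2.0, 4.0, "linear", 30, 3, "finite")
        with pytest.raises(NotImplementedError):
            joint_stationary_distribution(m)

    def test_noise_nearly_unchanged_by_pool(self):
        # coupling to the pool moves the mean but barely the relative width
        from depograd import moments, stationary_distribution_large_pool

        large = moments(
            stationary_distribution_large_pool(
                KineticModel.from_dimensionless(5.0, 6.66e3, "linear", 2_000_000)
            )
        )
        fin = joint_stationary_distribution(finite_model(5.0, 6.66e3)).moments(0)
        assert abs(fin.noise - large.noise) / large.noise < 0.25


class TestMarginal:
    def test_symmetric_marginals_identical(self):
        joint = joint_stationary_distribution(finite_model(5.0, 6.66e3))
        m0 = marginal_distribution(joint, 0)
        m1 = marginal_distribution(joint, 1)
        assert np.array_equal(m0.lengths, m1.lengths)
        assert np.max(np.abs(m0.probs - m1.probs)) < 1e-15

    def test_probability_conserved(self):
        joint = joint_stationary_distribution(finite_model(200.0, 3.94e3, "exponential"))
        assert marginal_distribution(joint, 0).probs.sum() == pytest.approx(
            joint.probs.sum(), abs=1e-12
        )

    def test_product_joint_recovers_factor(self):
        p = np.array([0.2, 0.5, 0.3])
        q = np.array([0.6, 0.4])
        joint = JointLengthDistribution(
            l1=np.arange(3), l2=np.arange(2), probs=np.outer(p, q)
        )
        assert np.allclose(marginal_distribution(joint, 0).probs, p)
        assert np.allclose(marginal_distribution(joint, 1).probs, q)

    def test_index_out_of_range(self):
        joint = joint_stationary_distribution(finite_model(5.0, 6.66e3))
        with pytest.raises(IndexError):
            marginal_distribution(joint, 2)

    def test_marginal_matches_ssa_histogram(self):
        """Scaled-down stand-in for the cell-scale SSA cross-check.

        At gradient scales ~1e4 the chain mixes too slowly for a TV test
        (it would need ~1e11 events); the same code path is validated on a
        small model where 2e4 effectively independent samples exist.
        """
        from depograd import stationary_sample

        m = finite_model(5.0, 40.0, n=2000)
        joint = joint_stationary_distribution(m, tail_tol=1e-15)
        exact = marginal_distribution(joint, 0)
        emp = stationary_sample(
            m, n_samples=20_000, burn_in=400.0, thin_interval=40.0, seed=11
        )
        p = np.zeros(max(exact.lengths[-1], emp.lengths[-1]) + 1)
        q = np.zeros_like(p)
        p[exact.lengths] = exact.probs
        q[emp.lengths] = emp.probs
        tv = 0.5 * np.abs(p - q).sum()
        assert tv < 0.05


class TestSteadyStateFinite:
    def test_linear_closed_form_reference(self):
        m = finite_model(5.0, 6.66e4)
        assert steady_state_length_finite(m) == pytest.approx(1.998e5, rel=5e-4)

    def test_exponential_matches_reference_scale(self):
        m = finite_model(200.0, 3.94e4, "exponential")
        assert steady_state_length_finite(m) == pytest.approx(2e5, abs=1e2)

    def test_exponential_root_satisfies_balance(self):
        m = finite_model(7.0, 300.0, "exponential", n=50_000)
        L = steady_state_length_finite(m)
        assert m.polymerization_rate([L, L]) == pytest.approx(
            m.depolymerization_rate(L), rel=1e-6
        )

    def test_large_pool_limit(self):
        lam, qn = 500.0, 5.0
        l_inf = steady_state_length_large_pool(
            KineticModel.from_dimensionless(qn, lam, "linear", 10**9)
        )
        l_fin = steady_state_length_finite(finite_model(qn, lam, n=10**9))
        assert l_fin == pytest.approx(l_inf, rel=1e-5)

    def test_no_steady_state(self):
        with pytest.raises(NoSteadyStateError):
            steady_state_length_finite(finite_model(0.5, 100.0))


class TestFiniteVsInfinite:
    def test_linear_thirty_percent(self):
        from depograd import solve_lambda_for_length

        lam = solve_lambda_for_length(2e5, 5.0, 2e6, 2, "linear", "finite")
        diff = finite_vs_infinite_difference(finite_model(5.0, lam))
        assert diff == pytest.approx(1.0 / 3.0, rel=1e-9)

    def test_exponential_five_percent(self):
        from depograd import solve_lambda_for_length

        lam = solve_lambda_for_length(2e5, 200.0, 2e6, 2, "exponential", "finite")
        diff = finite_vs_infinite_difference(finite_model(200.0, lam, "exponential"))
        assert diff == pytest.approx(0.044, abs=0.001)

    def test_difference_vanishes_with_small_lam(self):
        diffs = [
            finite_vs_infinite_difference(finite_model(5.0, lam))
            for lam in (1e4, 1e3, 1e2)
        ]
        assert np.all(np.diff(diffs) < 0)
        assert diffs[-1] < 1e-3


class TestPoolFraction:
    def test_reference_value(self):
        frac = pool_fraction_in_filaments(finite_model(5.0, 6.66e3))
        assert frac == pytest.approx(0.026, abs=0.001)

    def test_zero_when_no_steady_state(self):
        assert pool_fraction_in_filaments(finite_model(0.5, 100.0)) == 0.0

    def test_increasing_in_lam(self):
        fracs = [
            pool_fraction_in_filaments(finite_model(5.0, lam))
            for lam in (1e3, 1e4, 1e5)
        ]
        assert np.all(np.diff(fracs) > 0)

    def test_marginal_mode_agrees_with_balance(self):
        m = finite_model(5.0, 6.66e3)
        a = pool_fraction_in_filaments(m, method="balance")
        b = pool_fraction_in_filaments(m, method="marginal")
        assert a == pytest.approx(b, rel=1e-3)


def test_requires_finite_mode():
    m = KineticModel.from_dimensionless(5.0, 100.0, "linear", 1000, 2, "large")
    with pytest.raises(ValueError):
        steady_state_length_finite(m)
    with pytest.raises(ValueError):
        joint_stationary_distribution(m)
    with pytest.raises(ValueError):
        log_stationary_weight(m, [1, 1])
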
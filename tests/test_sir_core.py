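"""SIR estimator, delta-method variance, and the one-sided test."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st
from scipy import stats

from sirpower import (
    DegenerateDenominatorError,
    IndexSample,
    InfeasibleSIRError,
    ReferenceStandard,
    SIRModel,
    UnknownStratumError,
    compute_sir,
    delta_method_parts,
    sigma,
    sigma2,
    test_sir as sir_test,
)
from sirpower.sir_core import batch_z_statistics

from conftest import random_reference


class TestComputeSir:
    @pytest.mark.parametrize(
        "prevalence, expected",
        [(0.3, 1.0), (0.45, 1.5), (0.0, 0.0)],
    )
    def test_ratio_of_observed_to_expected(self, two_stratum_reference, prevalence, expected):
        assert compute_sir(two_stratum_reference, [0.5, 0.5], prevalence) == pytest.approx(expected)

    def test_zero_expected_prevalence_is_degenerate(self):
        ref = ReferenceStandard(
            strata=("a", "b"), lam=[0.0, 0.5], hospital_mixes=[[1.0, 0.0]], pooled_mix=[1.0, 0.0]
        )
        with pytest.raises(DegenerateDenominatorError):
            compute_sir(ref, [1.0, 0.0], 0.2)

    def test_mix_must_sum_to_one(self, two_stratum_reference):
        with pytest.raises(ValueError):
            compute_sir(two_stratum_reference, [0.5, 0.6], 0.3)


class TestDeltaMethod:
    def test_two_stratum_variance_oracle(self, two_stratum_reference):
        # hand-computed: q(1-q)/m^2 + q^2/m^4 (Σλ²p − m²) at q=m=0.3
        parts = delta_method_parts(two_stratum_reference, [0.5, 0.5], 0.3)
        assert parts.sigma2 == pytest.approx(2.7778, abs=1e-4)
        assert sigma(two_stratum_reference, 1.0, [0.5, 0.5]) == pytest.approx(1.6667, abs=1e-4)

    def test_single_stratum_reduces_to_binomial(self, single_stratum_reference):
        parts = delta_method_parts(single_stratum_reference, [1.0], 0.5)
        assert parts.sigma2 == pytest.approx(1.0)
        assert np.allclose(parts.covariance[1:, 1:], 0.0)

    def test_gradient_matches_finite_differences(self):
        """Analytic ∇θ vs central finite differences on random (Λ, p, q)."""
        rng = np.random.default_rng(123)
        h = 1e-6
        for _ in range(300):
            J = int(rng.integers(1, 8))
            ref, p, q = random_reference(rng, J)
            grad = delta_method_parts(ref, p, q).gradient
            fd = np.empty(J + 1)
            fd[0] = (compute_sir(ref, p, q + h) - compute_sir(ref, p, q - h)) / (2 * h)
            m = float(ref.lam @ p)
            for j in range(J):
                # directional derivative in p_j alone (mix validation bypassed)
                fd[j + 1] = (
                    q / (m + ref.lam[j] * h) - q / (m - ref.lam[j] * h)
                ) / (2 * h)
            assert np.allclose(grad, fd, rtol=1e-5, atol=1e-7)

    def test_multinomial_block_structure(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ref, p, q = random_reference(rng, int(rng.integers(2, 10)))
            cov = delta_method_parts(ref, p, q).covariance
            block = cov[1:, 1:]
            assert np.allclose(cov, cov.T)
            assert np.max(np.abs(block.sum(axis=0))) < 1e-12
            assert np.linalg.eigvalsh(block).min() >= -1e-10

    def test_asymptotic_variance_matches_monte_carlo(self):
        """n·Var(θ̂) over multinomial/binomial replicates approaches σ²."""
        rng = np.random.default_rng(77)
        n, reps = 10**5, 10**4
        for _ in range(3):
            ref, p, q = random_reference(rng, 5)
            s2 = delta_method_parts(ref, p, q).sigma2
            p_hat = rng.multinomial(n, p, size=reps) / n
            q_hat = rng.binomial(n, q, size=reps) / n
            theta = q_hat / (p_hat @ ref.lam)
            assert n * theta.var() == pytest.approx(s2, rel=0.05)


class TestSigma:
    def test_single_stratum_closed_form(self, single_stratum_reference):
        # σ(θ) = sqrt(θλ(1-θλ))/λ exactly
        lam = 0.5
        for theta in (0.3, 1.0, 1.5, 1.9):
            expected = np.sqrt(theta * lam * (1 - theta * lam)) / lam
            assert sigma(single_stratum_reference, theta, [1.0]) == pytest.approx(expected)

    def test_prevalence_boundary_gives_zero(self, single_stratum_reference):
        assert sigma(single_stratum_reference, 2.0, [1.0]) == pytest.approx(0.0)

    def test_infeasible_sir_raises(self, single_stratum_reference):
        with pytest.raises(InfeasibleSIRError):
            sigma(single_stratum_reference, 2.5, [1.0])

    def test_scale_equivariance_in_lambda(self):
        """Scaling all λ by c scales θ by 1/c; σ follows the scaled system."""
        rng = np.random.default_rng(9)
        for c in (0.5, 2.0):
            ref, p, q = random_reference(rng, 4)
            scaled = ReferenceStandard(
                strata=ref.strata,
                lam=np.clip(ref.lam * c, 0, 1),
                hospital_mixes=ref.hospital_mixes,
                pooled_mix=ref.pooled_mix,
            )
            if np.any(scaled.lam >= 1) or not np.any((scaled.lam > 0) & (scaled.lam < 1)):
                continue
            theta = compute_sir(ref, p, q)
            theta_c = compute_sir(scaled, p, q)
            assert theta_c == pytest.approx(theta / c)
            # σ evaluated at the corresponding SIR refers to the same implied q
            assert sigma(scaled, theta_c, p) * (ref.lam @ p * c) == pytest.approx(
                sigma(ref, theta, p) * (ref.lam @ p), rel=1e-10
            )


class TestOneSidedTest:
    def test_direct_substitution_example(self, single_stratum_reference):
        sample = IndexSample(n=100, stratum_counts=[100], outcome_count=60)
        res = sir_test(single_stratum_reference, sample, alpha=0.05)
        assert res.theta_hat == pytest.approx(1.2)
        assert res.sigma_null == pytest.approx(1.0)
        assert res.z_statistic == pytest.approx(2.0)
        assert res.critical_value == pytest.approx(1.6449, abs=1e-4)
        assert res.reject

    def test_observed_equals_expected_never_rejects(self, two_stratum_reference):
        # q̂ exactly equal to Σ λ_j p̂_j gives z = 0
        sample = IndexSample(n=100, stratum_counts=[50, 50], outcome_count=30)
        for alpha in (0.05, 0.2, 0.45):
            res = sir_test(two_stratum_reference, sample, alpha=alpha)
            assert res.z_statistic == pytest.approx(0.0)
            assert not res.reject

    @given(st.integers(min_value=0, max_value=199))
    @settings(
        max_examples=60,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_rejection_monotone_in_outcome_count(self, two_stratum_reference, k):
        sample_lo = IndexSample(n=200, stratum_counts=[120, 80], outcome_count=k)
        sample_hi = IndexSample(n=200, stratum_counts=[120, 80], outcome_count=k + 1)
        lo = sir_test(two_stratum_reference, sample_lo)
        hi = sir_test(two_stratum_reference, sample_hi)
        assert hi.z_statistic > lo.z_statistic
        assert hi.reject >= lo.reject

    def test_unknown_stratum_rejected(self, two_stratum_reference):
        sample = IndexSample(
            n=10, stratum_counts=[5, 5], outcome_count=2, strata=("a", "zz")
        )
        with pytest.raises(UnknownStratumError):
            sir_test(two_stratum_reference, sample)

    def test_known_mix_override_changes_only_the_scale(self, two_stratum_reference):
        sample = IndexSample(n=100, stratum_counts=[60, 40], outcome_count=40)
        default = sir_test(two_stratum_reference, sample)
        overridden = sir_test(two_stratum_reference, sample, known_mix=[0.5, 0.5])
        assert overridden.theta_hat == default.theta_hat
        assert overridden.sigma_null == pytest.approx(sigma(two_stratum_reference, 1.0, [0.5, 0.5]))

    def test_model_fit_equals_functional_api(self, two_stratum_reference):
        sample = IndexSample(n=100, stratum_counts=[60, 40], outcome_count=45)
        res = SIRModel(sample, two_stratum_reference).fit(alpha=0.1)
        assert res == sir_test(two_stratum_reference, sample, alpha=0.1)
        assert "SIR estimate" in res.summary()

    def test_batch_statistics_match_scalar_test(self, two_stratum_reference):
        rng = np.random.default_rng(3)
        n = 400
        counts = rng.multinomial(n, [0.6, 0.4], size=20)
        outcomes = rng.binomial(n, 0.3, size=20)
        z = batch_z_statistics(two_stratum_reference, counts, outcomes, n)
        for i in range(20):
            sample = IndexSample(n=n, stratum_counts=counts[i], outcome_count=int(outcomes[i]))
            assert z[i] == pytest.approx(sir_test(two_stratum_reference, sample).z_statistic)

    def test_null_rejection_rate_below_level(self, two_stratum_reference):
        """Monte-Carlo calibration at true SIR 1 under a fixed mix."""
        rng = np.random.default_rng(2024)
        n, reps, alpha = 2000, 20000, 0.05
        p = np.array([0.5, 0.5])
        m = float(two_stratum_reference.lam @ p)
        counts = rng.multinomial(n, p, size=reps)
        outcomes = rng.binomial(n, m, size=reps)
        z = batch_z_statistics(two_stratum_reference, counts, outcomes, n)
        rate = float(np.mean(z > stats.norm.ppf(1 - alpha)))
        mcse = np.sqrt(alpha * (1 - alpha) / reps)
        assert rate <= alpha + 3 * mcse

    def test_sigma2_consistent_with_delta_parts(self, two_stratum_reference):
        mix = [0.3, 0.7]
        m = float(np.asarray(two_stratum_reference.lam) @ mix)
        theta = 1.2
        assert sigma2(two_stratum_reference, theta, mix) == pytest.approx(
            delta_method_parts(two_stratum_reference, mix, theta * m).sigma2
        )
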
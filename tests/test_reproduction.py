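"""Controlled R0 closed forms, next-generation oracle, sensitivities, efficiency."""

import dataclasses

import numpy as np
import pytest

import mstrain as ms

from conftest import random_extended_params


class TestBaselineR0:
    def test_figure_rate_rounds_to_canonical_value(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, beta_C=0.3)
        assert ms.r0_baseline(p).value == pytest.approx(1.19592, abs=1e-5)
        assert round(ms.r0_baseline(p).value, 1) == 1.2

    def test_large_treatment_limit(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, u_T=1e9)
        limit = case1_baseline.xi * case1_baseline.beta_C / (
            case1_baseline.gamma + case1_baseline.mu)
        assert ms.r0_baseline(p).value == pytest.approx(limit, rel=1e-8)

    def test_unit_xi_no_treatment_collapse(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, xi=1.0, u_T=0.0)
        assert ms.r0_baseline(p).value == pytest.approx(p.beta_C / p.mu)

    def test_independent_of_mutation_matrix(self, case1_baseline):
        rng = np.random.default_rng(12)
        ref = ms.r0_baseline(case1_baseline).value
        for _ in range(5):
            M = rng.uniform(0.01, 1, (4, 4))
            M /= M.sum(axis=0)
            p = dataclasses.replace(case1_baseline, A=ms.MutationMatrix(M))
            assert abs(ms.r0_baseline(p).value - ref) < 1e-12


class TestExtendedR0:
    def test_reduces_to_baseline(self, case1_baseline, case1_extended):
        assert ms.r0_extended(case1_extended).value == pytest.approx(
            ms.r0_baseline(case1_baseline).value, abs=1e-12)

    def test_reduction_with_arbitrary_psi_at_zero_up(self, case1_extended,
                                                     case1_baseline):
        p = dataclasses.replace(case1_extended, psi=np.array([1.0, 0.5, 0.2, 0.0]))
        assert ms.r0_extended(p).value == pytest.approx(
            ms.r0_baseline(case1_baseline).value, abs=1e-12)

    def test_large_control_resistant_floor(self, case1_extended):
        beta = 0.301024
        p = dataclasses.replace(case1_extended, beta_C=np.full(4, beta),
                                psi=np.array([1.0, 1, 1, 0]),
                                u_T=1e6, u_P=1e6)
        assert ms.r0_extended(p).value == pytest.approx(5 * beta / 3.025, rel=1e-3)

    def test_monotone_in_both_controls(self, case1_extended):
        p = dataclasses.replace(case1_extended, psi=np.array([1.0, 1, 1, 0]),
                                zeta=np.array([0.0, 0.1, 0, 0.3]))
        for other in (0.0, 0.5):
            vals_T = [ms.r0_extended(p.with_controls(u_T=u, u_P=other)).value
                      for u in np.linspace(0, 3, 13)]
            vals_P = [ms.r0_extended(p.with_controls(u_T=other, u_P=u)).value
                      for u in np.linspace(0, 3, 13)]
            assert np.all(np.diff(vals_T) <= 1e-12)
            assert np.all(np.diff(vals_P) <= 1e-12)


class TestNextGenerationOracle:
    def test_baseline_case_matches_closed_form(self, case1_baseline):
        assert ms.ng_oracle("baseline", case1_baseline) == pytest.approx(
            ms.r0_baseline(case1_baseline).value, abs=1e-8)

    def test_extended_random_draws_match_closed_form(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            p = random_extended_params(rng)
            assert ms.ng_oracle("extended", p) == pytest.approx(
                ms.r0_extended(p).value, abs=1e-8)

    def test_baseline_random_draws_match_closed_form(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            p = random_extended_params(rng)
            base = dataclasses.replace(
                p, beta_C=np.full(p.n, p.beta_C[0]), zeta=np.zeros(p.n), u_P=0.0)
            bp = ms.collapse_extended(base)
            assert ms.ng_oracle("baseline", bp) == pytest.approx(
                ms.r0_baseline(bp).value, abs=1e-8)

    def test_single_strain_hand_computation(self):
        A = ms.MutationMatrix(np.ones((1, 1)))
        p = ms.ExtendedParams(beta_C=[0.3], xi=5, gamma=3, mu=0.025, u_T=0.4,
                              u_P=0.0, zeta=[0.0], psi=[0.0], delta=4.0, A=A)
        # one strain, no controls on P: R0 = beta*(xi*(uT+mu)+gamma)/((gamma+mu)(uT+mu))
        hand = 0.3 * (5 * 0.425 + 3) / (3.025 * 0.425)
        assert ms.ng_oracle("extended", p) == pytest.approx(hand, abs=1e-10)


class TestSensitivities:
    def test_baseline_hand_values(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, beta_C=0.25)
        sens = ms.sensitivity_baseline(p)
        assert sens.R0_at_zero == pytest.approx(10.3306, abs=1e-4)
        assert sens.R1_T == pytest.approx(-396.69, abs=0.01)
        assert sens.theta_A == pytest.approx(1 / 3.025)

    def test_baseline_matches_finite_difference(self, case1_baseline):
        sens = ms.sensitivity_baseline(case1_baseline)
        h = 1e-5
        up = dataclasses.replace(case1_baseline, u_T=h)
        dn = dataclasses.replace(case1_baseline, u_T=0.0)
        fd = (ms.r0_baseline(up).value - ms.r0_baseline(dn).value) / h
        assert sens.R1_T == pytest.approx(fd, rel=1e-3)
        assert sens.R1_T < 0  # treatment always locally efficient

    def test_extended_matches_central_differences(self):
        rng = np.random.default_rng(314)
        for _ in range(10):
            p = random_extended_params(rng, n=4).with_controls(u_T=0.0, u_P=0.0)
            sens = ms.sensitivity_extended(p)
            h = 1e-5

            def deriv(**axis):  # second-order one-sided difference at 0
                f0 = ms.r0_extended(p).value
                f1 = ms.r0_extended(p.with_controls(**{k: h for k in axis})).value
                f2 = ms.r0_extended(p.with_controls(**{k: 2 * h for k in axis})).value
                return (-3 * f0 + 4 * f1 - f2) / (2 * h)

            fd_T = deriv(u_T=True)
            fd_P = deriv(u_P=True)
            assert sens.R1_T == pytest.approx(fd_T, rel=1e-4, abs=1e-10)
            assert sens.R1_P == pytest.approx(fd_P, rel=1e-4, abs=1e-10)
            assert sens.R1_T <= 0 and sens.R1_P <= 0

    def test_uniform_beta_reduction(self, case1_extended):
        # with uniform beta and zeta = 0: R1_T = -R0 * gamma/(gamma+xi*mu) / mu
        sens = ms.sensitivity_extended(case1_extended)
        p = case1_extended
        expected = -sens.R0_at_zero * p.gamma / (p.gamma + p.xi * p.mu) / p.mu
        assert sens.R1_T == pytest.approx(expected, rel=1e-9)
        np.testing.assert_allclose(sens.w0, np.ones(4), atol=1e-9)

    def test_zero_psi_gives_zero_prophylaxis_sensitivity(self, case1_extended):
        sens = ms.sensitivity_extended(case1_extended)  # psi = 0 in fixture
        assert sens.R1_P == pytest.approx(0.0, abs=1e-15)

    def test_reducible_matrix_rejected(self, case1_extended):
        p = dataclasses.replace(case1_extended, A=ms.MutationMatrix(np.eye(4)))
        with pytest.raises(ValueError, match="irreducible"):
            ms.sensitivity_extended(p)


class TestEfficiency:
    def test_baseline_global_condition(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, beta_C=0.25)
        verdict = ms.classify_efficiency(p)
        assert verdict.global_lhs == pytest.approx(1.25)
        assert verdict.global_rhs == pytest.approx(3.025)
        assert verdict.globally_efficient

    def test_baseline_global_condition_fails_for_large_beta(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, beta_C=0.7)
        assert not ms.classify_efficiency(p).globally_efficient

    def test_fast_prophylaxis_turnover_prefers_treatment(self, case1_extended):
        p = dataclasses.replace(case1_extended, psi=np.ones(4), delta=1e6)
        assert ms.classify_efficiency(p).preferred_control == "treatment"

    def test_durable_full_prophylaxis_preferred(self, case1_extended):
        # zeta = 0, psi = 1, delta = 0, xi = 1: gamma/((gamma+mu)) < 1 => prophylaxis
        p = dataclasses.replace(case1_extended, psi=np.ones(4), delta=0.0, xi=1.0)
        verdict = ms.classify_efficiency(p)
        assert verdict.preferred_control == "prophylaxis"
        g, m = p.gamma, p.mu
        assert verdict.comparison_lhs == pytest.approx(g / ((g + m) * m), rel=1e-9)
        assert verdict.comparison_rhs == pytest.approx(1 / m, rel=1e-9)

    def test_extended_joint_global_condition(self, case1_extended):
        p = dataclasses.replace(case1_extended, psi=np.array([1.0, 1, 1, 0]))
        verdict = ms.classify_efficiency(p)
        limit = ms.r0_limit(p)
        assert verdict.globally_efficient == (limit < 1.0)


class TestLimitsAndCriticalControl:
    def test_limit_examples(self, case1_extended):
        full = dataclasses.replace(case1_extended, psi=np.ones(4))
        assert ms.r0_limit(full) == 0.0
        p = dataclasses.replace(case1_extended, beta_C=np.full(4, 0.301024),
                                psi=np.array([1.0, 1, 1, 0]))
        assert ms.r0_limit(p) == pytest.approx(5 * 0.301024 / 3.025, rel=1e-9)
        assert ms.r0_limit(p) == pytest.approx(0.49756, abs=1e-4)

    def test_limit_matches_huge_controls(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            p = random_extended_params(rng).with_controls(u_T=1e6, u_P=1e6)
            assert ms.r0_extended(p).value == pytest.approx(
                ms.r0_limit(p), rel=1e-3)

    def test_baseline_no_root_when_floor_above_one(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, beta_C=0.7)  # xi*beta > gamma+mu
        result = ms.critical_control(p, which="u_T")
        assert result.value is None and result.grid_value is None

    def test_baseline_bisection_matches_closed_form_inversion(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, beta_C=0.301024)
        result = ms.critical_control(p, which="u_T")
        # invert R0(u_T) = 1 analytically
        b, xi, g, m = p.beta_C, p.xi, p.gamma, p.mu
        u_star = (b * g - (g + m - xi * b) * m) / (g + m - xi * b)
        assert result.value == pytest.approx(u_star, rel=1e-8)
        check = dataclasses.replace(p, u_T=result.value)
        assert ms.r0_baseline(check).value == pytest.approx(1.0, abs=1e-8)

    def test_case1_prophylaxis_threshold(self, case1_extended):
        p = dataclasses.replace(case1_extended, beta_C=np.full(4, 0.3),
                                psi=np.array([1.0, 1, 1, 0]), delta=4.0)
        result = ms.critical_control(p, which="u_P")
        assert result.grid_value == pytest.approx(0.88)
        assert 0.87 < result.value < 0.88
        at_root = ms.r0_extended(p.with_controls(u_P=result.value)).value
        assert at_root == pytest.approx(1.0, abs=1e-8)

    def test_requires_supercritical_start(self, case1_baseline):
        p = dataclasses.replace(case1_baseline, beta_C=0.02)  # R0(0) < 1
        with pytest.raises(ValueError, match="<= 1"):
            ms.critical_control(p, which="u_T")
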
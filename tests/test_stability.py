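"""Equilibria, reproductive number, eigenvalues, Lyapunov diagnostics."""

import math

import numpy as np
import pytest

from plsqr import (
    CompartmentState,
    ModelVariant,
    SmokingParameters,
    dfe_eigenvalues,
    disease_free_equilibrium,
    endemic_equilibrium,
    lyapunov_derivative,
    lyapunov_value,
    reproductive_number,
    rhs,
    stability_report,
)

from conftest import random_params


class TestDiseaseFreeEquilibrium:
    def test_closed_form_is_parameter_free(self, rng, paper_params):
        for params in [paper_params] + [random_params(rng) for _ in range(20)]:
            e0 = disease_free_equilibrium(params)
            assert e0.as_array().tolist() == [1, 0, 0, 0, 0]
            assert np.all(rhs(e0, params, ModelVariant.PS) == 0)


class TestReproductiveNumber:
    def test_paper_value_to_six_decimals(self, paper_params):
        assert round(reproductive_number(paper_params), 6) == 0.431034

    def test_vanishes_when_all_quitting_is_permanent(self):
        params = SmokingParameters(a=0.1, b=0.2, c=0.3, d=0.4, e=1.0, f=0.5)
        assert reproductive_number(params) == 0

    def test_vanishes_without_quitting(self):
        params = SmokingParameters(a=0.1, b=0.2, c=0.3, d=0.0, e=0.5, f=0.5)
        assert reproductive_number(params) == 0

    def test_zero_denominator_names_vanishing_factor(self):
        params = SmokingParameters(a=0, b=0.2, c=0.3, d=0, e=0.5, f=0.5)
        with pytest.raises(ZeroDivisionError, match="a \\+ d"):
            reproductive_number(params)

    def test_always_below_one_for_positive_rates(self, rng):
        """d f (1-e) < (a+d)(a+f) holds identically: the printed formula can
        never exceed the threshold, whatever positive rates are supplied."""
        for _ in range(1000):
            assert reproductive_number(random_params(rng)) < 1


class TestEndemicEquilibrium:
    def test_paper_parameters_have_no_endemic_root(self, paper_params):
        # oracle: the scalar residual is negative on a dense grid over (0, 1]
        from plsqr.stability import _endemic_residual

        grid = np.linspace(0, 1, 100_001)[1:]
        assert all(_endemic_residual(s, paper_params) < 0 for s in grid)
        assert endemic_equilibrium(paper_params) == []

    def test_high_contact_rates_yield_root_with_tiny_residual(self):
        params = SmokingParameters(a=0.04, b=5, c=5, d=0.2, e=0.4, f=0.25)
        roots = endemic_equilibrium(params)
        assert roots
        for state in roots:
            res = np.max(np.abs(rhs(state, params, ModelVariant.PS)))
            assert res < 1e-10

    def test_root_is_local_residual_minimum(self):
        params = SmokingParameters(a=0.04, b=5, c=5, d=0.2, e=0.4, f=0.25)
        state = endemic_equilibrium(params)[0]
        res_at_root = np.max(np.abs(rhs(state, params)))
        from plsqr.stability import _compose_endemic

        perturbed = _compose_endemic(state.S + 1e-3, params)
        assert np.max(np.abs(rhs(perturbed, params))) > res_at_root

    def test_zero_death_rate_rejected(self):
        params = SmokingParameters(a=0, b=1, c=1, d=0.2, e=0.4, f=0.25)
        with pytest.raises(ZeroDivisionError):
            endemic_equilibrium(params)


class TestDfeEigenvalues:
    def test_paper_closed_form_values(self, paper_params):
        closed, _, _ = dfe_eigenvalues(paper_params)
        # discriminant d^2+2df-4def+f^2 = 0.1225, sqrt = 0.35
        assert closed == pytest.approx([-0.04, -0.44, -0.09], abs=1e-14)

    def test_paper_numeric_spectrum_and_verdict(self, paper_params):
        _, numeric, verdict = dfe_eigenvalues(paper_params)
        assert np.max(np.abs(numeric.imag)) < 1e-12
        expected = sorted([-0.44, -0.09, -0.04, -0.04, -0.04])
        assert sorted(numeric.real) == pytest.approx(expected, abs=1e-8)
        assert verdict == "locally_stable"

    def test_product_identity_lambda2_lambda3(self, rng):
        """lambda2*lambda3 = (a+d)(a+f) - d f (1-e), an algebraic identity."""
        for _ in range(1000):
            p = random_params(rng)
            _, _, _ = (None, None, None)
            closed, _, _ = dfe_eigenvalues(p)
            lhs = closed[1] * closed[2]
            rhs_ = (p.a + p.d) * (p.a + p.f) - p.d * p.f * (1 - p.e)
            assert complex(lhs).real == pytest.approx(rhs_, abs=1e-12)
            assert abs(complex(lhs).imag) < 1e-12

    def test_closed_form_embeds_in_numeric_spectrum(self, rng):
        """Each closed-form eigenvalue matches a numeric one; the two
        remaining numeric eigenvalues equal -a."""
        for _ in range(50):
            p = random_params(rng)
            closed, numeric, _ = dfe_eigenvalues(p)
            remaining = list(numeric)
            for lam in closed:
                i = int(np.argmin(np.abs(np.array(remaining) - complex(lam))))
                assert abs(remaining[i] - complex(lam)) < 1e-8
                remaining.pop(i)
            assert len(remaining) == 2
            for lam in remaining:
                assert lam == pytest.approx(-p.a, abs=1e-8)

    def test_stable_whenever_r0_below_one_and_rates_positive(self, rng):
        for _ in range(200):
            p = random_params(rng)
            assert reproductive_number(p) < 1
            _, _, verdict = dfe_eigenvalues(p)
            assert verdict == "locally_stable"


class TestLyapunov:
    def test_zero_at_reference_and_positive_elsewhere(self, rng):
        eq = CompartmentState(0.5, 0.2, 0.1, 0.1, 0.1)
        assert lyapunov_value(eq, eq) == 0
        for _ in range(100):
            state = CompartmentState(*map(float, rng.uniform(0.01, 2, size=5)))
            if np.allclose(state.as_array(), eq.as_array()):
                continue
            assert lyapunov_value(state, eq) > 0

    def test_single_compartment_closed_form(self):
        # summand e - 1 - log(e) = e - 2 for a single displaced component
        eq = CompartmentState(1, 1, 1, 1, 1)
        state = CompartmentState(math.e, 1, 1, 1, 1)
        assert lyapunov_value(state, eq) == pytest.approx(math.e - 2, rel=1e-12)

    def test_nonpositive_state_component_rejected(self):
        eq = CompartmentState(1, 1, 1, 1, 1)
        with pytest.raises(ValueError, match="L"):
            lyapunov_value(CompartmentState(1, 0, 1, 1, 1), eq)

    def test_derivative_vanishes_at_equilibrium(self):
        params = SmokingParameters(a=0.04, b=5, c=5, d=0.2, e=0.4, f=0.25)
        eq = endemic_equilibrium(params)[0]
        assert lyapunov_derivative(eq, eq, params) == pytest.approx(0, abs=1e-10)

    def test_derivative_matches_finite_difference_along_flow(self, paper_params):
        """dM/dt from the chain rule equals the time derivative of M along
        the exact integer-order flow (centered finite difference, RK4 step)."""
        from plsqr.model import rhs_array

        eq = CompartmentState(0.5, 0.2, 0.1, 0.1, 0.1)
        y = np.array([0.55, 0.2, 0.12, 0.08, 0.05])

        def rk4_step(y, h):
            f = lambda v: rhs_array(v, paper_params, ModelVariant.PS)
            k1 = f(y)
            k2 = f(y + h / 2 * k1)
            k3 = f(y + h / 2 * k2)
            k4 = f(y + h * k3)
            return y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        h = 1e-4
        m_plus = lyapunov_value(CompartmentState(*rk4_step(y, h)), eq)
        m_minus = lyapunov_value(CompartmentState(*rk4_step(y, -h)), eq)
        fd = (m_plus - m_minus) / (2 * h)
        got = lyapunov_derivative(CompartmentState(*y), eq, paper_params)
        assert got == pytest.approx(fd, abs=1e-7)

    def test_decreases_along_flow_approaching_smoking_free_state(self, paper_params):
        """As the trajectory converges to the smoking-free state, the
        Volterra Lyapunov value relative to that state decays and its
        chain-rule derivative along the flow is negative.  (A one-sided
        uniform perturbation of E0 need not have dM/dt < 0 pointwise:
        to leading order dM/dt = eps*(b - 4a) there, which is positive
        for these rates; stability only forces decay along the flow.)"""
        from plsqr import PAPER_INITIAL, rk4_solve
        from plsqr.model import rhs_array

        e0 = disease_free_equilibrium(paper_params)
        traj = rk4_solve(
            lambda t, y, p: rhs_array(y, p, ModelVariant.PS),
            PAPER_INITIAL.as_array(), paper_params, 0.05, 60.0,
        )
        m = [
            lyapunov_value(CompartmentState(*traj.states[i]), e0)
            for i in (400, 800, 1200)  # t = 20, 40, 60
        ]
        assert m[0] > m[1] > m[2]
        late = CompartmentState(*traj.states[-1])
        assert lyapunov_derivative(late, e0, paper_params) < 0


class TestStabilityReport:
    def test_report_serializes_flat_json(self, paper_params):
        import json

        report = stability_report(paper_params)
        doc = json.loads(report.to_json())
        assert set(doc) == {
            "dfe", "endemic", "R0",
            "eigenvalues_closed_form", "eigenvalues_numeric", "verdict",
        }
        assert doc["dfe"] == [1, 0, 0, 0, 0]
        assert doc["endemic"] == []
        assert doc["verdict"] == "locally_stable"
        assert doc["R0"] == pytest.approx(0.431034, abs=5e-7)
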
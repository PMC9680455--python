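import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inkfidelity import beam
from inkfidelity.errors import (
    BracketError,
    DomainError,
    InvalidParameterError,
    TensionLimitError,
)

from .conftest import random_beam_params


class TestSectionProperties:
    def test_constants_cancel(self):
        # rho chosen so q = rho * g * pi * r^2 collapses to 1
        p = beam.BeamParameters(E=1.0, P=0.0, r=1.0, rho=1.0 / (math.pi * 9.81), L=2.0, g=9.81)
        I, A, q = beam.derive_section_properties(p)
        assert q == pytest.approx(1.0)
        assert A == pytest.approx(math.pi)
        assert I == pytest.approx(math.pi / 4.0)

    def test_alginate_values_against_direct_arithmetic(self):
        r, rho, g = 0.4e-3, 1026.0, 9.81
        p = beam.BeamParameters(E=1e3, P=0.0, r=r, rho=rho, L=4e-3, g=g)
        I, A, q = beam.derive_section_properties(p)
        assert I == pytest.approx(math.pi * r**4 / 4.0, rel=1e-15)
        assert A == pytest.approx(math.pi * r**2, rel=1e-15)
        # independent arithmetic: q = 1026 * 9.81 * pi * (4e-4)^2
        assert q == pytest.approx(1026.0 * 9.81 * math.pi * 1.6e-7, rel=1e-12)

    def test_power_laws(self):
        p1 = beam.BeamParameters(E=1e3, P=0.0, r=0.2e-3, rho=1026.0, L=4e-3)
        p2 = beam.BeamParameters(E=1e3, P=0.0, r=0.4e-3, rho=1026.0, L=4e-3)
        assert p2.I == pytest.approx(16.0 * p1.I)
        assert p2.q == pytest.approx(4.0 * p1.q)

    @pytest.mark.parametrize("field,value", [("r", -1e-3), ("rho", 0.0), ("E", 0.0), ("L", -1.0)])
    def test_invalid_parameters(self, field, value):
        kwargs = dict(E=1e3, P=0.0, r=0.4e-3, rho=1026.0, L=4e-3)
        kwargs[field] = value
        with pytest.raises(InvalidParameterError):
            beam.BeamParameters(**kwargs)

    def test_slenderness(self):
        with pytest.raises(InvalidParameterError):
            beam.BeamParameters(E=1e3, P=0.0, r=5e-3, rho=1026.0, L=4e-3)


class TestClosedForm:
    def test_boundary_conditions(self, default_params):
        sol = beam.solve_coefficients(default_params)
        L = default_params.L
        w_max = beam.deflection_profile(sol, L / 2.0)
        for x in (0.0, L):
            assert abs(beam.deflection_profile(sol, x)) <= 1e-9 * max(1.0, w_max)
        # second derivative at the ends via one-sided 4-point O(h^2) stencil
        h = L * 1e-4
        for x0, sign in ((0.0, 1.0), (L, -1.0)):
            xs = x0 + sign * h * np.arange(4)
            w = beam.deflection_profile(sol, xs)
            wpp = (2 * w[0] - 5 * w[1] + 4 * w[2] - w[3]) / h**2
            assert abs(wpp) <= 1e-6 * max(1.0, abs(sol.q / sol.P))

    def test_zero_load_means_zero_deflection(self):
        # q -> 0 surrogate: vanishing density
        p = beam.BeamParameters(E=10e3, P=5e-6, r=0.4e-3, rho=1e-12, L=4e-3)
        sol = beam.solve_coefficients(p)
        xs = np.linspace(0, p.L, 101)
        assert np.allclose(beam.deflection_profile(sol, xs), 0.0, atol=1e-18)

    def test_symmetry(self, default_params):
        sol = beam.solve_coefficients(default_params)
        L = default_params.L
        xs = np.linspace(0, L, 501)
        w = beam.deflection_profile(sol, xs)
        assert np.allclose(w, w[::-1], rtol=1e-9, atol=1e-20)

    def test_midpoint_is_scan_maximum(self, default_params):
        sol = beam.solve_coefficients(default_params)
        L = default_params.L
        xs = np.linspace(0, L, 10001)
        w = beam.deflection_profile(sol, xs)
        assert np.argmax(w) == 5000
        assert beam.deflection_profile(sol, 0.3 * L) == pytest.approx(
            beam.deflection_profile(sol, 0.7 * L), rel=1e-9
        )

    def test_raw_coefficients_reproduce_profile(self, default_params):
        """c1..c4 back-transformed from the stable basis satisfy the raw form."""
        sol = beam.solve_coefficients(default_params)
        xs = np.linspace(0, sol.L, 11)
        raw = (
            sol.c1 + sol.c2 * xs + sol.c3 * np.exp(sol.k * xs)
            + sol.c4 * np.exp(-sol.k * xs) - sol.q / (2 * sol.P) * xs**2
        )
        assert np.allclose(raw, beam.deflection_profile(sol, xs), rtol=1e-9)

    def test_large_kl_no_overflow(self):
        p = random_beam_params(np.random.default_rng(7), kl_range=(400.0, 500.0))
        sol = beam.solve_coefficients(p)
        w = beam.deflection_profile(sol, np.linspace(0, p.L, 101))
        assert np.all(np.isfinite(w))
        assert w.max() > 0

    def test_p_zero_signals_classic_limit(self):
        p = beam.BeamParameters(E=10e3, P=0.0, r=0.4e-3, rho=1026.0, L=4e-3)
        with pytest.raises(TensionLimitError):
            beam.solve_coefficients(p)
        assert beam.solve(p).mode == "classic_limit"

    def test_domain_error(self, default_params):
        sol = beam.solve_coefficients(default_params)
        with pytest.raises(DomainError):
            beam.deflection_profile(sol, -0.1 * default_params.L)
        with pytest.raises(DomainError):
            beam.deflection_profile(sol, 1.1 * default_params.L)


class TestClassicLimit:
    def test_formula(self, default_params):
        p = default_params
        expected = 5.0 * p.q * p.L**4 / (384.0 * p.EI)
        assert beam.classic_limit_deflection(p) == pytest.approx(expected, rel=1e-15)

    def test_modulus_inverse_proportionality(self, default_params):
        p2 = default_params.with_modulus(2 * default_params.E)
        assert beam.classic_limit_deflection(p2) == pytest.approx(
            beam.classic_limit_deflection(default_params) / 2.0, rel=1e-12
        )

    def test_tiny_tension_agreement(self, monkeypatch):
        """The raw tensioned closed form at k*L = 1e-3 matches the limit."""
        monkeypatch.setattr(beam, "KL_SWITCH", 0.0)
        E, r, L = 10e3, 0.4e-3, 4e-3
        I = math.pi * r**4 / 4.0
        P = (1e-3 / L) ** 2 * E * I
        p = beam.BeamParameters(E=E, P=P, r=r, rho=1026.0, L=L)
        sol = beam.solve_coefficients(p)
        assert sol.mode == "closed_form_tensioned"
        w_mid = beam.deflection_profile(sol, L / 2.0)
        assert w_mid == pytest.approx(beam.classic_limit_deflection(p), rel=1e-3)

    def test_classic_profile_midpoint(self, default_params):
        sol = beam.classic_solution(default_params)
        assert beam.deflection_profile(sol, default_params.L / 2) == pytest.approx(
            beam.classic_limit_deflection(default_params), rel=1e-12
        )


class TestNumericOracle:
    def test_zero_load(self):
        p = beam.BeamParameters(E=10e3, P=5e-6, r=0.4e-3, rho=1e-12, L=4e-3)
        w = beam.solve_deflection_numeric(p, 64)
        assert np.allclose(w, 0.0, atol=1e-18)

    def test_agrees_with_closed_form(self, default_params):
        w_num = beam.solve_deflection_numeric(default_params, 1025)
        w_cf = beam.deflection_profile(
            beam.solve_coefficients(default_params),
            np.linspace(0, default_params.L, 1025),
        )
        assert np.max(np.abs(w_num - w_cf)) <= 1e-5 * w_cf.max()

    def test_second_order_convergence(self, default_params):
        sol = beam.solve_coefficients(default_params)

        def max_err(n):
            xs = np.linspace(0, default_params.L, n)
            return np.max(np.abs(
                beam.solve_deflection_numeric(default_params, n)
                - beam.deflection_profile(sol, xs)
            ))

        e_coarse, e_fine = max_err(129), max_err(257)
        assert e_coarse / e_fine >= 3.0

    def test_sweep_agreement(self, rng):
        for _ in range(20):
            p = random_beam_params(rng)
            w_num = beam.solve_deflection_numeric(p, 2049)
            mid = beam.deflection_profile(beam.solve_coefficients(p), p.L / 2.0)
            assert w_num[1024] == pytest.approx(mid, rel=1e-4)

    def test_too_few_nodes(self, default_params):
        with pytest.raises(InvalidParameterError):
            beam.solve_deflection_numeric(default_params, 8)


class TestMonotonicity:
    def test_decreasing_in_modulus(self, default_params):
        w = [beam.midpoint_deflection(default_params.with_modulus(E))
             for E in np.logspace(2, 6, 10)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_increasing_in_span(self):
        w = [beam.midpoint_deflection(
                beam.BeamParameters(E=10e3, P=5e-6, r=0.4e-3, rho=1026.0, L=L))
             for L in np.linspace(2e-3, 16e-3, 10)]
        assert all(a < b for a, b in zip(w, w[1:]))

    def test_increasing_in_load(self):
        w = [beam.midpoint_deflection(
                beam.BeamParameters(E=10e3, P=5e-6, r=0.4e-3, rho=rho, L=4e-3))
             for rho in np.linspace(200.0, 2000.0, 10)]
        assert all(a < b for a, b in zip(w, w[1:]))


class TestInverseModulus:
    @pytest.mark.parametrize("E_true", [1e3, 10e3, 100e3])
    def test_round_trip(self, E_true, default_params):
        p = default_params.with_modulus(E_true)
        w = beam.midpoint_deflection(p)
        est = beam.estimate_modulus(w, p)
        assert est.E_hat == pytest.approx(E_true, rel=1e-3)

    def test_boundary_root(self, default_params):
        E_lo = 100.0
        w_lo = beam.midpoint_deflection(default_params.with_modulus(E_lo))
        est = beam.estimate_modulus(w_lo, default_params, bracket=(E_lo, 1e7))
        assert est.E_hat == pytest.approx(E_lo, rel=1e-5)

    def test_monotone_estimates(self, default_params):
        w1 = beam.midpoint_deflection(default_params.with_modulus(5e3))
        w2 = beam.midpoint_deflection(default_params.with_modulus(50e3))
        assert w1 > w2
        e1 = beam.estimate_modulus(w1, default_params).E_hat
        e2 = beam.estimate_modulus(w2, default_params).E_hat
        assert e1 < e2

    def test_bracket_error_reports_achievable(self, default_params):
        with pytest.raises(BracketError) as exc:
            beam.estimate_modulus(1.0, default_params, bracket=(1e6, 1e7))
        assert exc.value.achievable is not None
        lo, hi = exc.value.achievable
        assert lo < hi

    def test_chord_observable_round_trip(self, default_params):
        w_chord = beam.chord_deflection(default_params)
        est = beam.estimate_modulus(w_chord, default_params, observable="chord")
        assert est.E_hat == pytest.approx(default_params.E, rel=1e-3)


class TestModulusRadiusFit:
    def test_exact_line(self):
        r = np.array([0.1, 0.2, 0.3, 0.4]) * 1e-3
        E = -2e7 * r + 20e3
        fit = beam.fit_modulus_vs_radius(np.c_[r, E])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-2e7, rel=1e-9)
        assert fit.intercept == pytest.approx(20e3, rel=1e-9)

    def test_against_normal_equations(self):
        pts = np.array([[1e-4, 5e3], [2e-4, 4.2e3], [3e-4, 2.9e3]])
        r, E = pts[:, 0], pts[:, 1]
        n = len(r)
        # hand OLS via normal equations
        sx, sy, sxx, sxy = r.sum(), E.sum(), (r * r).sum(), (r * E).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        fit = beam.fit_modulus_vs_radius(pts)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_modulus_up_as_radius_down_gives_negative_slope(self):
        pts = [(0.1e-3, 50e3), (0.2e-3, 30e3), (0.3e-3, 22e3), (0.4e-3, 10e3)]
        assert beam.fit_modulus_vs_radius(pts).slope < 0

    def test_noise_consistency(self, rng):
        r = np.linspace(0.1e-3, 0.5e-3, 50)
        for sigma in (100.0, 1.0):
            E = -3e7 * r + 25e3 + rng.normal(0, sigma, len(r))
            fit = beam.fit_modulus_vs_radius(np.c_[r, E])
            if sigma <= 1.0:
                assert fit.slope == pytest.approx(-3e7, rel=1e-3)
                assert fit.intercept == pytest.approx(25e3, rel=1e-3)

    def test_degenerate(self):
        with pytest.raises(InvalidParameterError):
            beam.fit_modulus_vs_radius([(1e-4, 1e3), (1e-4, 2e3)])


class TestAnglesToDeflection:
    def test_flat(self):
        assert beam.angles_to_midpoint_deflection(0.0, 0.0, 8e-3) == 0.0

    def test_45_degrees(self):
        assert beam.angles_to_midpoint_deflection(45.0, 45.0, 8e-3) == pytest.approx(4e-3)

    def test_asymmetric(self):
        expected = 4e-3 * math.tan(math.radians(15.0))
        assert beam.angles_to_midpoint_deflection(30.0, 0.0, 8e-3) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(DomainError):
            beam.angles_to_midpoint_deflection(90.0, 0.0, 8e-3)

    @given(th=st.floats(0, 89), L=st.floats(1e-3, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_monotone(self, th, L):
        w = beam.angles_to_midpoint_deflection(th, th, L)
        assert w >= 0
        if th > 1:
            assert w > beam.angles_to_midpoint_deflection(th - 1, th - 1, L)
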
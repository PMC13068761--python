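"""Reduced switching submodel: root solve, steady states, Jacobian, stability."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from plaqueswitch import (
    ReducedParams,
    classify,
    jacobian,
    rhs_reduced,
    solve_k,
    steady_states,
)


def closed_form_k_n1(rp):
    """Quadratic closed form for the Hill-exponent-1 case."""
    disc = (rp.Pi_c + rp.beta_c * rp.alpha_c) ** 2 + 4 * rp.delta_c * rp.Pi_c * rp.alpha_c
    return (rp.Pi_c - rp.beta_c * rp.alpha_c + math.sqrt(disc)) / (
        2 * (rp.beta_c + rp.delta_c))


class TestSolveK:
    def test_matches_closed_form_for_linear_hill(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rp = ReducedParams(Pi_c=rng.uniform(0.1, 50), beta_c=rng.uniform(0.05, 2),
                               delta_c=rng.uniform(0.0, 20), alpha_c=rng.uniform(0.2, 5),
                               n=1.0)
            assert solve_k(rp) == pytest.approx(closed_form_k_n1(rp), rel=1e-12)

    def test_reference_value(self, rp):
        k = solve_k(rp)
        assert rp.Pi_c / k == pytest.approx(1.568, abs=1e-3)
        assert k == pytest.approx(1.9135, abs=1e-3)

    def test_no_switching_collapses_to_apoptosis_balance(self, rp):
        assert solve_k(replace(rp, delta_c=0.0)) == pytest.approx(
            rp.Pi_c / rp.beta_c, rel=1e-14)

    def test_residual_and_bracket_over_grid(self, rp):
        """Across a (Pi_c, delta_c) grid the polynomial residual is at
        machine scale and Pi_c/k always lies in (beta_c, beta_c+delta_c)."""
        for Pi in np.geomspace(0.1, 50, 12):
            for dc in np.geomspace(0.1, 50, 12):
                rpi = replace(rp, Pi_c=Pi, delta_c=dc)
                k = solve_k(rpi)
                n = rpi.n
                resid = ((rpi.beta_c + dc) * k ** (n + 1) - Pi * k ** n
                         + rpi.alpha_c ** n * rpi.beta_c * k - rpi.alpha_c ** n * Pi)
                scale = Pi * max(k, rpi.alpha_c) ** n + 1.0
                assert abs(resid) < 1e-12 * scale
                assert rpi.beta_c < Pi / k < rpi.beta_c + dc

    def test_k_independent_of_rho_c(self, rp):
        ks = [solve_k(replace(rp, rho_c=r)) for r in np.linspace(2, 20, 7)]
        assert np.ptp(ks) == 0.0


class TestSteadyStates:
    def test_trivial_branch_average_load(self, rp):
        trivial, _ = steady_states(rp)
        assert trivial.C_star == 0.0 and trivial.S_star == 0.0
        assert trivial.Abar_c_star == pytest.approx(1 + rp.Pi_c / rp.rho_c)

    def test_population_ratio_at_reference_uptake(self, rp):
        _, nt = steady_states(rp)
        assert nt.S_star / nt.C_star == pytest.approx(4.558, abs=2e-3)
        assert nt.Abar_c_star == pytest.approx(1 + nt.k)
        assert nt.physical

    def test_saturated_uptake_limits(self, rp):
        """As the uptake rate grows without bound, switching saturates and
        the normalised populations approach their analytic limits."""
        _, nt = steady_states(replace(rp, Pi_c=1e6))
        C_lim = 1 - (rp.beta_c + rp.delta_c) / rp.rho_c
        assert nt.C_star / rp.C_0 == pytest.approx(C_lim, rel=1e-3)
        assert nt.S_star / rp.C_0 == pytest.approx(
            rp.delta_c / (rp.beta_s - rp.rho_s) * C_lim, rel=1e-3)

    def test_transcritical_point_branches_coincide(self, rp):
        k = solve_k(rp)
        trivial, nt = steady_states(replace(rp, rho_c=rp.Pi_c / k))
        assert nt.C_star == pytest.approx(0.0, abs=1e-9)
        assert nt.S_star == pytest.approx(0.0, abs=1e-9)
        assert trivial.Abar_c_star == pytest.approx(nt.Abar_c_star, rel=1e-9)

    def test_rejects_unbounded_sdm_parameters(self, rp):
        with pytest.raises(ValueError, match="beta_s > rho_s"):
            steady_states(replace(rp, beta_s=5.0, rho_s=5.0))


class TestJacobian:
    def test_structure_third_column(self, rp):
        J = jacobian(rp, (0.1, 2.0, 0.3))
        assert J[0, 2] == 0.0 and J[1, 2] == 0.0
        assert J[2, 2] == rp.rho_s - rp.beta_s

    def test_trivial_eigenvalues_closed_form(self, rp):
        trivial, _ = steady_states(rp)
        x = (rp.Pi_c / rp.rho_c / rp.alpha_c) ** rp.n
        lam1 = rp.rho_c - rp.beta_c - rp.delta_c * x / (1 + x)
        expected = sorted([lam1, -rp.rho_c, rp.rho_s - rp.beta_s])
        got = sorted(np.real(trivial.eigenvalues))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_matches_finite_differences(self, rp):
        rng = np.random.default_rng(17)
        eps = 1e-7
        for _ in range(100):
            state = np.array([rng.uniform(0.01, 0.27), rng.uniform(1.01, 6),
                              rng.uniform(0.0, 2)])
            J = jacobian(rp, state)
            for j in range(3):
                dp, dm = state.copy(), state.copy()
                dp[j] += eps
                dm[j] -= eps
                col = (rhs_reduced(rp, dp) - rhs_reduced(rp, dm)) / (2 * eps)
                np.testing.assert_allclose(J[:, j], col, rtol=1e-5, atol=1e-6)


class TestClassify:
    def test_baseline_coexistence_stable(self, rp):
        report = classify(rp)
        assert report["nontrivial"].stable and report["nontrivial"].physical
        assert report["trivial"].stability == "saddle"

    def test_weak_proliferation_extinction(self, rp):
        report = classify(replace(rp, rho_c=1.0))  # below the 1.568 threshold
        assert report["trivial"].stability == "stable node"
        assert not report["nontrivial"].physical

    def test_apoptosis_dominated_smc_nonphysical(self, rp):
        report = classify(replace(rp, rho_c=0.1, beta_c=0.2))
        assert not report["nontrivial"].physical


class TestRhsForms:
    def test_steady_states_are_fixed_points(self, rp):
        trivial, nt = steady_states(rp)
        for ss in (trivial, nt):
            d = rhs_reduced(rp, (ss.C_star, ss.Abar_c_star, ss.S_star))
            assert np.max(np.abs(d)) < 1e-10

    def test_average_form_finite_at_extinction(self, rp):
        d = rhs_reduced(rp, (0.0, 2.5, 0.0))
        assert np.all(np.isfinite(d))
        assert d[1] == pytest.approx(rp.Pi_c - rp.rho_c * 1.5)

    def test_total_and_average_forms_agree_along_trajectory(self, rp):
        y0 = np.array([0.05, 1.2, 0.01])
        sol_avg = solve_ivp(lambda t, y: rhs_reduced(rp, y), (0, 5), y0,
                            rtol=1e-11, atol=1e-13, dense_output=True)
        y0_tot = np.array([y0[0], y0[0] * y0[1], y0[2]])
        sol_tot = solve_ivp(lambda t, y: rhs_reduced(rp, y, form="total"),
                            (0, 5), y0_tot, rtol=1e-11, atol=1e-13,
                            dense_output=True)
        for t in np.linspace(0.5, 5, 10):
            C, Abar, S = sol_avg.sol(t)
            Ct, A_c, St = sol_tot.sol(t)
            assert Ct == pytest.approx(C, rel=1e-7)
            assert A_c / Ct == pytest.approx(Abar, rel=1e-7)
            assert St == pytest.approx(S, rel=1e-6, abs=1e-9)

    def test_random_starts_converge_to_predicted_branch(self):
        """Long-time integration lands on whichever branch the eigenvalue
        classification marks stable."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            rp = ReducedParams(
                Pi_c=rng.uniform(0.5, 10), rho_c=rng.uniform(0.5, 12),
                beta_c=rng.uniform(0.05, 0.5), delta_c=rng.uniform(0.5, 8),
                alpha_c=rng.uniform(0.5, 4), beta_s=5.3, rho_s=5.0,
                n=float(rng.integers(1, 5)))
            report = classify(rp)
            target = (report["nontrivial"] if report["nontrivial"].physical
                      else report["trivial"])
            y0 = np.array([rng.uniform(0.01, rp.C_0), rng.uniform(1.0, 4.0),
                           rng.uniform(0.0, 1.0)])
            sol = solve_ivp(lambda t, y: rhs_reduced(rp, y), (0, 200), y0,
                            method="LSODA", rtol=1e-10, atol=1e-12)
            C, Abar, S = sol.y[:, -1]
            assert C == pytest.approx(target.C_star, rel=1e-5, abs=1e-7)
            assert Abar == pytest.approx(target.Abar_c_star, rel=1e-5)
            assert S == pytest.approx(target.S_star, rel=1e-5, abs=1e-7)
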
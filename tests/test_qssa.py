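"""Tests of the quasi-steady-state reduction, nullclines and fixed points."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from perisilence import (find_fixed_points, h3k9me_nullcline,
                         qssa_bifurcation, rhs_three_state,
                         rna_quasi_equilibrium, sirna_nullcline)
from perisilence.qssa import reduced_rhs
from conftest import jittered_parameters


class TestRnaQuasiEquilibrium:
    def test_unmethylated_limit(self, wt):
        assert rna_quasi_equilibrium(0.0, wt) == pytest.approx(
            wt.copy_number * wt.alpha / wt.delta1)

    def test_fully_methylated_limit_closed_form(self, wt):
        # with k1=k2=1, rho1=1, rho2=2 the x3=1 limit is C*alpha/(2*delta1+gamma)
        assert (wt.k1, wt.k2, wt.rho1, wt.rho2) == (1.0, 1.0, 1.0, 2.0)
        assert rna_quasi_equilibrium(1.0, wt) == pytest.approx(
            wt.copy_number * wt.alpha / (2 * wt.delta1 + wt.gamma))

    @pytest.mark.parametrize("x3", [0.05, 0.3, 0.8])
    def test_matches_relaxation_of_rna_equation_alone(self, wt, x3):
        # independent oracle: integrate dx1/dt with x2, x3 frozen
        x2 = 5.0
        sol = solve_ivp(
            lambda t, y: [rhs_three_state((y[0], x2, x3), wt)[0]],
            (0, 5000), [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(rna_quasi_equilibrium(x3, wt),
                                             rel=1e-6)


class TestSirnaNullcline:
    def test_zero_at_zero_methylation(self, wt):
        assert sirna_nullcline(0.0, wt) == 0.0

    def test_linear_in_copy_number(self, wt):
        x3 = np.linspace(0.01, 0.99, 25)
        double = wt.replace(copy_number=2 * wt.copy_number)
        assert np.allclose(sirna_nullcline(x3, double),
                           2 * sirna_nullcline(x3, wt), rtol=1e-12)

    def test_monotone_increasing_in_copy_number(self, wt):
        x3 = np.linspace(0.01, 0.99, 25)
        prev = sirna_nullcline(x3, wt.replace(copy_number=1.0))
        for cn in (2.0, 5.0, 17.0, 40.0):
            cur = sirna_nullcline(x3, wt.replace(copy_number=cn))
            assert np.all(cur > prev)
            prev = cur

    @pytest.mark.parametrize("x3", [0.1, 0.5, 0.9])
    def test_balances_sirna_equation_at_rna_equilibrium(self, wt, x3):
        # substituting the quasi-equilibrium RNA into the siRNA balance must
        # return zero exactly at the nullcline value
        x2 = sirna_nullcline(x3, wt)
        x1 = rna_quasi_equilibrium(x3, wt)
        assert rhs_three_state((x1, x2, x3), wt)[1] == pytest.approx(
            0.0, abs=1e-14)


class TestH3K9meNullcline:
    def test_zero_where_methylation_terms_balance_without_sirna(self, wt):
        # numerator root: delta3*x3 = phi*(1-x3)*x3 + zeta*(1-x3)
        from scipy.optimize import brentq

        root = brentq(lambda x: wt.delta3 * x - (1 - x) * (wt.phi * x
                                                           + wt.zeta),
                      1e-9, 0.5)
        assert h3k9me_nullcline(root, wt) == pytest.approx(0.0, abs=1e-12)

    def test_diverges_near_full_methylation(self, wt):
        assert h3k9me_nullcline(1 - 1e-9, wt) > 1e6

    def test_copy_number_independent(self, wt):
        x3 = np.linspace(0.01, 0.99, 50)
        a = h3k9me_nullcline(x3, wt.replace(copy_number=2.0))
        b = h3k9me_nullcline(x3, wt.replace(copy_number=40.0))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("x3", [0.0, 1.0])
    def test_rejects_singular_endpoints(self, wt, x3):
        with pytest.raises(ValueError):
            h3k9me_nullcline(x3, wt)


class TestFixedPoints:
    def test_wild_type_is_monostable_silenced(self, wt):
        fps = find_fixed_points(wt)
        assert len(fps) == 1
        assert fps[0].stability == "stable"
        assert fps[0].regime == "silenced"

    def test_low_copy_number_has_three_with_unstable_middle(self, wt):
        fps = find_fixed_points(wt.replace(copy_number=5.0))
        assert len(fps) == 3
        assert [fp.stability for fp in fps] == ["stable", "unstable",
                                                "stable"]
        assert fps[0].regime == "desilenced"
        assert fps[2].regime == "silenced"

    def test_no_methylation_rate_leaves_single_desilenced_state(self, wt):
        fps = find_fixed_points(wt.replace(epsilon=0.0))
        assert len(fps) == 1
        assert fps[0].is_stable and fps[0].regime == "desilenced"

    def test_qssa_roots_are_full_model_roots(self, wt):
        # oracle equivalence across randomized parameter sets: each reduced
        # fixed point, completed with the quasi-equilibrium RNA, must zero
        # the full three-variable RHS
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = jittered_parameters(wt, rng)
            for fp in find_fixed_points(p):
                res = rhs_three_state((fp.x1, fp.x2, fp.x3), p)
                assert max(abs(v) for v in res) < 1e-7

    def test_stability_agrees_with_full_jacobian(self, wt):
        # no spurious flips between the reduced 2x2 and full 3x3 Jacobians
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = jittered_parameters(wt, rng)
            for fp in find_fixed_points(p):
                h = 1e-7
                j = np.empty((3, 3))
                y0 = np.array([fp.x1, fp.x2, fp.x3])
                for col in range(3):
                    dp = np.zeros(3)
                    dp[col] = h
                    up = np.array(rhs_three_state(y0 + dp, p))
                    dn = np.array(rhs_three_state(y0 - dp, p))
                    j[:, col] = (up - dn) / (2 * h)
                full_stable = np.all(np.linalg.eigvals(j).real < 0)
                assert full_stable == fp.is_stable

    def test_bistability_across_hill_coefficients(self, wt):
        # three intersections remain achievable whenever rho1>=1, rho2>=2,
        # rho3>=1 near the reference parameters
        for rho in [(1, 2, 1), (2, 2, 1), (1, 3, 1), (1, 2, 2), (2, 3, 2)]:
            p = wt.replace(rho1=rho[0], rho2=rho[1], rho3=rho[2])
            counts = [len(find_fixed_points(p.replace(copy_number=c)))
                      for c in range(1, 25)]
            assert max(counts) == 3, f"no bistability for rho={rho}"


class TestQssaBifurcation:
    def test_saddle_node_interval_on_copy_number(self, wt):
        diagram = qssa_bifurcation(wt, "copy_number", np.arange(1.0, 21.0))
        counts = diagram.stable_counts()
        assert list(counts[:11]) == [2] * 11
        assert list(counts[11:]) == [1] * 9
        assert diagram.saddle_nodes == [(11.0, 12.0)]

    def test_no_spreading_extends_bistability_to_large_copy_numbers(self, wt):
        diagram = qssa_bifurcation(wt.replace(phi=0.0), "copy_number",
                                   np.array([15.0, 25.0, 35.0]))
        assert list(diagram.stable_counts()) == [2, 2, 2]

    def test_singleton_grid_equals_direct_fixed_points(self, wt):
        diagram = qssa_bifurcation(wt, "copy_number", np.array([5.0]))
        direct = find_fixed_points(wt.replace(copy_number=5.0))
        assert diagram.fixed_points[0] == direct
        assert diagram.saddle_nodes == []

    def test_reduced_and_full_dynamics_agree_on_timescales(self, wt):
        # the reduced model tracks the full model closely at CN=15
        from perisilence import integrate

        full = integrate(wt, (0.0, 0.0, 0.0), 8000.0, record_step=400.0)
        sol = solve_ivp(lambda t, y: list(reduced_rhs(y[0], min(y[1], 1.0),
                                                      wt)),
                        (0, 8000.0), [0.0, 0.0], t_eval=full.times,
                        rtol=1e-8, atol=1e-10, method="LSODA")
        # small timing offsets during the silencing transition are expected;
        # the reduced model must track the full model to a few percent
        assert np.allclose(sol.y[1], full.states[:, 2], atol=0.05)
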
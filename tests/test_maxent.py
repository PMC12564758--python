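"""MaxEnt constructors and transfer-function-constrained identification."""

import math

import numpy as np
import pytest

import pathent as pe
from pathent.maxent import _theta_2pool


class TestMaxEntGivenInputAndTransit:
    def test_one_pool_reduces_to_exponential(self):
        sys = pe.maxent_given_input_and_transit([1.0], ET=2.0, d=1)
        np.testing.assert_allclose(sys.B, [[-0.5]])

    def test_constructed_transit_time_is_exact(self):
        sys = pe.maxent_given_input_and_transit([1, 1, 1], ET=2.0, d=3)
        np.testing.assert_allclose(np.diag(sys.B), [-2.5] * 3)
        assert pe.diagnostics(sys).ET == pytest.approx(2.0, rel=1e-12)

    def test_nonpositive_transit_rejected(self):
        with pytest.raises(ValueError):
            pe.maxent_given_input_and_transit([1.0], ET=0.0, d=2)

    def test_dominates_rejection_sampled_competitors(self):
        # any other 2-pool system with the same (u, ET) has lower path entropy
        u, ET = [1.0, 1.0], 1.0
        best = pe.path_entropy(pe.maxent_given_input_and_transit(u, ET, d=2)).H_path
        rng = np.random.default_rng(31)
        for _ in range(500):
            cand = pe.validate_system(u, pe.random_system(2, rng=rng).B)
            # rescale rates so the mean transit time matches exactly
            cand = cand.with_rates_scaled(pe.diagnostics(cand).ET / ET)
            assert pe.diagnostics(cand).ET == pytest.approx(ET, rel=1e-10)
            assert pe.path_entropy(cand).H_path <= best + 1e-9


class TestMaxEntGivenSteadyState:
    def test_two_pool_unit_stocks_matrix(self):
        # plugging x*=(1,1) into the closed form
        sys = pe.maxent_given_steady_state([1, 1], [1, 1])
        np.testing.assert_allclose(sys.B, [[-2, 1], [1, -2]])

    def test_steady_state_reproduced(self):
        # stocks balanced enough that the implied input vector is nonnegative
        x = np.array([0.9, 1.2, 1.05])
        B = x[:, None] / x[None, :]
        np.fill_diagonal(B, -(x.sum() - x) / x - 1.0 / x)
        u = -B @ x
        sys = pe.maxent_given_steady_state(u, x)
        np.testing.assert_allclose(pe.steady_state(sys), x, rtol=1e-10)

    def test_incompatible_input_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            pe.maxent_given_steady_state([1, 0], [1, 1])

    def test_nonpositive_stocks_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pe.maxent_given_steady_state([1, 1], [1, 0])

    def test_stock_constraint_can_only_lower_entropy(self):
        # fixing x* on top of (u, ET) breaks symmetry: H2* <= H1*
        rng = np.random.default_rng(13)
        for _ in range(20):
            # draws kept near-balanced so the implied input is nonnegative
            x = rng.uniform(0.8, 1.2, size=3)
            B = x[:, None] / x[None, :]
            np.fill_diagonal(B, -(x.sum() - x) / x - 1.0 / x)
            u = -B @ x
            sys2 = pe.maxent_given_steady_state(u, x)
            ET = pe.diagnostics(sys2).ET
            sys1 = pe.maxent_given_input_and_transit(u, ET, d=3)
            assert (
                pe.path_entropy(sys2).H_path
                <= pe.path_entropy(sys1).H_path + 1e-9
            )


class TestGammas:
    def test_reported_optimum_parameters_reproduce_constraints(self):
        g = pe.gammas_from_parameters((1.821, 1.098, 0.902, 1.179))
        np.testing.assert_allclose(g, (3.0, 5.0, 4.0), atol=2e-3)

    def test_decoupled_pools_factorize(self):
        a, b = 1.3, 0.7
        assert pe.gammas_from_parameters((0, 0, a, b)) == pytest.approx(
            (b, a + b, a * b)
        )

    def test_round_trip_through_system(self):
        # the system built from p yields a transfer function with exactly p's gammas
        p = (0.9, 1.4, 0.3, 1.1)
        sys = pe.system_from_parameters(p)
        g1, g2, g3 = pe.gammas_from_parameters(p)
        assert -np.trace(sys.B) == pytest.approx(g2)
        assert np.linalg.det(sys.B) == pytest.approx(g3)
        assert sys.B[0, 1] + sys.z[1] == pytest.approx(g1)

    def test_positive_gammas_required(self):
        with pytest.raises(ValueError):
            pe.TransferConstraints(0.0, 5.0, 4.0)


def _feasible_curve_theta(b12, gammas=(3.0, 5.0, 4.0)):
    """Analytic elimination of the constraints: independent oracle.

    For gammas (g1, g2, g3), z2 = g1 - b12, B21 + z1 = g2 - g1 and
    z1 = (g3 - (g2 - g1) z2) / b12 parameterize the feasible set by b12.
    """
    g1, g2, g3 = gammas
    z2 = g1 - b12
    s = g2 - g1
    z1 = (g3 - s * z2) / b12
    b21 = s - z1
    p = (b12, b21, z1, z2)
    if min(p) < 0:
        return None, None
    return p, _theta_2pool(p, (1.0, 0.0))


class TestIdentification:
    def test_recovers_known_optimum(self):
        result = pe.identify_max_theta(
            pe.TransferConstraints(3.0, 5.0, 4.0), mesh=1.0
        )
        assert result.feasible
        assert result.best_theta == pytest.approx(1.916, abs=2e-3)
        B = result.best_system.B
        assert B[0, 1] == pytest.approx(1.821, abs=2e-3)
        assert B[1, 0] == pytest.approx(1.098, abs=2e-3)
        # closed-form objective and full entropy pipeline agree at the optimum
        assert pe.path_entropy(result.best_system).theta_time == pytest.approx(
            result.best_theta, rel=1e-10
        )

    def test_matches_analytic_elimination_oracle(self):
        # maximize theta along the eliminated 1-D feasible curve by brute force
        from scipy import optimize

        grid = np.linspace(1.0 + 1e-9, 3.0 - 1e-9, 400)
        thetas = [_feasible_curve_theta(b)[1] for b in grid]
        b_best = grid[int(np.argmax(thetas))]
        res = optimize.minimize_scalar(
            lambda b: -_feasible_curve_theta(b)[1],
            bounds=(max(1.0, b_best - 0.05), b_best + 0.05),
            method="bounded",
            options={"xatol": 1e-10},
        )
        oracle_theta = -res.fun
        result = pe.identify_max_theta(
            pe.TransferConstraints(3.0, 5.0, 4.0), mesh=1.0
        )
        assert result.best_theta == pytest.approx(oracle_theta, abs=1e-6)
        assert result.best_p[0] == pytest.approx(res.x, abs=1e-4)

    def test_all_reported_maxima_feasible(self):
        result = pe.identify_max_theta(
            pe.TransferConstraints(3.0, 5.0, 4.0), mesh=1.0
        )
        target = np.array([3.0, 5.0, 4.0])
        for m in result.local_maxima:
            assert min(m["p"]) >= -1e-12
            resid = np.abs(np.array(pe.gammas_from_parameters(m["p"])) - target)
            assert resid.max() <= 1e-8

    def test_theta_optimum_does_not_maximize_path_entropy(self):
        # along the feasible curve, argmax H and argmax theta differ
        grid = np.linspace(1.0 + 1e-6, 3.0 - 1e-6, 600)
        h_vals, t_vals = [], []
        for b in grid:
            p, th = _feasible_curve_theta(b)
            h_vals.append(pe.path_entropy(pe.system_from_parameters(p)).H_path)
            t_vals.append(th)
        assert abs(grid[np.argmax(h_vals)] - grid[np.argmax(t_vals)]) > 0.05

    def test_refining_grid_never_lowers_best_theta(self):
        c = pe.TransferConstraints(3.0, 5.0, 4.0)
        coarse = pe.identify_max_theta(c, mesh=2.5)
        fine = pe.identify_max_theta(c, mesh=1.25)
        assert fine.best_theta >= coarse.best_theta - 1e-9

    def test_dominates_planted_feasible_systems(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            p = tuple(rng.uniform(0.2, 3.0, size=4))
            gammas = pe.gammas_from_parameters(p)
            planted_theta = pe.path_entropy(pe.system_from_parameters(p)).theta_time
            result = pe.identify_max_theta(
                pe.TransferConstraints(*gammas), mesh=2.5
            )
            assert result.feasible
            assert result.best_theta >= planted_theta - 1e-6

    def test_infeasible_constraints_reported_not_raised(self):
        result = pe.identify_max_theta(
            pe.TransferConstraints(1.0, 1.1, 5.0), mesh=2.5
        )
        assert not result.feasible
        assert result.best_system is None
        assert result.best_theta == -math.inf

    def test_start_order_does_not_change_result(self):
        c = pe.TransferConstraints(3.0, 5.0, 4.0)
        a = pe.identify_max_theta(c, mesh=2.5)
        b = pe.identify_max_theta(c, mesh=2.5, rng=np.random.default_rng(3))
        assert a.best_theta == pytest.approx(b.best_theta, abs=1e-12)
        np.testing.assert_allclose(a.best_p, b.best_p, atol=1e-9)
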
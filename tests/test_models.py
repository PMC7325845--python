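import numpy as np
import pytest

import clv
from helpers import matrix_exponential_affine, rk4


class TestGlvRhs:
    def test_extinct_taxon_stays_extinct(self, rng):
        p = clv.GLVParams(rng.normal(0, 1, 3), rng.normal(0, 1, (3, 3)))
        dx = clv.glv_rhs([0.5, 0.0, 0.2], None, p)
        assert dx[1] == 0.0

    def test_single_taxon_exponential(self):
        p = clv.GLVParams([0.7], [[0.0]])
        assert clv.glv_rhs([2.0], None, p)[0] == pytest.approx(1.4)

    def test_logistic_closed_form(self):
        # dx/dt = x(g + a x) solves to the logistic curve with K = -g/a
        g, a, x0 = 1.0, -2.0, 0.1
        p = clv.GLVParams([g], [[a]])
        times = np.linspace(0, 6, 13)
        traj = clv.forecast("glv", p, [x0], times)
        K = -g / a
        analytic = K / (1 + (K / x0 - 1) * np.exp(-g * times))
        np.testing.assert_allclose(traj.native[:, 0], analytic, rtol=1e-6)

    def test_dimension_mismatch(self):
        p = clv.GLVParams([0.5, 0.5], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            clv.glv_rhs([1.0], None, p)


class TestClvRhs:
    def test_zero_params_zero_derivative(self):
        p = clv.CLVParams(np.zeros(2), np.zeros((2, 3)), denominator=2)
        np.testing.assert_array_equal(clv.clv_alr_rhs(np.full(3, 1 / 3), None, p), 0.0)

    def test_uniform_composition_toy(self, rng):
        p = clv.CLVParams(rng.normal(0, 1, 2), rng.normal(0, 1, (2, 3)), denominator=2)
        expect = p.g_rel + p.A_rel @ np.full(3, 1 / 3)
        np.testing.assert_allclose(
            clv.clv_alr_rhs(np.full(3, 1 / 3), None, p), expect
        )

    def test_matches_glv_alr_derivative_on_unit_simplex(self, rng):
        D, P = 5, 2
        g = clv.GLVParams(
            rng.normal(0.5, 0.2, D), rng.normal(0, 0.5, (D, D)), rng.normal(0, 1, (D, P))
        )
        c = clv.glv_to_clv(g, denominator=1)
        for _ in range(10):
            pi = rng.dirichlet(np.ones(D))
            u = rng.integers(0, 2, P).astype(float)
            dx = clv.glv_rhs(pi, u, g)
            dlog = dx / pi
            expect = (dlog - dlog[1])[c.numerator_taxa()]
            np.testing.assert_allclose(clv.clv_alr_rhs(pi, u, c), expect, atol=1e-10)


class TestClvSimplexRhs:
    def test_derivative_sums_to_zero(self, random_clv_params, rng):
        for _ in range(20):
            pi = rng.dirichlet(np.ones(4))
            u = rng.integers(0, 2, 1).astype(float)
            d = clv.clv_simplex_rhs(pi, u, random_clv_params)
            assert abs(d.sum()) < 1e-12

    def test_vertices_are_fixed_points(self, random_clv_params):
        for k in range(4):
            vertex = np.zeros(4)
            vertex[k] = 1.0
            d = clv.clv_simplex_rhs(vertex, [0.0], random_clv_params)
            np.testing.assert_allclose(d, 0.0, atol=1e-14)

    def test_zero_component_has_zero_derivative(self, random_clv_params):
        pi = np.array([0.0, 0.4, 0.35, 0.25])
        assert clv.clv_simplex_rhs(pi, [0.0], random_clv_params)[0] == 0.0

    def test_consistent_with_alr_flow(self, random_clv_params, rng):
        # push alr coordinates along f for +-h and centrally difference pi
        p = random_clv_params
        h = 1e-6
        for _ in range(5):
            pi = rng.dirichlet(np.ones(4) * 2)
            u = np.array([1.0])
            eta = clv.alr(pi, p.denominator).values
            f = clv.clv_alr_rhs(pi, u, p)
            plus = clv.alr_inverse(eta + h * f, p.denominator)
            minus = clv.alr_inverse(eta - h * f, p.denominator)
            central = (plus - minus) / (2 * h)
            np.testing.assert_allclose(
                central, clv.clv_simplex_rhs(pi, u, p), atol=1e-7
            )


class TestLinearModels:
    def test_alr_drift_only_gives_linear_coordinates(self):
        p = clv.ALRParams([0.5, -0.25], np.zeros((2, 2)), denominator=2)
        times = np.linspace(0, 4, 9)
        traj = clv.forecast("alr", p, np.full(3, 1 / 3), times)
        np.testing.assert_allclose(traj.native[:, 0], 0.5 * times, atol=1e-8)
        np.testing.assert_allclose(traj.native[:, 1], -0.25 * times, atol=1e-8)

    def test_alr_matches_matrix_exponential(self, rng):
        p = clv.ALRParams(rng.normal(0, 0.5, 2), rng.normal(0, 0.5, (2, 2)), denominator=2)
        pi0 = rng.dirichlet(np.ones(3) * 2)
        times = np.linspace(0, 5, 11)
        traj = clv.forecast("alr", p, pi0, times)
        eta0 = clv.alr(pi0, 2).values
        oracle = matrix_exponential_affine(p.A_rel, p.g_rel, eta0, times)
        np.testing.assert_allclose(traj.native, oracle, atol=1e-6)

    def test_alr_at_origin(self, rng):
        p = clv.ALRParams(rng.normal(0, 1, 2), rng.normal(0, 1, (2, 2)),
                          rng.normal(0, 1, (2, 1)), denominator=2)
        out = clv.alr_linear_rhs(np.zeros(2), [1.0], p)
        np.testing.assert_allclose(out, p.g_rel + p.B_rel[:, 0])

    def test_alr_perturbation_response_additive_without_interactions(self, rng):
        p = clv.ALRParams(rng.normal(0, 0.5, 2), np.zeros((2, 2)),
                          rng.normal(0, 1, (2, 1)), denominator=2)
        pi0 = np.full(3, 1 / 3)
        times = np.linspace(0, 2, 5)
        on = clv.forecast("alr", p, pi0, times, schedule=np.ones((5, 1)))
        off = clv.forecast("alr", p, pi0, times)
        np.testing.assert_allclose(
            on.native - off.native, np.outer(times, p.B_rel[:, 0]), atol=1e-8
        )

    def test_linear_constant_when_all_zero(self):
        p = clv.LinearParams(np.zeros(3), np.zeros((3, 3)))
        traj = clv.forecast("linear", p, [0.2, 0.3, 0.5], np.linspace(0, 3, 7))
        np.testing.assert_allclose(traj.native, np.tile([0.2, 0.3, 0.5], (7, 1)))

    def test_linear_matches_matrix_exponential(self, rng):
        p = clv.LinearParams(rng.normal(0, 0.3, 3), rng.normal(0, 0.3, (3, 3)))
        pi0 = rng.dirichlet(np.ones(3))
        times = np.linspace(0, 5, 11)
        traj = clv.forecast("linear", p, pi0, times, rtol=1e-9, atol=1e-12)
        oracle = matrix_exponential_affine(p.A, p.g, pi0, times)
        np.testing.assert_allclose(traj.native, oracle, atol=1e-6)

    def test_linear_derivative_sum_is_affine_not_conserved(self, rng):
        p = clv.LinearParams(rng.normal(0, 1, 3), rng.normal(0, 1, (3, 3)))
        pi = rng.dirichlet(np.ones(3))
        d = clv.linear_rhs(pi, None, p)
        assert d.sum() == pytest.approx(p.g.sum() + p.A.sum(axis=0) @ pi)


class TestGlvToClv:
    def test_degenerate_system_maps_to_zero(self):
        g = clv.GLVParams(np.full(3, 0.4), np.tile([0.1, -0.2, 0.3], (3, 1)),
                          np.tile([0.5], (3, 1)))
        c = clv.glv_to_clv(g, 0)
        assert np.all(c.g_rel == 0) and np.all(c.A_rel == 0) and np.all(c.B_rel == 0)

    def test_commutes_with_change_denominator(self, rng):
        g = clv.GLVParams(rng.normal(0, 1, 4), rng.normal(0, 1, (4, 4)),
                          rng.normal(0, 1, (4, 2)))
        via_change = clv.change_denominator(clv.glv_to_clv(g, 3), 1)
        direct = clv.glv_to_clv(g, 1)
        np.testing.assert_allclose(via_change.g_rel, direct.g_rel, atol=1e-12)
        np.testing.assert_allclose(via_change.A_rel, direct.A_rel, atol=1e-12)
        np.testing.assert_allclose(via_change.B_rel, direct.B_rel, atol=1e-12)


class TestCommunitySizeSnr:
    @pytest.mark.parametrize(
        "var,expect,flag",
        [(1.0, 1.0, False), (0.055, 1 / 0.055, False), (1.10, 1 / 1.10, True)],
    )
    def test_values_and_noise_flag(self, var, expect, flag):
        snr, dominated = clv.community_size_snr(var)
        assert snr == pytest.approx(expect)
        assert dominated is flag

    def test_zero_variance_infinite_snr(self):
        snr, dominated = clv.community_size_snr(0.0)
        assert np.isinf(snr) and not dominated


class TestForecast:
    def test_zero_params_constant_for_every_model(self, rng):
        pi0 = rng.dirichlet(np.ones(3) * 4)
        times = np.linspace(0, 5, 6)
        cases = [
            ("clv", clv.CLVParams(np.zeros(2), np.zeros((2, 3)), denominator=2)),
            ("alr", clv.ALRParams(np.zeros(2), np.zeros((2, 2)), denominator=2)),
            ("glv", clv.GLVParams(np.zeros(3), np.zeros((3, 3)))),
            ("linear", clv.LinearParams(np.zeros(3), np.zeros((3, 3)))),
        ]
        for kind, params in cases:
            traj = clv.forecast(kind, params, pi0, times)
            np.testing.assert_allclose(traj.relative, np.tile(pi0, (6, 1)), atol=1e-9)

    def test_clv_matches_fixed_step_rk4_oracle(self, random_clv_params, rng):
        p = random_clv_params
        pi0 = rng.dirichlet(np.ones(4) * 3)
        times = np.linspace(0, 5, 11)
        traj = clv.forecast("clv", p, pi0, times)
        eta0 = clv.alr(pi0, p.denominator).values
        oracle_eta = rk4(
            lambda t, y: clv.clv_alr_rhs(clv.alr_inverse(y, p.denominator), [0.0], p),
            eta0, times, step=1e-3,
        )
        np.testing.assert_allclose(traj.native, oracle_eta, atol=1e-5)

    def test_clv_trajectory_stays_in_open_simplex(self, random_clv_params, rng):
        pi0 = rng.dirichlet(np.ones(4) * 3)
        traj = clv.forecast("clv", random_clv_params, pi0, np.linspace(0, 10, 21))
        assert np.all(traj.relative > 0)
        np.testing.assert_allclose(traj.relative.sum(axis=1), 1.0, atol=1e-6)

    def test_perturbation_window_equals_chained_segments(self, random_clv_params, rng):
        p = random_clv_params
        pi0 = rng.dirichlet(np.ones(4) * 3)
        times = np.linspace(0, 9, 10)
        u = np.zeros((10, 1))
        u[3:7] = 1.0
        whole = clv.forecast("clv", p, pi0, times, schedule=u)
        state = pi0
        chained = [pi0]
        for a, b, val in [(0, 3, 0.0), (3, 7, 1.0), (7, 9, 0.0)]:
            seg = clv.forecast(
                "clv", p, state, times[a : b + 1],
                schedule=np.full((b - a + 1, 1), val),
            )
            chained.extend(seg.relative[1:])
            state = seg.relative[-1]
        np.testing.assert_allclose(whole.relative, np.array(chained), atol=1e-7)

    def test_failure_carries_partial_trajectory(self):
        # super-exponential blow-up: positive feedback overwhelms the solver
        p = clv.LinearParams([0.0], [[1e8]])
        with pytest.raises(clv.ForecastError) as err, np.errstate(
            over="ignore", invalid="ignore"
        ):
            clv.forecast("linear", p, [1.0], np.linspace(0, 50, 6), max_step=np.inf)
        assert err.value.partial is not None

    def test_rejects_non_increasing_times(self, random_clv_params):
        with pytest.raises(ValueError):
            clv.forecast("clv", random_clv_params, np.full(4, 0.25), [0.0, 0.0, 1.0])
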
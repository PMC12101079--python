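import numpy as np
import pytest
import scipy.integrate
from scipy.stats import binom, poisson

from crnbridge import (
    A_over_g,
    AffineLNARGuiding,
    DegenerateCovarianceError,
    FearnheadGuiding,
    FunctionGuiding,
    GaussianFilterGuiding,
    LNARGuiding,
    MetricEpsGuiding,
    Observation,
    ObservationSet,
    PoissonMixedGuiding,
    ReversedPoissonGuiding,
    TimeScaledGuiding,
    UnitGuiding,
    alpha_eps,
    backward_filter,
    build_example,
    check_greedy,
    cle_coefficients,
    guided_intensities,
    lnar_guiding,
    zero_noise_filter,
)


class TestMetricEps:
    def test_hand_example(self, death_net):
        # d=1, L=1, a=1, v=0, x=2, xi=-1, T+eps-t = 1 -> exp(1.5)
        g = MetricEpsGuiding([[1.0]], [0.0], 1.0, [[1.0]], 1e-6, death_net.xi)
        t = 1.0 + 1e-6 - 1.0  # T + eps - t = 1
        val = alpha_eps(g, 0, t, np.array([2.0]))
        assert val == pytest.approx(np.exp(1.5), rel=1e-9)

    def test_ratio_equals_two_point_log_g_difference(self, gtt_net, rng):
        """Metric jump ratio vs g(t, x+xi)/g(t, x) on 100 random points."""
        a = cle_coefficients(gtt_net, 0.0, [1, 50, 10]).a
        g = MetricEpsGuiding(
            np.eye(3), [1.0, 11.0, 56.0], 1.0, a, 1e-3, gtt_net.xi
        )
        for _ in range(100):
            t = rng.uniform(0, 0.999)
            x = rng.integers(0, 60, size=3)
            for l in range(4):
                two_point = g.log_g(t, x + gtt_net.xi[l]) - g.log_g(t, x)
                assert g.log_ratio(t, x, l) == pytest.approx(two_point, abs=1e-12)

    def test_ratio_one_when_observation_unaffected(self, gtt_net):
        # observing only the protein: mRNA reactions leave the distance alone
        a = cle_coefficients(gtt_net, 0.0, [1, 50, 10]).a
        g = MetricEpsGuiding([[0.0, 0.0, 1.0]], [40.0], 1.0, a, 1e-4, gtt_net.xi)
        assert g.log_ratio(0.3, np.array([1, 20, 30]), 2) == pytest.approx(0.0)

    def test_matches_filter_guiding_with_eps_noise(self, rng):
        """C = eps L a L' in the backward filter gives the metric ratios."""
        net = build_example("death", c=0.5)
        a = np.array([[2.0]])
        eps = 1e-3
        L = np.array([[1.0]])
        obs = ObservationSet(
            [Observation(t=1.0, L=L, v=[20.0], C=eps * L @ a @ L.T, eps=eps)]
        )
        gf = GaussianFilterGuiding(backward_filter(obs, a), net.xi)
        gm = MetricEpsGuiding(L, [20.0], 1.0, a, eps, net.xi)
        for t in [0.0, 0.5, 0.99]:
            for x in [15, 20, 30]:
                assert gf.log_ratio(t, np.array([x]), 0) == pytest.approx(
                    gm.log_ratio(t, np.array([x]), 0), rel=1e-9
                )

    def test_analytic_time_derivative(self, death_net):
        g = MetricEpsGuiding([[1.0]], [20.0], 1.0, [[2.0]], 1e-3, death_net.xi)
        x = np.array([31.0])
        for t in [0.1, 0.6, 0.95]:
            h = 1e-7
            fd = (g.log_g(t + h, x) - g.log_g(t - h, x)) / (2 * h)
            assert g.dt_log_g(t, x) == pytest.approx(fd, rel=1e-5)

    def test_log_g_bounded_on_box(self):
        """Boundedness on [0, T] x box: the change-of-measure condition."""
        net = build_example("death", c=0.5)
        g = MetricEpsGuiding([[1.0]], [20.0], 1.0, [[2.0]], 1e-2, net.xi)
        vals = [
            g.log_g(t, np.array([float(x)]))
            for t in np.linspace(0, 1.0, 30)
            for x in range(0, 51)
        ]
        assert np.all(np.isfinite(vals))


class TestGaussianFilterGuiding:
    def _two_obs(self, rng):
        net = build_example("gtt")
        a = cle_coefficients(net, 0.0, [1, 50, 10]).a + 0.1 * np.eye(3)
        o1 = Observation(t=0.5, L=[[0.0, 1.0, 0.0]], v=[8.0], C=[[0.05]])
        o2 = Observation(t=1.0, L=np.eye(3), v=[1.0, 11.0, 56.0], C=0.01 * np.eye(3))
        obs = ObservationSet([o1, o2])
        return net, GaussianFilterGuiding(backward_filter(obs, a), net.xi)

    def test_analytic_dt_log_g_matches_fd(self, rng):
        net, g = self._two_obs(rng)
        x = np.array([1, 9, 40])
        for t in [0.1, 0.45, 0.8]:
            h = 1e-7
            fd = (g.log_g(t + h, x) - g.log_g(t - h, x)) / (2 * h)
            assert g.dt_log_g(t, x) == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_interior_jump_constant(self, rng):
        net, g = self._two_obs(rng)
        assert g.log_jump(0, None) == pytest.approx(-0.5 * 8.0**2 / 0.05)

    def test_block_exponents_match_scalar_ratios(self, rng):
        net, g = self._two_obs(rng)
        x = np.array([1, 9, 40])
        ts = np.array([0.1, 0.3, 0.49])
        block = g.log_ratio_block(ts, x, 0)
        for l in range(4):
            for j, t in enumerate(ts):
                assert block[l, j] == pytest.approx(g.log_ratio(t, x, l, 0))


class TestFearnhead:
    def test_collapses_to_noise_density_at_T(self, death_net):
        g = FearnheadGuiding(death_net, [[1.0]], [30.0], 1.0, [[0.3]])
        from scipy.stats import norm

        val = g.log_g(1.0, np.array([31.0]))
        assert val == pytest.approx(norm.logpdf(30.0, 31.0, np.sqrt(0.3)))

    def test_death_moments(self, death_net):
        # mean x - c x (T-t); variance c x (T-t) + C
        g = FearnheadGuiding(death_net, [[1.0]], [30.0], 1.0, [[0.1]])
        from scipy.stats import norm

        t, x = 0.4, 40.0
        mean = x - 0.5 * x * 0.6
        var = 0.5 * x * 0.6 + 0.1
        assert g.log_g(t, np.array([x])) == pytest.approx(
            norm.logpdf(30.0, mean, np.sqrt(var))
        )

    def test_degenerate_covariance_raises(self, death_net):
        g = FearnheadGuiding(death_net, [[1.0]], [30.0], 1.0, [[0.0]])
        with pytest.raises(DegenerateCovarianceError):
            g.log_g(1.0, np.array([0.0]))  # all rates vanish and C = 0

    def test_unimodal_in_x_near_conditioning_mean(self, death_net):
        g = FearnheadGuiding(death_net, [[1.0]], [30.0], 1.0, [[0.3]])
        vals = [g.log_g(0.5, np.array([float(x)])) for x in range(20, 50)]
        best = 20 + int(np.argmax(vals))
        assert 33 <= best <= 42  # near v / (1 - c (T-t)) = 40
        assert np.all(np.isfinite(vals))


class TestLNAR:
    def test_zero_rate_network_reduces_to_noise_density(self):
        from crnbridge import MassAction, Reaction, ReactionNetwork

        net = ReactionNetwork(["A"], [Reaction(xi=(-1,), rate=MassAction(0.0, {0: 1}))])
        g = LNARGuiding(net, [[1.0]], [4.0], 1.0, [[0.5]])
        from scipy.stats import norm

        assert g.log_g(0.0, np.array([4.0])) == pytest.approx(
            norm.logpdf(4.0, 4.0, np.sqrt(0.5)), rel=1e-9
        )

    def test_death_mean_is_exact_exponential_decay(self, death_net):
        g = lnar_guiding(death_net, [[1.0]], [30.0], 1.0, [[1e-5]])
        assert isinstance(g, AffineLNARGuiding)
        for t, x in [(0.0, 50.0), (0.5, 37.0)]:
            z, V = g.mean_cov(t, np.array([x]))
            assert z[0] == pytest.approx(x * np.exp(-0.5 * (1 - t)), rel=1e-8)
            # LNA variance of the death process matches the binomial variance
            p = np.exp(-0.5 * (1 - t))
            assert V[0, 0] == pytest.approx(x * p * (1 - p), rel=1e-8)

    def test_rk4_matches_stiff_integrator_on_enzyme(self, enzyme_net):
        g = LNARGuiding(
            enzyme_net, np.eye(4), [0.0, 15, 5, 27], 1.0, 1e-5 * np.eye(4),
            steps_per_unit=120,
        )
        x0 = np.array([12.0, 10, 10, 10])
        z, V = g.mean_cov(0.0, x0)

        d = 4

        def rhs(s, u):
            zz = np.maximum(u[:d], 0)
            Vv = u[d:].reshape(d, d)
            lam = enzyme_net.rates_continuous(s, zz)
            b = lam @ enzyme_net.xi
            a = (enzyme_net.xi.T * lam) @ enzyme_net.xi
            J = enzyme_net.drift_jacobian(s, zz)
            return np.concatenate([b, (Vv @ J.T + J @ Vv + a).ravel()])

        sol = scipy.integrate.solve_ivp(
            rhs, (0, 1.0), np.concatenate([x0, np.zeros(16)]),
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        z_ref = sol.y[:d, -1]
        V_ref = sol.y[d:, -1].reshape(d, d)
        np.testing.assert_allclose(z, z_ref, atol=2e-4)
        np.testing.assert_allclose(V, V_ref, atol=2e-4)

    def test_covariance_psd_on_random_gtt_states(self, gtt_net, rng):
        g = lnar_guiding(gtt_net, np.eye(3), [1.0, 11, 56], 1.0, 0.01 * np.eye(3))
        for _ in range(100):
            t = rng.uniform(0, 0.99)
            x = rng.integers(0, 60, size=3).astype(float)
            _, V = g.mean_cov(t, x)
            assert np.min(np.linalg.eigvalsh(V)) > -1e-8
            np.testing.assert_allclose(V, V.T, atol=1e-10)


class TestPoissonGuidings:
    def test_reversed_poisson_pmf_factor(self, death_net):
        g = ReversedPoissonGuiding(30.0, 1.0, 15.0, death_net.xi)
        for t, x in [(0.0, 50), (0.7, 34)]:
            k = x - 30
            assert g.log_g(t, np.array([x])) == pytest.approx(
                poisson.logpmf(k, 15.0 * (1 - t))
            )

    def test_blocked_at_target(self, death_net):
        g = ReversedPoissonGuiding(30.0, 1.0, 15.0, death_net.xi)
        assert g.log_ratio(0.5, np.array([30]), 0) == -np.inf

    def test_mixed_terminal_value(self, enzyme_net):
        v = np.array([0.0, 15, 5, 27])
        a3 = cle_coefficients(enzyme_net, 0.0, [12, 10, 10, 10]).a[:3, :3]
        g = PoissonMixedGuiding(v, 1.0, a3, 30.0, 1e-4, enzyme_net.xi, y_index=3)
        # at the target with t = T the guiding equals one
        assert g.log_g(1.0, v) == pytest.approx(0.0)

    def test_mixed_blocks_production_past_target(self, enzyme_net):
        v = np.array([0.0, 15, 5, 27])
        a3 = cle_coefficients(enzyme_net, 0.0, [12, 10, 10, 10]).a[:3, :3]
        g = PoissonMixedGuiding(v, 1.0, a3, 30.0, 1e-4, enzyme_net.xi, y_index=3)
        x = np.array([2.0, 14, 6, 27])  # product already at target
        assert g.log_ratio(0.5, x, 2) == -np.inf  # catalysis blocked
        assert np.isfinite(g.log_ratio(0.5, x, 0))
        assert g.log_g(0.5, np.array([2.0, 14, 6, 28])) == -np.inf

    def test_mixed_poisson_factor_is_poisson_pmf(self, enzyme_net):
        v = np.array([0.0, 15, 5, 27])
        a3 = cle_coefficients(enzyme_net, 0.0, [12, 10, 10, 10]).a[:3, :3]
        theta = 30.0
        g = PoissonMixedGuiding(v, 1.0, a3, theta, 1e-4, enzyme_net.xi, y_index=3)
        x = np.array([0.0, 15, 5, 20])  # z-part at target: metric factor = 0
        t = 0.4
        assert g.log_g(t, x) == pytest.approx(
            poisson.logpmf(7, theta * (1 - t))
        )


class TestZeroNoiseAndGreedy:
    def test_single_obs_reduces_to_metric_eps_zero(self, death_net):
        obs = ObservationSet([Observation(t=1.0, L=[[1.0]], v=[30.0], C=None)])
        g = zero_noise_filter(obs, np.array([[2.0]]), death_net.xi)
        assert isinstance(g, MetricEpsGuiding) and g.eps == 0.0 and g.requires_hit

    def test_ratio_vanishes_for_distance_increasing_move_near_T(self, death_net):
        obs = ObservationSet([Observation(t=1.0, L=[[1.0]], v=[30.0], C=None)])
        g = zero_noise_filter(obs, np.array([[2.0]]), death_net.xi)
        # at x = v the only move increases the distance; alpha -> 0 as t -> T
        assert g.log_ratio(1.0 - 1e-9, np.array([30]), 0) < -1e6

    def test_greedy_holds_for_death_above_target(self, death_net):
        obs = ObservationSet([Observation(t=1.0, L=[[1.0]], v=[30.0], C=None)])
        probe = [(x,) for x in range(31, 51)]
        rep = check_greedy(death_net, obs, np.array([[1.0]]), probe)
        assert rep["all"]

    def test_greedy_fails_for_increase_only_network(self):
        from crnbridge import MassAction, Reaction, ReactionNetwork

        net = ReactionNetwork(["A"], [Reaction(xi=(1,), rate=MassAction(1.0, {0: 1}))])
        obs = ObservationSet([Observation(t=1.0, L=[[1.0]], v=[3.0], C=None)])
        rep = check_greedy(net, obs, np.array([[1.0]]), [(5,), (8,)])
        assert not rep["all"]


class TestOperatorIdentities:
    def test_unit_guiding_leaves_intensities_unchanged(self, gtt_net):
        g = UnitGuiding(gtt_net.xi, 1.0)
        x = np.array([1, 50, 10])
        np.testing.assert_allclose(
            guided_intensities(gtt_net, g, 0.2, x), gtt_net.rates(0.2, x)
        )
        assert A_over_g(gtt_net, g, 0.2, x) == pytest.approx(0.0)

    def test_exact_h_is_space_time_harmonic(self, death_net):
        """A h / h = 0 for the true conditional probability h."""
        h = FunctionGuiding(
            lambda t, x: binom.logpmf(30, int(round(x[0])), np.exp(-0.5 * (1 - t))),
            death_net.xi,
            1.0,
            singular=1.0,
        )
        h.fd_step = 1e-9
        for t, x in [(0.2, 45), (0.5, 38), (0.8, 33)]:
            lam_total = 0.5 * x
            assert abs(A_over_g(death_net, h, t, np.array([x]))) < 1e-5 * lam_total

    def test_metric_eps_intensities_match_lemma_form(self, gtt_net, rng):
        a = cle_coefficients(gtt_net, 0.0, [1, 50, 10]).a
        g = MetricEpsGuiding(np.eye(3), [1.0, 11, 56], 1.0, a, 1e-3, gtt_net.xi)
        for _ in range(20):
            t = rng.uniform(0, 0.99)
            x = rng.integers(1, 60, size=3)
            lam = gtt_net.rates(t, x)
            lam_g = guided_intensities(gtt_net, g, t, x)
            for l in range(4):
                expected = lam[l] * alpha_eps(g, l, t, x)
                assert lam_g[l] == pytest.approx(expected, rel=1e-12)

    def test_time_scaling_leaves_intensities_invariant(self, death_net):
        base = MetricEpsGuiding([[1.0]], [30.0], 1.0, [[2.0]], 1e-3, death_net.xi)
        scaled = TimeScaledGuiding(base, lambda t: 1 + t * t, lambda t: 2 * t)
        x = np.array([40])
        # moderate guided rates only: at strongly forced (t, x) the constant
        # d/dt log c drowns in the O(1e20) intensity sum in double precision
        for t in [0.1, 0.3, 0.5]:
            np.testing.assert_allclose(
                guided_intensities(death_net, scaled, t, x),
                guided_intensities(death_net, base, t, x),
                rtol=1e-12,
            )
            # Ag/g picks up exactly d/dt log c
            diff = A_over_g(death_net, scaled, t, x) - A_over_g(death_net, base, t, x)
            assert diff == pytest.approx(2 * t / (1 + t * t), rel=1e-6)
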
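import numpy as np
import pytest
from scipy.stats import binom, chisquare

from crnbridge import (
    DeltaNotApplicableError,
    FunctionGuiding,
    MetricEpsGuiding,
    Observation,
    ObservationSet,
    ReversedPoissonGuiding,
    ThinningConfig,
    TimeScaledGuiding,
    UnitGuiding,
    assemble_weight,
    delta_window,
    estimate_transition_probability,
    forward_simulate,
    log_E_g,
    log_psi,
    psi_integral_direct,
    simulate_guided,
    zero_noise_filter,
)


def _obs1(v, T=1.0):
    return ObservationSet([Observation(t=T, L=[[1.0]], v=[float(v)])])


class TestDeltaWindow:
    def test_eta_near_one_gives_vanishing_window(self):
        d = delta_window(0.0, 1.0, 1e-5, 0.999999, 0.0, 1.0)
        assert 0 < d < 1e-5 * 10

    def test_hand_value(self):
        # T + eps - t = 1, d^2 difference = -1, eta = 0.9
        d = delta_window(1e-5, 1.0, 1e-5, 0.9, 0.0, 1.0)
        assert d == pytest.approx(0.17405, abs=1e-4)

    def test_distance_increasing_move_not_applicable(self):
        with pytest.raises(DeltaNotApplicableError):
            delta_window(0.0, 1.0, 1e-5, 0.9, 2.0, 1.0)

    def test_empirical_acceptance_meets_target(self, death_net):
        """Candidates proposed with the window bound accept at >= eta - 0.02."""
        eta = 0.9
        g = MetricEpsGuiding([[1.0]], [30.0], 1.0, [[50.0]], 1e-5, death_net.xi)
        rng = np.random.default_rng(8)
        acc = tot = 0
        x = np.array([40])
        t = 0.2
        lam = death_net.rates(t, x)
        while tot < 10_000:
            d = g.propose_delta(t, x, lam, 0, eta)
            t1 = min(t + d, 1.0)
            bounds, _, _ = g.ratio_bounds(t, t1, x, 0)
            bar = lam * bounds
            tau = rng.exponential(1.0 / bar.sum())
            if t + tau <= t1:
                tot += 1
                rate = lam[0] * np.exp(g.log_ratio(t + tau, x, 0))
                if rng.random() * bar[0] < rate:
                    acc += 1
        assert acc / tot >= eta - 0.02


class TestGuidedSimulation:
    def test_unit_guiding_reproduces_forward_law(self, death_net):
        """g = 1: guided simulation is the unconditioned process."""
        g = UnitGuiding(death_net.xi, 1.0)
        rng = np.random.default_rng(6)
        n = 6000
        sim = np.array(
            [
                simulate_guided(death_net, g, _obs1(30), [50], rng).path.terminal_state[0]
                for _ in range(n)
            ]
        )
        q = binom.pmf(np.arange(51), 50, np.exp(-0.5))
        edges = np.concatenate(([0], np.arange(24, 38), [51]))
        obs_counts = np.histogram(sim, bins=edges)[0]
        exp_counts = (
            np.array([q[a:b].sum() for a, b in zip(edges[:-1], edges[1:])]) * n
        )
        assert chisquare(obs_counts, exp_counts).pvalue > 0.001

    def test_zero_noise_death_hits_or_rejects(self, death_net):
        """Noiseless bridge: every non-rejected path ends exactly at v."""
        obs = ObservationSet([Observation(t=1.0, L=[[1.0]], v=[30.0], C=None)])
        g = zero_noise_filter(obs, np.array([[0.05]]), death_net.xi)
        rng = np.random.default_rng(2)
        hits = rejects = 0
        for _ in range(300):
            wp = simulate_guided(death_net, g, obs, [50], rng)
            if wp.rejected:
                rejects += 1
            else:
                assert wp.hit and wp.path.terminal_state[0] == 30
                hits += 1
        assert hits + rejects == 300
        assert hits >= 290  # the greedy forcing all but guarantees the hit

    def test_eps_softening_controls_hit_rate(self, death_net):
        """Hit rates increase as the conditioning is softened less."""
        rates = []
        for eps in [1e-1, 1e-2, 1e-4]:
            g = MetricEpsGuiding([[1.0]], [30.0], 1.0, [[50.0]], eps, death_net.xi)
            rng = np.random.default_rng(5)
            hits = sum(
                simulate_guided(death_net, g, _obs1(30), [50], rng).hit
                for _ in range(400)
            )
            rates.append(hits / 400)
        assert rates[0] < rates[1] - 0.02
        assert rates[2] >= rates[1] - 0.03  # saturates once eps is small

    def test_event_budget_marks_rejection(self, death_net):
        g = MetricEpsGuiding([[1.0]], [10.0], 1.0, [[50.0]], 1e-5, death_net.xi)
        rng = np.random.default_rng(1)
        cfg = ThinningConfig(max_events=3)
        wp = simulate_guided(death_net, g, _obs1(10), [50], rng, cfg)
        assert wp.rejected and wp.reason == "event-budget"

    def test_absorbing_state_freezes_path(self, enzyme_net):
        g = UnitGuiding(enzyme_net.xi, 1.0)
        obs = ObservationSet(
            [Observation(t=1.0, L=np.eye(4), v=[0.0, 5, 0, 3])]
        )
        rng = np.random.default_rng(0)
        wp = simulate_guided(enzyme_net, g, obs, [0, 5, 0, 3], rng)
        assert wp.hit and wp.path.n_jumps == 0


class TestWeights:
    def test_unit_guiding_gives_zero_log_psi(self, death_net, rng):
        g = UnitGuiding(death_net.xi, 1.0)
        path = forward_simulate(death_net, [50], 0.0, 1.0, rng)
        assert log_psi(path, g, death_net) == pytest.approx(0.0, abs=1e-12)

    def test_product_form_equals_direct_integral(self, death_net):
        """Telescoped product vs direct quadrature of Ag/g on random paths."""
        g = MetricEpsGuiding([[1.0]], [30.0], 1.0, [[50.0]], 1e-3, death_net.xi)
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 20:
            path = forward_simulate(death_net, [50], 0.0, 1.0, rng)
            lp = log_psi(path, g, death_net)
            direct = (
                g.log_g(0.0, [50], 0)
                - g.log_g(1.0, path.terminal_state, 0)
                + psi_integral_direct(path, g, death_net)
            )
            # unconditioned paths can stray far from v, where both forms are
            # astronomically large; compare relatively there
            assert lp == pytest.approx(direct, abs=1e-6, rel=1e-9)
            checked += 1

    def test_weight_invariant_under_time_rescaled_guiding(self, death_net):
        """g -> c(t) g with c(t) = 2 + sin t leaves the path weight unchanged."""
        base = MetricEpsGuiding([[1.0]], [30.0], 1.0, [[50.0]], 1e-3, death_net.xi)
        scaled = TimeScaledGuiding(
            base, lambda t: 2 + np.sin(t), lambda t: np.cos(t)
        )
        rng = np.random.default_rng(9)
        for _ in range(10):
            wp = simulate_guided(death_net, base, _obs1(30), [50], rng)
            if not wp.hit:
                continue
            w1 = assemble_weight(wp, base, death_net)
            w2 = assemble_weight(wp, scaled, death_net)
            assert w2 == pytest.approx(w1, abs=1e-10)

    def test_exact_h_gives_constant_weights(self, death_net):
        """With g = h the importance weight is exactly h(0, x0) path by path."""
        v, c, T = 30, 0.5, 1.0

        def log_h(t, x):
            return binom.logpmf(v, int(round(x[0])), np.exp(-c * (T - t)))

        gh = FunctionGuiding(log_h, death_net.xi, T, singular=T)
        gh.requires_hit = True
        rng = np.random.default_rng(11)
        lws = []
        for _ in range(40):
            wp = simulate_guided(death_net, gh, _obs1(v), [50], rng)
            if wp.hit:
                lws.append(assemble_weight(wp, gh, death_net))
        lws = np.array(lws)
        assert len(lws) > 30
        assert np.var(np.exp(lws - log_h(0, [50]))) < 1e-10
        assert lws.mean() == pytest.approx(log_h(0, [50]), abs=1e-8)

    def test_h_transform_reproduces_conditioned_marginal(self, death_net):
        """X(1/2) under exact-h guiding matches the analytic bridge law."""
        v, c, T = 30, 0.5, 1.0

        def log_h(t, x):
            return binom.logpmf(v, int(round(x[0])), np.exp(-c * (T - t)))

        gh = FunctionGuiding(log_h, death_net.xi, T, singular=T)
        gh.requires_hit = True
        rng = np.random.default_rng(13)
        n = 700
        mids = np.array(
            [
                simulate_guided(death_net, gh, _obs1(v), [50], rng).path.state_at(0.5)[0]
                for _ in range(n)
            ]
        )
        ys = np.arange(v, 51)
        p_half = np.exp(-c * 0.5)
        w = binom.pmf(ys, 50, p_half) * binom.pmf(v, ys, p_half)
        w /= w.sum()
        # pool tails so expected counts exceed ~5
        keep = w * n >= 5
        edges = [v] + list(ys[keep]) + [51]
        edges = sorted(set(edges))
        obs_c = np.histogram(mids, bins=edges)[0]
        exp_c = np.array(
            [w[(ys >= a) & (ys < b)].sum() for a, b in zip(edges[:-1], edges[1:])]
        ) * n
        assert chisquare(obs_c, exp_c).pvalue > 0.001

    def test_martingale_mean_one(self, death_net):
        """E[E^g(T)] = 1 over unconditioned paths (change-of-measure validity)."""
        g = MetricEpsGuiding([[1.0]], [30.0], 1.0, [[50.0]], 1e-3, death_net.xi)
        rng = np.random.default_rng(21)
        n = 10_000
        vals = np.empty(n)
        for i in range(n):
            path = forward_simulate(death_net, [50], 0.0, 1.0, rng)
            vals[i] = log_E_g(path, g, death_net)
        E = np.exp(vals)
        assert abs(E.mean() - 1.0) < 3 * E.std() / np.sqrt(n)


class TestEstimator:
    def test_unit_guiding_counts_hits(self, death_net):
        g = UnitGuiding(death_net.xi, 1.0)
        rng = np.random.default_rng(3)
        est = estimate_transition_probability(
            death_net, g, _obs1(30), [50], 400, rng
        )
        assert est["p_hat"] == pytest.approx(est["hit_fraction"])

    def test_poisson_guiding_matches_binomial(self, death_net):
        """Benchmark identity: p_hat(30) near Binom(50, e^{-1/2}) pmf."""
        g = ReversedPoissonGuiding(30.0, 1.0, 15.0, death_net.xi)
        rng = np.random.default_rng(17)
        est = estimate_transition_probability(
            death_net, g, _obs1(30), [50], 2000, rng
        )
        q = binom.pmf(30, 50, np.exp(-0.5))
        assert abs(est["p_hat"] - q) < 4 * est["se"]
        assert est["hit_fraction"] > 0.99

    def test_all_rejected_warns(self, death_net):
        g = MetricEpsGuiding([[1.0]], [10.0], 1.0, [[50.0]], 1e-5, death_net.xi)
        rng = np.random.default_rng(1)
        cfg = ThinningConfig(max_events=2)
        with pytest.warns(UserWarning):
            est = estimate_transition_probability(
                death_net, g, _obs1(10), [50], 5, rng, cfg
            )
        assert est["p_hat"] == 0.0
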
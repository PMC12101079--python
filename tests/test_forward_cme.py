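import numpy as np
import pytest
from scipy.stats import binom, chisquare

from crnbridge import (
    MassAction,
    Reaction,
    ReactionNetwork,
    BoundViolationError,
    box_states,
    cme_transition,
    forward_simulate,
    reachable_states,
    simulate_thinning,
    TruncationError,
)
from crnbridge.forward import sample_terminal_states


def _death_binom_bins(x0, p, counts, n):
    """Pool binomial cells so expected counts stay above ~5."""
    q = binom.pmf(np.arange(x0 + 1), x0, p)
    lo = int(np.searchsorted(np.cumsum(q), 5.0 / n))
    hi = int(np.searchsorted(np.cumsum(q), 1 - 5.0 / n))
    edges = [0] + list(range(lo, hi)) + [x0 + 1]
    obs = np.histogram(counts, bins=edges)[0]
    exp = np.array([q[a:b].sum() for a, b in zip(edges[:-1], edges[1:])]) * n
    return obs, exp


class TestForward:
    def test_absorbing_start_gives_no_jumps(self, enzyme_net, rng):
        path = forward_simulate(enzyme_net, [0, 5, 0, 3], 0.0, 1.0, rng)
        assert path.n_jumps == 0
        np.testing.assert_array_equal(path.terminal_state, [0, 5, 0, 3])

    def test_gtt_gene_count_constant(self, gtt_net, rng):
        for _ in range(5):
            path = forward_simulate(gtt_net, [1, 50, 10], 0.0, 0.3, rng)
            assert np.all(path.states[:, 0] == 1)

    def test_death_terminal_matches_binomial(self, death_net):
        """Goodness of fit of X(T) against Binom(x0, e^{-cT}), n = 10^4."""
        rng = np.random.default_rng(42)
        n = 10_000
        term = sample_terminal_states(death_net, [50], 0.0, 1.0, n, rng)[:, 0]
        p = np.exp(-0.5)
        assert abs(term.mean() - 50 * p) < 3 * np.sqrt(50 * p * (1 - p) / n)
        obs, exp = _death_binom_bins(50, p, term, n)
        assert chisquare(obs, exp).pvalue > 0.001

    def test_consecutive_states_differ_by_one_reaction(self, enzyme_net, rng):
        path = forward_simulate(enzyme_net, [12, 10, 10, 10], 0.0, 0.5, rng)
        xi_set = {tuple(v) for v in enzyme_net.xi}
        for j in range(path.n_jumps):
            assert tuple(path.states[j + 1] - path.states[j]) in xi_set


class TestThinning:
    def test_constant_rates_reduce_to_next_reaction(self, death_net):
        rng = np.random.default_rng(7)
        n = 4000
        term = np.empty(n)
        for i in range(n):
            path = simulate_thinning(
                death_net, [20], 0.0, 1.0, rng, bounds=lambda x: 0.5 * x
            )
            term[i] = path.terminal_state[0]
        p = np.exp(-0.5)
        assert abs(term.mean() - 20 * p) < 3 * np.sqrt(20 * p * (1 - p) / n)

    def test_sinusoidal_death_matches_time_dependent_cme(self):
        # c(t) = c (1 + 0.5 sin t), dominated by 1.5 c x
        c = 0.5
        net = ReactionNetwork(
            ["N"],
            [
                Reaction(
                    xi=(-1,),
                    rate=lambda t, x: c * (1 + 0.5 * np.sin(t)) * float(x[0]),
                )
            ],
        )
        res = cme_transition(net, [(i,) for i in range(21)], [20], 1.0)
        mean_exact = float(np.array([s[0] for s in res["states"]]) @ res["p"])
        rng = np.random.default_rng(3)
        n = 3000
        term = np.empty(n)
        for i in range(n):
            path = simulate_thinning(
                net, [20], 0.0, 1.0, rng, bounds=lambda x: np.array([1.5 * c * x[0]])
            )
            term[i] = path.terminal_state[0]
        # mean jump count = x0 - mean X(T) for a pure death process
        se = term.std() / np.sqrt(n)
        assert abs(term.mean() - mean_exact) < 3 * se

    def test_bound_violation_raises(self):
        net = ReactionNetwork(
            ["N"], [Reaction(xi=(-1,), rate=lambda t, x: (1 + t) * float(x[0]))]
        )
        rng = np.random.default_rng(0)
        with pytest.raises(BoundViolationError):
            for _ in range(50):
                simulate_thinning(
                    net, [30], 0.0, 1.0, rng, bounds=lambda x: np.array([1.1 * x[0]])
                )


class TestCME:
    def test_zero_time_is_point_mass(self, death_net):
        res = cme_transition(death_net, [(i,) for i in range(6)], [5], 0.0)
        expected = np.zeros(6)
        expected[-1] = 1.0
        np.testing.assert_array_equal(res["p"], expected)

    def test_substochastic_probabilities(self, gtt_net):
        states = box_states([1, 0, 5], [1, 8, 15])
        res = cme_transition(gtt_net, states, [1, 4, 10], 0.01, leak_tol=1.0)
        assert np.all(res["p"] >= 0) and res["p"].sum() <= 1 + 1e-12

    def test_death_matches_binomial_pmf(self, death_net):
        res = cme_transition(death_net, [(i,) for i in range(51)], [50], 1.0)
        q = binom.pmf(np.arange(51), 50, np.exp(-0.5))
        np.testing.assert_allclose(res["p"], q, atol=1e-10)

    def test_truncation_leak_detected(self, gtt_net):
        states = box_states([1, 40, 5], [1, 60, 15])  # far too small a box
        with pytest.raises(TruncationError):
            cme_transition(gtt_net, states, [1, 50, 10], 1.0)

    def test_enzyme_small_instance_matches_empirical(self, enzyme_net):
        x0 = [3, 2, 2, 0]
        states = reachable_states(enzyme_net, x0)
        res = cme_transition(enzyme_net, states, x0, 1.0)
        rng = np.random.default_rng(11)
        n = 20_000
        term = sample_terminal_states(enzyme_net, x0, 0.0, 1.0, n, rng)
        index = res["index"]
        counts = np.zeros(len(states))
        for row in term:
            counts[index[tuple(row)]] += 1
        freq = counts / n
        se = np.sqrt(res["p"] * (1 - res["p"]) / n)
        mask = res["p"] > 1e-4
        assert np.all(np.abs(freq[mask] - res["p"][mask]) < 4 * se[mask] + 1e-12)
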
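"""Temporal-network simulator: sampling primitives, invariants, mechanisms."""

import itertools

import numpy as np
import pytest
from scipy import stats

from netmse.io_contacts import CommunityMap
from netmse.netmodel import (ModelConfig, choose_active_nodes, choose_partner,
                             draw_step_counts, generate_network,
                             generate_null_network,
                             preferential_activation_sample, sample_activities)
from netmse.network_series import (aggregate, estimate_mixing_ratio,
                                   extract_series, gini, modularity,
                                   power_law_tail_exponent)
from netmse.periodic import PeriodicSeriesConfig, solve_rates


def planted_map(config):
    labels = config.community_labels()
    return CommunityMap({i: int(labels[i]) for i in range(config.N)})


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(N=10, K=100), dict(W=500), dict(rho_K=0.0), dict(p=1.5),
        dict(n_communities=3), dict(activation="other"),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)

    def test_community_blocks_equal_sized(self):
        cfg = ModelConfig(n_communities=5)
        labels = cfg.community_labels()
        assert np.bincount(labels).tolist() == [20] * 5


class TestSampleActivities:
    def test_uniform_spec(self):
        assert sample_activities(("uniform", 0.5), 3).tolist() == [0.5] * 3

    def test_power_law_support(self):
        a = sample_activities(("powerlaw", 2.5, 1e-3), 10_000, 0)
        assert a.min() >= 1e-3 and a.max() <= 1.0

    def test_power_law_exponent_recovered(self):
        a = sample_activities(("powerlaw", 2.5, 1e-3), 100_000, 3)
        est = power_law_tail_exponent(a, 1e-3, 1.0)
        assert est == pytest.approx(2.5, abs=0.1)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            sample_activities(("powerlaw", 0.5, 1e-3), 10)
        with pytest.raises(ValueError):
            sample_activities(("uniform", -1.0), 10)


class TestDrawStepCounts:
    def test_case2_rates_solve_by_hand(self):
        cfg_K = PeriodicSeriesConfig(Z=1000, T=2000, rho=0.2, n=5, t_h=100,
                                     ratio=3.0)
        prof = solve_rates(cfg_K)
        assert prof.lambda_l == pytest.approx(5 / 3)
        assert prof.lambda_h == pytest.approx(5.0)
        cfg_L = PeriodicSeriesConfig(Z=9000, T=2000, rho=0.8, n=5, t_h=100,
                                     ratio=1.0)
        prof_L = solve_rates(cfg_L)
        assert prof_L.lambda_h == prof_L.lambda_l == pytest.approx(5.625)

    def test_budget_series_conserve_exactly_in_expectation(self):
        """The drawn K(t), L(t) budgets (before any registry clamping) are
        unbiased for the targets K and L."""
        config = ModelConfig()
        rng = np.random.default_rng(14)
        sums = np.array([[k.sum(), l.sum()]
                         for k, l in (draw_step_counts(config, rng)
                                      for _ in range(200))])
        se = sums.std(axis=0, ddof=1) / np.sqrt(len(sums))
        assert abs(sums[:, 0].mean() - config.K) < 3 * se[0]
        assert abs(sums[:, 1].mean() - config.L) < 3 * se[1]


class TestChooseActiveNodes:
    def test_uniform_activities_give_uniform_subsets(self):
        rng = np.random.default_rng(2)
        acts = np.ones(4)
        counts = {frozenset(c): 0 for c in itertools.combinations(range(4), 2)}
        n_draws = 10_000
        for _ in range(n_draws):
            counts[frozenset(choose_active_nodes(acts, 2, rng))] += 1
        res = stats.chisquare(list(counts.values()))
        assert res.pvalue > 0.01

    def test_degenerate_activity_forces_node(self):
        acts = np.array([1.0, 0.0, 0.0, 0.0])
        rng = np.random.default_rng(3)
        assert choose_active_nodes(acts, 1, rng) == [0]

    def test_count_equal_N_returns_all(self):
        got = choose_active_nodes(np.ones(5), 5, np.random.default_rng(0))
        assert sorted(got) == [0, 1, 2, 3, 4]


class TestChoosePartner:
    def test_p_zero_stays_intra(self):
        comm = np.array([0, 0, 0, 1, 1, 1])
        rng = np.random.default_rng(4)
        for _ in range(200):
            j = choose_partner(0, set(), comm, 0.0, rng, 6)
            assert comm[j] == 0

    def test_p_one_is_uniform(self):
        rng = np.random.default_rng(5)
        comm = np.array([0, 0, 1, 1])
        counts = np.zeros(4)
        for _ in range(9000):
            counts[choose_partner(0, set(), comm, 1.0, rng, 4)] += 1
        assert stats.chisquare(counts[1:]).pvalue > 0.01

    def test_mixing_odds_two_communities_of_five(self):
        """p=0.5: inter weight 5*0.5 = 2.5 vs intra weight 4 for the chooser."""
        comm = np.array([0] * 5 + [1] * 5)
        rng = np.random.default_rng(6)
        n_inter = sum(comm[choose_partner(0, set(), comm, 0.5, rng, 10)] == 1
                      for _ in range(20_000))
        expect = 2.5 / 6.5
        sd = np.sqrt(expect * (1 - expect) / 20_000)
        assert abs(n_inter / 20_000 - expect) < 4 * sd

    def test_saturation_returns_none(self):
        assert choose_partner(0, {1, 2}, None, 1.0,
                              np.random.default_rng(0), 3) is None


class TestPreferentialActivation:
    def test_two_link_frequencies(self):
        rng = np.random.default_rng(7)
        w = np.array([3.0, 1.0])
        hits = sum(preferential_activation_sample(w, 1, rng) == [0]
                   for _ in range(10_000))
        sd = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(hits / 10_000 - 0.75) < 4 * sd

    def test_equal_weights_uniform_inclusion(self):
        rng = np.random.default_rng(8)
        counts = np.zeros(4)
        for _ in range(8000):
            for idx in preferential_activation_sample(np.ones(4), 2, rng):
                counts[idx] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_count_above_registry_rejected(self):
        with pytest.raises(ValueError):
            preferential_activation_sample(np.ones(2), 3,
                                           np.random.default_rng(0))


class TestGenerateNetwork:
    def test_series_invariants_and_round_trip(self, sim_network):
        s = sim_network.series
        assert np.all(s.K_t <= s.W_t)
        assert s.W == s.K + s.L
        ext = extract_series(sim_network.events, T=2000)
        assert np.array_equal(ext.K_t, s.K_t)
        assert np.array_equal(ext.W_t, s.W_t)

    def test_first_event_equals_registry_creation(self, sim_network):
        first_seen = {}
        for t, i, j in sim_network.events:
            first_seen.setdefault((i, j), t)
        for pair, created in zip(sim_network.link_pairs,
                                 sim_network.link_created):
            assert first_seen[pair] == created

    def test_reactivations_bounded_by_registry(self, sim_network):
        """L(t) never exceeds the number of links created before step t."""
        created_before = np.zeros(2001, dtype=int)
        for t in sim_network.link_created:
            created_before[t] += 1
        cum = np.cumsum(created_before)
        L_t = sim_network.series.L_t
        for t in range(1, 2001):
            assert L_t[t - 1] <= cum[t - 1]

    def test_weight_totals_match_events(self, sim_network):
        assert sim_network.link_weights.sum() == sim_network.events.n_events

    def test_seed_determinism(self):
        a = generate_network(ModelConfig(seed=9))
        b = generate_network(ModelConfig(seed=9))
        assert a.events.events == b.events.events

    def test_saturation_truncates_with_counter(self):
        cfg = ModelConfig(N=4, K=6, W=24, T=20, rho_K=0.25, rho_L=0.3,
                          n=1, t_h=10, ratio_K=1.0, ratio_L=1.0, seed=0)
        net = generate_network(cfg)
        assert len(net.link_pairs) <= 6
        assert net.series.K <= 6


class TestMechanisms:
    def test_rich_get_richer_weight_concentration(self):
        """Preferential activation concentrates weight relative to uniform
        re-activation on the same seeds."""
        g_pref, g_unif = [], []
        for r in range(5):
            for act, bucket in (("preferential", g_pref), ("uniform", g_unif)):
                net = generate_network(ModelConfig(seed=[31, r], activation=act))
                bucket.append(gini(net.link_weights))
        assert np.mean(g_pref) > np.mean(g_unif) + 0.1

    def test_budgeted_weights_heavier_than_null_at_matched_events(self):
        """At matched total event counts the budgeted model concentrates
        activity on few links (heavy P(w)); the null model spreads it."""
        p99_b, p99_n, gini_b, gini_n = [], [], [], []
        for r in range(3):
            acts = sample_activities(("powerlaw", 2.5, 1e-3), 2000, [61, r])
            net_b = generate_network(ModelConfig(
                N=2000, activity="powerlaw", gamma=2.5, eps=1e-3, seed=[62, r]))
            scale = (net_b.events.n_events / 2000) / acts.sum()
            net_n = generate_null_network(np.minimum(acts * scale, 1.0),
                                          T=2000, seed=[63, r])
            p99_b.append(np.percentile(net_b.link_weights, 99))
            p99_n.append(np.percentile(net_n.link_weights, 99))
            gini_b.append(gini(net_b.link_weights))
            gini_n.append(gini(net_n.link_weights))
        assert np.mean(p99_b) > np.mean(p99_n)
        assert np.mean(gini_b) > np.mean(gini_n)

    def test_modularity_monotone_in_mixing_ratio(self):
        means = []
        for p in (0.0, 0.2, 0.5, 1.0):
            qs = []
            for r in range(5):
                cfg = ModelConfig(n_communities=5, p=p, seed=[41, r])
                net = generate_network(cfg)
                qs.append(modularity(aggregate(net.events), planted_map(cfg)))
            means.append(np.mean(qs))
        assert means[0] > means[1] > means[2] > means[3]
        assert abs(means[3]) < 0.05

    def test_p_zero_creates_no_inter_community_links(self):
        cfg = ModelConfig(n_communities=5, p=0.0, seed=3)
        net = generate_network(cfg)
        labels = cfg.community_labels()
        assert all(labels[i] == labels[j] for i, j in net.link_pairs)

    def test_mixing_ratio_estimator_monotone(self):
        """p_hat increases with the generating p (lighter-load N=250 runs)."""
        means = []
        for p in (0.2, 0.5, 1.0):
            est = []
            for r in range(4):
                cfg = ModelConfig(N=250, n_communities=5, p=p, seed=[43, r])
                net = generate_network(cfg)
                est.append(estimate_mixing_ratio(aggregate(net.events),
                                                 planted_map(cfg)))
            means.append(np.mean(est))
        assert means[0] < means[1] < means[2]


class TestNullNetwork:
    def test_event_rate_matches_activity_sum(self):
        acts = np.full(500, 0.02)
        net = generate_null_network(acts, T=400, seed=0)
        per_step = net.events.n_events / 400
        assert per_step == pytest.approx(acts.sum(), rel=0.1)

    def test_uniform_activities_give_binomial_like_degrees(self):
        acts = np.full(1000, 0.01)
        net = generate_null_network(acts, T=1000, seed=1)
        deg = aggregate(net.events).degrees()
        # index of dispersion near 1 for binomial-like degrees
        assert deg.var() / deg.mean() < 1.5

    def test_activity_range_validated(self):
        with pytest.raises(ValueError):
            generate_null_network(np.array([0.5, 1.5]), T=10, seed=0)

    def test_determinism(self):
        acts = np.full(100, 0.05)
        a = generate_null_network(acts, T=100, seed=2)
        b = generate_null_network(acts, T=100, seed=2)
        assert a.events.events == b.events.events
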
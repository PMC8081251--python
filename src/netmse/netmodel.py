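"""Activity-driven temporal-network simulator with a periodic environment.

Each step t of the simulation activates

* K(t) new links: K(t) nodes are chosen with probability proportional to
  their activities (without replacement) and each connects to a partner it
  has never been linked with; with planted communities, intra-community
  candidates carry weight 1 and inter-community candidates weight p.
* L(t) previously created links, chosen without replacement with
  probability proportional to their accumulated weights w_i(t-1)
  (preferential activation) — the mechanism behind heavy-tailed link-weight
  distributions.

K(t) and L(t) are independent realizations of the periodic two-level series
model sharing (T, n, t_h) but with their own occupation probability and
rate contrast, calibrated so that the expected totals match the target
numbers of distinct links K and activations W = K + L.  Every activation
lasts a single step; weights are frozen at w(t-1) for the whole step and
updated afterwards.  While the link registry is still small, a positive
L(t) draw exceeding the registry size is redrawn from its geometric law
until it fits (and forced to 0 when the registry is empty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_contacts import ContactEventList
from .network_series import NetworkTimeSeries
from .periodic import PeriodicSeriesConfig, lambda_series, solve_rates

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SimulatedTemporalNetwork",
    "sample_activities",
    "draw_step_counts",
    "choose_active_nodes",
    "choose_partner",
    "preferential_activation_sample",
    "generate_network",
    "generate_null_network",
]


@dataclass(frozen=True)
class ModelConfig:
    """Full parameter set of the temporal-network simulator.

    Defaults follow the reference configuration used throughout:
    N = 100 nodes, K = 1000 distinct links, W = 10000 activations over
    T = 2000 steps with n = 5 environmental cycles, rho_K = 0.2,
    rho_L = 0.8.  ``ratio_K`` and ``ratio_L`` are the high/low rate
    contrasts of the environmental modulation for new links and
    re-activations; t_h is the high-activity duration per cycle.
    """

    N: int = 100
    K: int = 1000
    W: int = 10000
    T: int = 2000
    rho_K: float = 0.2
    rho_L: float = 0.8
    n: int = 5
    t_h: int = 100
    ratio_K: float = 3.0
    ratio_L: float = 1.0
    activity: str = "uniform"   # "uniform" | "powerlaw"
    a: float = 1.0              # common activity (uniform spec)
    gamma: float = 2.5          # tail exponent (powerlaw spec)
    eps: float = 1e-3           # lower activity cutoff (powerlaw spec)
    n_communities: int = 1
    p: float = 1.0              # inter/intra partner-choice weight ratio
    activation: str = "preferential"  # "preferential" | "uniform" (ablation)
    seed: int | None = None

    def __post_init__(self):
        if self.K > self.N * (self.N - 1) // 2:
            raise ValueError("K exceeds the number of distinct pairs")
        if self.W < self.K:
            raise ValueError("need W >= K")
        if not (0 < self.rho_K < 1 and 0 < self.rho_L < 1):
            raise ValueError("rho_K, rho_L must lie in (0, 1)")
        if not (0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")
        if self.n_communities < 1 or self.N % self.n_communities != 0:
            raise ValueError("n_communities must divide N")
        if self.activation not in ("preferential", "uniform"):
            raise ValueError("activation must be 'preferential' or 'uniform'")

    @property
    def L(self) -> int:
        return self.W - self.K

    def community_labels(self) -> np.ndarray:
        """Equal-sized contiguous blocks of N / n_communities nodes."""
        return np.arange(self.N) // (self.N // self.n_communities)


@dataclass
class SimulatedTemporalNetwork:
    """One realization of the simulator, with its link registry."""

    events: ContactEventList
    series: NetworkTimeSeries
    link_pairs: list
    link_weights: np.ndarray
    link_created: np.ndarray
    activities: np.ndarray
    communities: np.ndarray | None = None
    counters: dict = field(default_factory=dict)


def sample_activities(spec, N: int, rng=None) -> np.ndarray:
    """Draw node activities.

    ``spec`` is ``("uniform", a)`` for identical activities or
    ``("powerlaw", gamma, eps)`` for inverse-CDF draws from a density
    proportional to a^-gamma on [eps, 1].
    """
    rng = np.random.default_rng(rng)
    kind = spec[0]
    if kind == "uniform":
        a = float(spec[1])
        if a <= 0:
            raise ValueError("uniform activity must be > 0")
        return np.full(N, a)
    if kind == "powerlaw":
        gamma, eps = float(spec[1]), float(spec[2])
        if gamma <= 1 or not (0 < eps < 1):
            raise ValueError("need gamma > 1 and 0 < eps < 1")
        u = rng.random(N)
        e = 1.0 - gamma
        return (eps ** e + u * (1.0 - eps ** e)) ** (1.0 / e)
    raise ValueError(f"unknown activity spec {spec!r}")


def _sub_configs(config: ModelConfig) -> tuple[PeriodicSeriesConfig, PeriodicSeriesConfig]:
    cfg_K = PeriodicSeriesConfig(Z=config.K, T=config.T, rho=config.rho_K,
                                 n=config.n, t_h=config.t_h, ratio=config.ratio_K)
    cfg_L = PeriodicSeriesConfig(Z=config.L, T=config.T, rho=config.rho_L,
                                 n=config.n, t_h=config.t_h, ratio=config.ratio_L)
    return cfg_K, cfg_L


def draw_step_counts(config: ModelConfig, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw the budget series {K(t)} and {L(t)} as independent periodic series.

    Expected totals equal the targets K and L = W - K by construction.
    """
    from .periodic import generate_series

    rng = np.random.default_rng(rng)
    cfg_K, cfg_L = _sub_configs(config)
    return (generate_series(cfg_K, rng, allow_low_rate=True),
            generate_series(cfg_L, rng, allow_low_rate=True))


def _weighted_draw(weights: np.ndarray, rng) -> int:
    """One index drawn with probability proportional to ``weights``."""
    c = np.cumsum(weights)
    total = c[-1]
    if total <= 0:
        raise ValueError("no positive weight to draw from")
    return int(np.searchsorted(c, rng.random() * total, side="right"))


def _weighted_sample_without_replacement(weights: np.ndarray, count: int, rng) -> list[int]:
    """Sequential weighted draws; the drawn weight is zeroed before the next."""
    w = np.asarray(weights, dtype=float).copy()
    out = []
    for _ in range(count):
        idx = _weighted_draw(w, rng)
        out.append(idx)
        w[idx] = 0.0
    return out


def choose_active_nodes(activities: np.ndarray, count: int, rng=None) -> list[int]:
    """Distinct nodes sampled sequentially with probability ~ activity."""
    rng = np.random.default_rng(rng)
    N = len(activities)
    if count > N:
        log.warning("requested %d active nodes from %d; truncating", count, N)
        count = N
    return _weighted_sample_without_replacement(activities, count, rng)


def choose_partner(node: int, neighbors, communities, p: float, rng,
                   N: int) -> int | None:
    """Partner for a newly activated node among never-connected candidates.

    Candidates exclude the node itself and its existing neighbors; an
    intra-community candidate has weight 1 and an inter-community candidate
    weight p (no communities: all weight 1).  Returns None when no candidate
    has positive weight (saturation; the caller resamples the active node).
    """
    w = np.ones(N)
    if communities is not None and p != 1.0:
        w = np.where(communities == communities[node], 1.0, p)
    w[node] = 0.0
    if neighbors:
        w[list(neighbors)] = 0.0
    total = w.sum()
    if total <= 0:
        return None
    return _weighted_draw(w, rng)


def preferential_activation_sample(weights: np.ndarray, count: int, rng=None) -> list[int]:
    """Distinct links drawn with probability ~ accumulated weight.

    Sequential draws with renormalization (the drawn link is removed).  The
    caller must guarantee count <= number of registered links.
    """
    if count > len(weights):
        raise ValueError("count exceeds registry size; apply the redraw rule first")
    rng = np.random.default_rng(rng)
    return _weighted_sample_without_replacement(weights, count, rng)


def generate_network(config: ModelConfig) -> SimulatedTemporalNetwork:
    """Run the simulator for T steps and return the realized temporal network.

    All randomness flows from ``config.seed`` through four named
    sub-streams (budget counts, node choice, partner choice, activation),
    so each stage is individually reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_nodes, rng_partner, rng_act = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    cfg_K, cfg_L = _sub_configs(config)
    from .periodic import generate_series

    K_t = generate_series(cfg_K, rng_counts, allow_low_rate=True)
    L_t = generate_series(cfg_L, rng_counts, allow_low_rate=True)
    lam_L = lambda_series(solve_rates(cfg_L))
    p_redraw = np.where(lam_L >= 1.0, 1.0 / np.maximum(lam_L, 1.0),
                        -np.expm1(-1.0 / lam_L))

    N = config.N
    activities = sample_activities(
        ("uniform", config.a) if config.activity == "uniform"
        else ("powerlaw", config.gamma, config.eps),
        N, rng_nodes)
    communities = config.community_labels() if config.n_communities > 1 else None

    neighbors: list[set] = [set() for _ in range(N)]
    link_pairs: list[tuple[int, int]] = []
    link_weights: list[int] = []
    link_created: list[int] = []
    events: list[tuple[int, int, int]] = []
    K_real = np.zeros(config.T, dtype=np.int64)
    W_real = np.zeros(config.T, dtype=np.int64)
    counters = {"redraws": 0, "forced_zero_L": 0, "truncated_K": 0}

    for t in range(1, config.T + 1):
        registry_size = len(link_pairs)
        frozen_w = np.asarray(link_weights, dtype=float)

        # --- new links -------------------------------------------------
        k_budget = int(K_t[t - 1])
        new_links: list[tuple[int, int]] = []
        if k_budget > 0:
            remaining = activities.copy()
            made = 0
            while made < k_budget and remaining.sum() > 0:
                i = _weighted_draw(remaining, rng_nodes)
                remaining[i] = 0.0
                j = choose_partner(i, neighbors[i], communities, config.p,
                                   rng_partner, N)
                if j is None:
                    continue  # saturated node: resample another active node
                neighbors[i].add(j)
                neighbors[j].add(i)
                new_links.append((min(i, j), max(i, j)))
                made += 1
            if made < k_budget:
                counters["truncated_K"] += k_budget - made

        # --- re-activations (preferential, frozen weights) -------------
        l_budget = int(L_t[t - 1])
        if l_budget > registry_size:
            if registry_size == 0:
                counters["forced_zero_L"] += 1
                l_budget = 0
            else:
                while l_budget > registry_size:
                    counters["redraws"] += 1
                    l_budget = int(rng_counts.geometric(p_redraw[t - 1]))
        if l_budget > 0:
            if config.activation == "preferential":
                chosen = preferential_activation_sample(frozen_w, l_budget, rng_act)
            else:
                chosen = list(rng_act.choice(registry_size, size=l_budget,
                                             replace=False))
            for idx in chosen:
                link_weights[idx] += 1
                events.append((t,) + link_pairs[idx])
        else:
            chosen = []

        # new links register and count as activated after the step
        for pair in new_links:
            link_pairs.append(pair)
            link_weights.append(1)
            link_created.append(t)
            events.append((t,) + pair)
        K_real[t - 1] = len(new_links)
        W_real[t - 1] = len(new_links) + len(chosen)

    event_list = ContactEventList(tuple(sorted(events)), step_seconds=20.0,
                                  extra_nodes=frozenset(range(N)))
    return SimulatedTemporalNetwork(
        events=event_list,
        series=NetworkTimeSeries(K_real, W_real),
        link_pairs=link_pairs,
        link_weights=np.asarray(link_weights, dtype=np.int64),
        link_created=np.asarray(link_created, dtype=np.int64),
        activities=activities,
        communities=communities,
        counters=counters,
    )


def generate_null_network(activities, T: int, links_per_activation: int = 1,
                          seed=None) -> SimulatedTemporalNetwork:
    """Plain activity-driven model without budgets or preferential activation.

    At every step each node independently activates with probability equal
    to its activity and links to ``links_per_activation`` uniformly random
    other nodes; repeated pairs simply re-activate the existing link.
    """
    activities = np.asarray(activities, dtype=float)
    if np.any(activities <= 0) or np.any(activities > 1):
        raise ValueError("activities must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    N = len(activities)
    events: list[tuple[int, int, int]] = []
    for t in range(1, T + 1):
        active = np.flatnonzero(rng.random(N) < activities)
        for i in active:
            for _ in range(links_per_activation):
                j = int(rng.integers(N - 1))
                if j >= i:
                    j += 1
                events.append((t, min(int(i), j), max(int(i), j)))
    # per-step duplicates collapse (binary activation), matching real data
    events = sorted(set(events))
    seen: dict = {}
    weights: dict = {}
    for t, i, j in events:
        seen.setdefault((i, j), t)
        weights[(i, j)] = weights.get((i, j), 0) + 1
    pairs = list(seen)
    event_list = ContactEventList(tuple(events), step_seconds=20.0,
                                  extra_nodes=frozenset(range(N)))
    from .network_series import extract_series

    return SimulatedTemporalNetwork(
        events=event_list,
        series=extract_series(event_list, T=T),
        link_pairs=pairs,
        link_weights=np.array([weights[p] for p in pairs], dtype=np.int64),
        link_created=np.array([seen[p] for p in pairs], dtype=np.int64),
        activities=activities,
        counters={},
    )
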
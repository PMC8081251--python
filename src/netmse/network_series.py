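"""Network-level time series and time-aggregated statistics.

From a stream of timestamped contacts we derive the per-step counts

* ``W(t)`` — number of links activated (pairs in contact) at step *t*,
* ``K(t)`` — number of links activated *for the first time* at step *t*,
* ``L(t) = W(t) - K(t)`` — re-activations of previously created links,

with totals ``K = sum K(t)`` (distinct links), ``W = sum W(t)`` (total
activations) and ``L = W - K``.  The time-aggregated network carries one
weighted link per pair, weight ``w_i = sum_t A_i(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.community import modularity as _nx_modularity

from .io_contacts import CommunityMap, ContactEventList

__all__ = [
    "NetworkTimeSeries",
    "AggregatedNetwork",
    "BinnedDistribution",
    "UndefinedValueError",
    "extract_series",
    "aggregate",
    "distribution",
    "modularity",
    "estimate_mixing_ratio",
    "gini",
    "power_law_tail_exponent",
]


class UndefinedValueError(ValueError):
    """A statistic is undefined for the given input (e.g. no links)."""


@dataclass(frozen=True)
class NetworkTimeSeries:
    """Per-step link-activation counts of a temporal network."""

    K_t: np.ndarray
    W_t: np.ndarray

    def __post_init__(self):
        K_t = np.asarray(self.K_t, dtype=np.int64)
        W_t = np.asarray(self.W_t, dtype=np.int64)
        object.__setattr__(self, "K_t", K_t)
        object.__setattr__(self, "W_t", W_t)
        if K_t.shape != W_t.shape:
            raise ValueError("K_t and W_t must have equal length")
        if np.any(K_t < 0) or np.any(W_t < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(K_t > W_t):
            raise ValueError("K(t) <= W(t) must hold at every step")

    @property
    def L_t(self) -> np.ndarray:
        return self.W_t - self.K_t

    @property
    def T(self) -> int:
        return len(self.K_t)

    @property
    def K(self) -> int:
        return int(self.K_t.sum())

    @property
    def W(self) -> int:
        return int(self.W_t.sum())

    @property
    def L(self) -> int:
        return self.W - self.K

    def to_table(self) -> str:
        """Tab-separated export: columns t, K, W, L."""
        lines = ["t\tK\tW\tL"]
        for t in range(self.T):
            lines.append(f"{t + 1}\t{self.K_t[t]}\t{self.W_t[t]}\t{self.L_t[t]}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class AggregatedNetwork:
    """Time-aggregated weighted network: one link per pair ever in contact."""

    graph: nx.Graph

    @property
    def N(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], dtype=np.int64)

    def weights(self) -> np.ndarray:
        return np.array(
            [d["weight"] for _, _, d in self.graph.edges(data=True)], dtype=np.int64
        )

    def to_edgelist(self) -> str:
        lines = []
        for i, j, d in sorted(self.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            lines.append(f"{i} {j} {d['weight']}")
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class BinnedDistribution:
    """Histogram with probability mass per bin (linear or logarithmic bins)."""

    edges: np.ndarray
    mass: np.ndarray
    mode: str

    @property
    def centers(self) -> np.ndarray:
        if self.mode == "logarithmic":
            return np.sqrt(self.edges[:-1] * self.edges[1:])
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_table(self) -> str:
        lines = ["bin_center\tmass"]
        for c, m in zip(self.centers, self.mass):
            lines.append(f"{c:.8g}\t{m:.8g}")
        return "\n".join(lines) + "\n"


def extract_series(events: ContactEventList, T: int | None = None) -> NetworkTimeSeries:
    """Derive {K(t)} and {W(t)} from an event stream.

    ``W(t)`` counts the distinct pairs with an event at step ``t``; ``K(t)``
    counts pairs whose earliest event falls at ``t``.  Steps without events
    contribute zeros up to ``T`` (default: the last event time).
    """
    max_t = events.max_time
    if T is None:
        T = max_t
    if T < max_t:
        raise ValueError(f"T={T} is smaller than the last event time {max_t}")
    K_t = np.zeros(T, dtype=np.int64)
    W_t = np.zeros(T, dtype=np.int64)
    seen: set = set()
    for t, i, j in events.events:
        W_t[t - 1] += 1
        if (i, j) not in seen:
            seen.add((i, j))
            K_t[t - 1] += 1
    return NetworkTimeSeries(K_t, W_t)


def aggregate(events: ContactEventList) -> AggregatedNetwork:
    """Collapse time: one weighted link per pair, weight = number of active steps."""
    if not events.events:
        raise UndefinedValueError("cannot aggregate an empty event list")
    G = nx.Graph()
    G.add_nodes_from(events.node_set)
    for _, i, j in events.events:
        if G.has_edge(i, j):
            G[i][j]["weight"] += 1
        else:
            G.add_edge(i, j, weight=1)
    return AggregatedNetwork(G)


def distribution(values, mode: str = "linear", n_bins: int = 10) -> BinnedDistribution:
    """Bin values into a normalized distribution.

    Degree distributions are conventionally linearly binned and weight
    distributions logarithmically binned; logarithmic mode requires strictly
    positive values and uses geometric bin edges between min and max.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if mode == "linear":
        lo, hi = values.min(), values.max()
        if lo == hi:
            edges = np.array([lo - 0.5, hi + 0.5])
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
    elif mode == "logarithmic":
        if np.any(values <= 0):
            raise ValueError("logarithmic binning requires all values > 0")
        lo, hi = values.min(), values.max()
        if lo == hi:
            edges = np.array([lo / np.sqrt(2), hi * np.sqrt(2)])
        else:
            edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    counts, edges = np.histogram(values, bins=edges)
    mass = counts / counts.sum()
    return BinnedDistribution(edges, mass, mode)


def _community_sets(net: AggregatedNetwork, communities: CommunityMap) -> list[set]:
    labels = communities.labels_for(net.graph.nodes)
    groups: dict = {}
    for node, lab in labels.items():
        groups.setdefault(lab, set()).add(node)
    return list(groups.values())


def modularity(net: AggregatedNetwork, communities: CommunityMap) -> float:
    """Newman–Girvan modularity Q of a given partition, on the binary network.

    Q = sum_c (e_cc - a_c^2) with e_cc the fraction of links inside community
    c and a_c the fraction of link ends attached to c; link weights are
    ignored (presence/absence only).
    """
    if net.n_links == 0:
        raise UndefinedValueError("modularity is undefined for a network without links")
    return float(_nx_modularity(net.graph, _community_sets(net, communities), weight=None))


def estimate_mixing_ratio(net: AggregatedNetwork, communities: CommunityMap) -> float:
    """Estimate the inter/intra partner-choice ratio p from link counts.

    p_hat = (inter-community link density) / (intra-community link density),
    densities being links divided by available pairs.  In a generator that
    weights intra-community candidates 1 and inter-community candidates p,
    per-pair link densities scale by exactly that factor, so p_hat recovers
    p in both limits (0: no inter links; 1: uniform wiring).
    """
    groups = _community_sets(net, communities)
    if len(groups) < 2:
        raise ValueError("need at least 2 communities to estimate p")
    sizes = np.array([len(g) for g in groups])
    n = sizes.sum()
    intra_pairs = int((sizes * (sizes - 1) // 2).sum())
    inter_pairs = n * (n - 1) // 2 - intra_pairs
    label_of = {}
    for idx, g in enumerate(groups):
        for node in g:
            label_of[node] = idx
    intra = sum(1 for i, j in net.graph.edges if label_of[i] == label_of[j])
    inter = net.n_links - intra
    if intra == 0:
        raise UndefinedValueError("p_hat unbounded: no intra-community links")
    return (inter / inter_pairs) / (intra / intra_pairs)


def gini(values) -> float:
    """Gini coefficient of a nonnegative sample (0 = equal, ->1 = concentrated)."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0 or np.any(x < 0):
        raise ValueError("gini requires a nonempty nonnegative sample")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / total).sum()) / n)


def power_law_tail_exponent(values, xmin: float, xmax: float | None = None) -> float:
    """Continuous maximum-likelihood estimate of a power-law tail exponent.

    For values in [xmin, inf) drawn from a density ~ x^(-alpha) this is the
    Hill estimator alpha = 1 + n / sum(log(x / xmin)).  When the support is
    bounded above (activity cutoffs, finite observation windows), pass
    ``xmax``: the truncated-support likelihood is then maximized
    numerically, removing the upward bias of the unbounded fit.
    """
    from scipy.optimize import brentq

    x = np.asarray(values, dtype=float)
    tail = x[x >= xmin]
    if xmax is not None:
        tail = tail[tail <= xmax]
    if tail.size < 2:
        raise ValueError("too few tail observations above xmin")
    mean_log = np.log(tail / xmin).mean()
    if xmax is None:
        return float(1.0 + 1.0 / mean_log)
    b = xmax / xmin
    log_b = np.log(b)

    def score(alpha):
        # d/dalpha of the mean log-likelihood under support [xmin, xmax]
        e = 1.0 - alpha
        if abs(e) < 1e-9:
            norm_term = log_b / 2.0
        else:
            norm_term = (log_b * b ** e / (b ** e - 1.0)) - 1.0 / e
        return norm_term - mean_log

    return float(brentq(score, 1.0 + 1e-6, 50.0))
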
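"""Sample entropy, multiscale entropy and series-level heterogeneity/memory.

Sample entropy S_E(m, r) is the negative logarithm of the conditional
probability that two length-m template vectors matching within Chebyshev
tolerance r still match when extended to length m+1, self-matches excluded:

    S_E(m, r) = ln( sum_t C_t^m(r) / sum_t C_t^{m+1}(r) ).

We build T - m templates for BOTH lengths m and m+1 (the length-(m+1)
template starting at t = T - m is still inside the series); the more common
convention uses T - m - 1 templates at length m+1 and differs by one
template, a discrepancy that vanishes for long series.

The multiscale entropy (MSE) curve evaluates S_E on coarse-grained copies of
the series, where scale factor tau replaces the series by averages over
non-overlapping windows of tau points.  The tolerance r = r_factor * sigma
is frozen from the ORIGINAL series and reused at every scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "EntropyCurve",
    "AveragedEntropyCurve",
    "SeriesStats",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "average_curves",
    "classify_mse_shape",
    "heterogeneity_level",
    "memory_coefficient",
    "series_stats",
]


@njit(cache=False)
def _match_counts(x, m, r):
    """Counts of template pairs matching at length m (A) and m+1 (B).

    Unordered pairs; the ratio A/B equals the ratio of the ordered sums.
    """
    n = x.shape[0] - m
    A = 0
    B = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = True
            for s in range(m):
                if abs(x[i + s] - x[j + s]) > r:
                    ok = False
                    break
            if ok:
                A += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    B += 1
    return A, B


def coarse_grain(x, tau: int) -> np.ndarray:
    """Average a series over non-overlapping windows of size tau.

    Output length floor(T / tau); a trailing partial window is dropped.
    tau = 1 returns the series unchanged.
    """
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError("tau must be a positive integer")
    if tau > x.size:
        raise ValueError(f"tau={tau} exceeds series length {x.size}")
    if tau == 1:
        return x.copy()
    n = x.size // tau
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Sample entropy S_E(m, r); NaN when no template pair matches.

    ``r`` is an absolute Chebyshev tolerance and must be positive.  Returns
    ``nan`` (an "undefined" value, not an error) when either match count is
    zero, which legitimately happens for short or very irregular series.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.15 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    if x.size < m + 2:
        raise ValueError(f"series length {x.size} < m + 2 = {m + 2}")
    A, B = _match_counts(x, m, float(r))
    if A == 0 or B == 0:
        return float("nan")
    return math.log(A / B)


@dataclass(frozen=True)
class EntropyCurve:
    """Sample entropy versus scale factor tau; NaN marks undefined entries."""

    tau: np.ndarray
    S_E: np.ndarray
    m: int
    r: float

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.S_E).sum())

    def slope(self, tau_min: int, tau_max: int) -> float:
        """Least-squares slope of S_E vs tau restricted to [tau_min, tau_max]."""
        mask = (self.tau >= tau_min) & (self.tau <= tau_max) & ~np.isnan(self.S_E)
        if mask.sum() < 2:
            raise ValueError("fewer than 2 defined points in the tau window")
        return float(np.polyfit(self.tau[mask], self.S_E[mask], 1)[0])


@dataclass(frozen=True)
class AveragedEntropyCurve:
    """Per-tau mean/sd of several MSE curves with contributing-curve counts."""

    tau: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_curves: np.ndarray
    m: int

    def slope(self, tau_min: int, tau_max: int) -> float:
        mask = (self.tau >= tau_min) & (self.tau <= tau_max) & ~np.isnan(self.mean)
        if mask.sum() < 2:
            raise ValueError("fewer than 2 defined points in the tau window")
        return float(np.polyfit(self.tau[mask], self.mean[mask], 1)[0])

    def to_table(self) -> str:
        lines = ["tau\tS_E_mean\tS_E_sd\tn_curves"]
        for t, mu, sd, n in zip(self.tau, self.mean, self.sd, self.n_curves):
            lines.append(f"{t}\t{mu:.8g}\t{sd:.8g}\t{n}")
        return "\n".join(lines) + "\n"


def mse_curve(x, tau_max: int = 100, m: int = 2, r_factor: float = 0.15,
              taus=None) -> EntropyCurve:
    """Multiscale entropy curve of a series.

    The tolerance r = r_factor * sigma(x) is computed once from the original
    (tau = 1) series with the population standard deviation, and reused for
    every coarse-grained copy.  Scales whose coarse series is too short, or
    with no matching templates, yield NaN entries rather than errors.

    ``taus`` optionally restricts evaluation to a subset of scale factors
    (e.g. a thinned grid for long series).
    """
    x = np.asarray(x, dtype=float)
    if taus is None:
        taus = np.arange(1, tau_max + 1)
    taus = np.asarray(taus, dtype=np.int64)
    if taus.size == 0 or taus[0] < 1 or np.any(np.diff(taus) <= 0):
        raise ValueError("taus must be strictly increasing positive integers")
    sigma = float(np.std(x))
    r = r_factor * sigma
    if r <= 0:
        raise ValueError("r = r_factor * sigma is not positive (constant series?)")
    values = np.full(taus.size, np.nan)
    for k, tau in enumerate(taus):
        if x.size // tau < m + 2:
            continue
        values[k] = sample_entropy(coarse_grain(x, int(tau)), m=m, r=r)
    return EntropyCurve(taus, values, m, r)


def average_curves(curves) -> AveragedEntropyCurve:
    """Average MSE curves on a shared tau grid (e.g. over days or replicates).

    Undefined (NaN) entries are excluded per tau; the per-tau count of
    contributing curves is reported.  Population standard deviation.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    tau = curves[0].tau
    m = curves[0].m
    for c in curves[1:]:
        if not np.array_equal(c.tau, tau) or c.m != m:
            raise ValueError("curves must share tau grid and template length m")
    stack = np.vstack([c.S_E for c in curves])
    n = (~np.isnan(stack)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(stack, axis=0), np.nan)
        sd = np.where(n > 0, np.nanstd(stack, axis=0), np.nan)
    return AveragedEntropyCurve(tau, mean, sd, n, m)


def classify_mse_shape(curve, early=(10, 40), late=(40, 100)) -> str:
    """Classify an (averaged) MSE curve into the three canonical shapes.

    Uses the least-squares slopes s1 and s2 of S_E vs tau on the early and
    late windows: a negative late slope means the curve falls at large
    scales (``"rise-then-fall"``, the white-noise-like regime); a late rise
    dominating the early trend (s2 > |s1|) means ``"increasing"`` (the
    1/f^2-like regime); anything else is ``"peak-then-flat"`` (the
    1/f-like regime with long-range correlations).
    """
    s1 = curve.slope(*early)
    s2 = curve.slope(*late)
    if s2 < 0:
        return "rise-then-fall"
    if s2 >= abs(s1):
        return "increasing"
    return "peak-then-flat"


def heterogeneity_level(x) -> float:
    """Heterogeneity level H = (sigma - mean) / (sigma + mean) of a series.

    H = -1 for a constant positive series, ~0 for exponentially distributed
    values, > 0 for heavy-tailed value distributions.  Population sigma.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    mx = float(np.mean(x))
    sx = float(np.std(x))
    if sx + mx == 0:
        raise ValueError("H undefined: sigma + mean = 0")
    return (sx - mx) / (sx + mx)


def memory_coefficient(x) -> float:
    """Lag-one memory coefficient M in [-1, 1].

    Correlates consecutive values using the means/deviations of the leading
    window {x_1..x_{T-1}} and trailing window {x_2..x_T} separately
    (population standard deviations).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("memory coefficient needs length >= 3")
    a, b = x[:-1], x[1:]
    m1, m2 = a.mean(), b.mean()
    s1, s2 = a.std(), b.std()
    if s1 == 0 or s2 == 0:
        raise ValueError("M undefined: zero deviation in a window")
    return float(((a - m1) * (b - m2)).mean() / (s1 * s2))


@dataclass(frozen=True)
class SeriesStats:
    """Heterogeneity/memory summary of one series."""

    H: float
    M: float
    mean: float
    sd: float


def series_stats(x) -> SeriesStats:
    x = np.asarray(x, dtype=float)
    return SeriesStats(
        H=heterogeneity_level(x),
        M=memory_coefficient(x),
        mean=float(np.mean(x)),
        sd=float(np.std(x)),
    )
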
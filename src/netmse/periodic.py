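"""Periodic two-level activity model for nonnegative-integer time series.

The observation window of T steps is divided into n equal intervals.  Each
interval starts with a high-activity period of t_h steps at rate lambda_h,
followed by T/n - t_h steps at rate lambda_l (lambda_h >= lambda_l).  At
each step the series takes the value 0 with probability 1 - rho, and
otherwise a positive integer drawn with mean lambda(t) — realized here as a
geometric distribution on {1, 2, ...} with success probability
1/lambda(t), which preserves the budget identity

    Z = sum_t z(t) = rho * sum_t lambda(t)
      = rho * [lambda_h * t_h + lambda_l * (T/n - t_h)] * n

exactly in expectation.  Given (Z, T, rho, n) and the ratio
lambda_h/lambda_l together with t_h, the two rates are fully determined.

The decomposition lambda(t) = lambda_int + lambda_ext(t) separates a
constant internal rate (the time average, lambda_int = Z / (rho * T)) from
a zero-mean periodic external modulation whose strength is summarized by
the fluctuation sigma_lambda^2 (time variance of lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeriodicSeriesConfig",
    "ActivityProfile",
    "solve_rates",
    "lambda_at",
    "lambda_series",
    "lambda_variance",
    "critical_high_period",
    "generate_series",
]


@dataclass(frozen=True)
class PeriodicSeriesConfig:
    """Control parameters of the periodic series generator.

    Z: target expected total sum of the series.
    T: number of steps; n must divide T.
    rho: probability of a positive value at each step (0 < rho < 1).
    n: number of high/low intervals per observation window.
    t_h: high-activity duration per interval, 1 <= t_h <= T/n.
    ratio: lambda_h / lambda_l >= 1.
    """

    Z: float
    T: int
    rho: float
    n: int
    t_h: int
    ratio: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if self.Z <= 0 or self.T < 1 or self.n < 1:
            raise ValueError("Z, T, n must be positive")
        if self.T % self.n != 0:
            raise ValueError("n must divide T")
        if not (1 <= self.t_h <= self.T // self.n):
            raise ValueError("t_h must lie in [1, T/n]")
        if self.ratio < 1:
            raise ValueError("ratio = lambda_h/lambda_l must be >= 1")


@dataclass(frozen=True)
class ActivityProfile:
    """The two-level periodic rate lambda(t) and its derived quantities."""

    lambda_h: float
    lambda_l: float
    t_h: int
    n: int
    T: int

    def __post_init__(self):
        if not (self.lambda_h >= self.lambda_l > 0):
            raise ValueError("need lambda_h >= lambda_l > 0")
        if self.T % self.n != 0:
            raise ValueError("n must divide T")
        if not (1 <= self.t_h <= self.T // self.n):
            raise ValueError("t_h must lie in [1, T/n]")

    @property
    def interval(self) -> int:
        return self.T // self.n

    @property
    def s(self) -> float:
        """Fraction of each interval spent at the high rate."""
        return self.t_h / self.interval

    @property
    def ratio(self) -> float:
        return self.lambda_h / self.lambda_l

    @property
    def lambda_int(self) -> float:
        """Time average of lambda(t) (the internal, constant rate)."""
        return (self.lambda_h * self.t_h
                + self.lambda_l * (self.interval - self.t_h)) / self.interval


def solve_rates(config: PeriodicSeriesConfig) -> ActivityProfile:
    """Solve the budget identity for (lambda_h, lambda_l) given ratio and t_h.

    lambda_l = Z / (rho * n * [ratio * t_h + (T/n - t_h)]); ratio = 1 or
    t_h = T/n collapse to the constant profile lambda(t) = Z / (rho * T).
    """
    interval = config.T // config.n
    denom = config.rho * config.n * (config.ratio * config.t_h + (interval - config.t_h))
    lambda_l = config.Z / denom
    if lambda_l <= 0:
        raise ValueError("infeasible configuration: lambda_l <= 0")
    return ActivityProfile(
        lambda_h=config.ratio * lambda_l,
        lambda_l=lambda_l,
        t_h=config.t_h,
        n=config.n,
        T=config.T,
    )


def lambda_at(profile: ActivityProfile, t: int) -> float:
    """Rate at 1-based step t: high during the first t_h steps of each interval."""
    if not (1 <= t <= profile.T):
        raise ValueError(f"t={t} outside [1, {profile.T}]")
    return profile.lambda_h if (t - 1) % profile.interval < profile.t_h else profile.lambda_l


def lambda_series(profile: ActivityProfile) -> np.ndarray:
    """The full rate sequence lambda(1..T) as an array."""
    phase = np.arange(profile.T) % profile.interval
    return np.where(phase < profile.t_h, profile.lambda_h, profile.lambda_l)


def lambda_variance(profile: ActivityProfile) -> float:
    """Time variance of lambda(t) around lambda_int (closed form).

    sigma_lambda^2 = lambda_int^2 (c)^2 s(1-s) / [1 + c*s]^2 with
    c = ratio - 1 and s = t_h / (T/n); equals the direct time average of
    (lambda(t) - lambda_int)^2 exactly.
    """
    c = profile.ratio - 1.0
    s = profile.s
    return (profile.lambda_int ** 2) * c * c * s * (1 - s) / (1 + c * s) ** 2


def critical_high_period(ratio: float, T: int, n: int) -> float:
    """The t_h maximizing the rate fluctuation: T / [n (ratio + 1)].

    For t_h beyond this boundary sigma_lambda^2 decreases, i.e. the profile
    approaches the constant rate and the external modulation weakens.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    return T / (n * (ratio + 1.0))


def generate_series(config: PeriodicSeriesConfig, rng=None,
                    allow_low_rate: bool = False) -> np.ndarray:
    """Draw one realization {z(t)} of the periodic series model.

    The positive part is geometric on {1, 2, ...} with mean lambda(t),
    which requires lambda >= 1; by default lambda_l < 1 raises.  With
    ``allow_low_rate=True``, steps whose rate falls below 1 instead draw
    the ceiling of an exponential variate with scale lambda(t) (a geometric
    with success probability 1 - exp(-1/lambda)) — the smallest-mean
    discretization of the exponential law on positive integers.  Its mean
    exceeds lambda, so the budget identity holds only approximately for
    those steps.
    """
    profile = solve_rates(config)
    if profile.lambda_l < 1 and not allow_low_rate:
        raise ValueError(
            "lambda_l < 1: the positive integer part (geometric with mean "
            "lambda) needs mean >= 1; increase Z or rho, reduce the rate "
            "contrast, or pass allow_low_rate=True"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = lambda_series(profile)
    positive = rng.random(config.T) < config.rho
    p_success = np.where(lam >= 1.0, 1.0 / np.maximum(lam, 1.0),
                         -np.expm1(-1.0 / lam))
    magnitudes = rng.geometric(p_success)
    return np.where(positive, magnitudes, 0).astype(np.int64)
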
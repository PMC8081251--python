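"""Reference noise generators for calibrating the multiscale-entropy method.

White (uncorrelated), 1/f (Voss–McCartney) and 1/f^2 (Brownian) series span
the three canonical MSE signatures: S_E decreasing, roughly constant, and
increasing with the scale factor, respectively.
"""

from __future__ import annotations

import numpy as np

__all__ = ["white_noise", "pink_noise", "brown_noise"]


def white_noise(T: int, seed=None) -> np.ndarray:
    """Iid standard normal series of length T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal(T)


def pink_noise(T: int, n_sources: int = 16, seed=None) -> np.ndarray:
    """Approximate 1/f noise via the Voss–McCartney algorithm.

    ``n_sources`` independent Gaussian sources are summed; source k holds its
    value for 2^k steps (source 0 refreshes every step), so the spectrum
    follows 1/f over roughly n_sources octaves.  Output standardized to zero
    mean, unit variance.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if n_sources < 2:
        raise ValueError("n_sources must be >= 2")
    rng = np.random.default_rng(seed)
    out = np.zeros(T)
    for k in range(n_sources):
        period = 1 << k
        n_vals = -(-T // period)  # ceil
        vals = rng.standard_normal(n_vals)
        out += np.repeat(vals, period)[:T]
    out -= out.mean()
    return out / out.std()


def brown_noise(T: int, seed=None) -> np.ndarray:
    """1/f^2 (Brownian) noise: cumulative sum of white noise, standardized."""
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal(T))
    walk -= walk.mean()
    return walk / walk.std()
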
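"""Seedable stochastic signal generators.

Flicker noise — the reference stochastic process of the whole method — is
synthesised in the frequency domain: independent Gaussian Fourier
coefficients are scaled by ``f**(-alpha/2)`` and transformed back, so the
expected periodogram follows ``1/f**alpha``.  ``alpha = 0`` is white
Gaussian noise, ``alpha = 2`` is Brownian-like.  The zero-frequency
component is set to zero (zero-mean output) and the result is rescaled to
unit standard deviation; ordinal patterns are invariant under monotone
affine maps, so this normalisation is cosmetic.

The remaining generators supply the stochastic benchmarks: uniform white
noise on [0, 1], a Gaussian random walk, a sampled sinusoid, and the
two-component mixtures Z = (1 - eta) * X + eta * Y used to study noise
contamination.
"""

from __future__ import annotations

import math

import numpy as np

from .series import TimeSeries, as_values

__all__ = [
    "flicker_noise",
    "uniform_noise",
    "random_walk",
    "sine_series",
    "rescale_unit",
    "mix",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def flicker_noise(alpha: float, n: int, seed=None) -> TimeSeries:
    """Gaussian 1/f**alpha noise of length ``n``.

    Parameters
    ----------
    alpha : spectral exponent; the expected log-log periodogram slope
        is ``-alpha``.
    n : number of samples (>= 2).
    seed : int, ``numpy.random.Generator`` or None.
    """
    if n < 2:
        raise ValueError(f"flicker noise needs n >= 2, got {n}")
    if not math.isfinite(alpha):
        raise ValueError(f"alpha must be finite, got {alpha}")
    rng = _rng(seed)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    sr = rng.normal(size=f.size) * scale
    si = rng.normal(size=f.size) * scale
    si[0] = 0.0
    if n % 2 == 0:  # Nyquist bin is real; double its variance instead
        si[-1] = 0.0
        sr[-1] *= math.sqrt(2.0)
    y = np.fft.irfft(sr + 1j * si, n=n)
    sd = y.std()
    if sd > 0:
        y = y / sd
    return TimeSeries(y, meta={"generator": "flicker_noise", "alpha": float(alpha), "n": n})


def uniform_noise(n: int, seed=None) -> TimeSeries:
    """I.i.d. samples uniform on [0, 1]."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    y = _rng(seed).random(n)
    return TimeSeries(y, meta={"generator": "uniform_noise", "n": n})


def random_walk(n: int, seed=None) -> TimeSeries:
    """Cumulative sum of N(0, 1) increments, starting at x0 = 0."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    steps = _rng(seed).standard_normal(n - 1)
    y = np.concatenate(([0.0], np.cumsum(steps)))
    return TimeSeries(y, meta={"generator": "random_walk", "n": n})


def sine_series(tau: float, n: int) -> TimeSeries:
    """sin(2*pi*n/tau) sampled at integer indices, min-max rescaled to [0, 1].

    ``tau`` is the period in samples; the angular frequency is
    ``omega = 2*pi/tau``.
    """
    if tau <= 0:
        raise ValueError(f"period tau must be positive, got {tau}")
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    y = np.sin(2.0 * np.pi * np.arange(n) / tau)
    y = rescale_unit(y)
    return TimeSeries(y, meta={"generator": "sine_series", "tau": float(tau), "n": n})


def rescale_unit(x) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant series maps to all zeros."""
    x = as_values(x)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def mix(deterministic, noise, eta: float) -> TimeSeries:
    """Two-component mixture Z = (1 - eta) * X + eta * Y.

    The deterministic component ``X`` is min-max rescaled to [0, 1] before
    mixing; the endpoints are exact: ``eta = 0`` returns the rescaled
    deterministic component, ``eta = 1`` returns the noise component
    unchanged.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    x = rescale_unit(deterministic)
    y = as_values(noise)
    if x.size != y.size:
        raise ValueError(f"component lengths differ: {x.size} vs {y.size}")
    if eta == 0.0:
        z = x.copy()
    elif eta == 1.0:
        z = y.copy()
    else:
        z = (1.0 - eta) * x + eta * y
    return TimeSeries(z, meta={"generator": "mix", "eta": float(eta), "n": int(z.size)})
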
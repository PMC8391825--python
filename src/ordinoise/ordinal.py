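"""Bandt-Pompe ordinal symbolisation and the quantifiers built on it.

A window of ``D`` (lagged) samples is mapped to the permutation that sorts
it ascending; the permutation is identified by its lexicographic (Lehmer)
rank in ``[0, D!-1]``.  Ties are broken by temporal order (earlier index
ranks first), the stable-sort convention.  Sliding the window at unit step
over a series of length ``N`` yields ``N - (D-1)*lag`` patterns whose
relative frequencies form the ordinal distribution ``P``.

From ``P`` we compute the normalised permutation entropy

    S = -sum_i P(i) ln P(i) / ln(D!),

the Jensen-Shannon divergence ``Q`` between ``P`` and the uniform
(equilibrium) distribution ``Pe`` — normalised so that a point-mass
distribution gives ``Q = 1`` — and the statistical complexity ``C = S*Q``,
which vanishes both for perfect order (S=0) and perfect randomness (P=Pe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .series import as_values

__all__ = [
    "OrdinalConfig",
    "OrdinalDistribution",
    "ComplexityResult",
    "encode_pattern",
    "ordinal_distribution",
    "permutation_entropy",
    "q0",
    "jensen_shannon",
    "statistical_complexity",
]

TIE_RULE = "stable"  # earlier-index-first; the only implemented convention


@dataclass(frozen=True)
class OrdinalConfig:
    """Pattern length ``D``, embedding lag, and tie-breaking convention."""

    D: int = 6
    lag: int = 1
    tie_rule: str = TIE_RULE

    def __post_init__(self) -> None:
        if not isinstance(self.D, (int, np.integer)) or self.D < 2:
            raise ValueError(f"pattern length D must be an integer >= 2, got {self.D}")
        if not isinstance(self.lag, (int, np.integer)) or self.lag < 1:
            raise ValueError(f"lag must be an integer >= 1, got {self.lag}")
        if self.tie_rule != TIE_RULE:
            raise ValueError(f"unknown tie rule {self.tie_rule!r}; only {TIE_RULE!r} is supported")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.D)

    def min_length(self) -> int:
        """Shortest series that yields at least one window."""
        return (self.D - 1) * self.lag + 1

    def to_dict(self) -> dict:
        return {"D": int(self.D), "lag": int(self.lag), "tie_rule": self.tie_rule}

    @classmethod
    def from_dict(cls, d: dict) -> "OrdinalConfig":
        return cls(D=d["D"], lag=d["lag"], tie_rule=d.get("tie_rule", TIE_RULE))


@dataclass
class OrdinalDistribution:
    """Counts and relative frequencies over the ``D!`` ordinal patterns."""

    config: OrdinalConfig
    counts: np.ndarray
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.config.n_patterns,):
            raise ValueError(
                f"counts must have length D! = {self.config.n_patterns}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("pattern counts must be non-negative")
        self.n_windows = int(self.counts.sum())
        if self.n_windows == 0:
            raise ValueError("distribution has no counted windows")

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_windows

    def to_frame(self):
        """Tidy (pattern_index, count, probability) table, CSV-ready."""
        import pandas as pd

        return pd.DataFrame(
            {
                "pattern_index": np.arange(self.config.n_patterns),
                "count": self.counts,
                "probability": self.probabilities,
            }
        )


@dataclass(frozen=True)
class ComplexityResult:
    """Normalised permutation entropy, JS divergence, and their product."""

    entropy: float
    divergence: float
    complexity: float
    q0: float


def _lehmer_ranks(perms: np.ndarray) -> np.ndarray:
    """Lexicographic rank of each permutation row (Lehmer code)."""
    n_rows, D = perms.shape
    ranks = np.zeros(n_rows, dtype=np.int64)
    for i in range(D - 1):
        smaller_after = np.zeros(n_rows, dtype=np.int64)
        for j in range(i + 1, D):
            smaller_after += perms[:, j] < perms[:, i]
        ranks += smaller_after * math.factorial(D - 1 - i)
    return ranks


def _encode_windows(windows: np.ndarray) -> np.ndarray:
    # stable argsort realises the earlier-index-first tie rule exactly
    perms = np.argsort(windows, axis=1, kind="stable")
    return _lehmer_ranks(perms)


def encode_pattern(window, tie_rule: str = TIE_RULE) -> int:
    """Ordinal pattern index of one window of ``D`` samples.

    Returns the lexicographic rank of the permutation that sorts the
    window ascending; ties resolve to the earlier index.  ``(1,2,3)``
    maps to 0, ``(3,2,1)`` to ``D!-1``.
    """
    if tie_rule != TIE_RULE:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError(f"window must be 1-D with at least 2 samples, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    return int(_encode_windows(w[None, :])[0])


def ordinal_distribution(series, config: OrdinalConfig | None = None) -> OrdinalDistribution:
    """Count ordinal patterns over all unit-step sliding windows.

    A series of length ``N`` yields ``N - (D-1)*lag`` windows (maximal
    overlap).  Raises if the series is shorter than ``(D-1)*lag + 1`` or
    contains non-finite values.
    """
    config = config or OrdinalConfig()
    x = as_values(series)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.size
    min_len = config.min_length()
    if n < min_len:
        raise ValueError(
            f"series of length {n} is too short for D={config.D}, lag={config.lag}; "
            f"minimum length is {min_len}"
        )
    n_windows = n - (config.D - 1) * config.lag
    idx = np.arange(n_windows)[:, None] + config.lag * np.arange(config.D)[None, :]
    ranks = _encode_windows(x[idx])
    counts = np.bincount(ranks, minlength=config.n_patterns)
    return OrdinalDistribution(config=config, counts=counts)


def _shannon(p: np.ndarray) -> float:
    """Un-normalised Shannon entropy in nats, with 0 ln 0 := 0."""
    nz = p[p > 0]
    return float(abs(-np.sum(nz * np.log(nz))))  # abs: a point mass gives -0.0


def permutation_entropy(dist: OrdinalDistribution) -> float:
    """Normalised permutation entropy in [0, 1]."""
    return _shannon(dist.probabilities) / math.log(dist.config.n_patterns)


def q0(D: int) -> float:
    """Normalisation constant of the Jensen-Shannon disequilibrium.

    Chosen so that the divergence between a point-mass distribution and
    the uniform distribution over ``D!`` patterns equals exactly 1.
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    M = math.factorial(D)
    denom = (M + 1) / M * math.log(M + 1) - 2 * math.log(2 * M) + math.log(M)
    return -2.0 / denom


def jensen_shannon(dist: OrdinalDistribution) -> float:
    """Normalised Jensen-Shannon divergence between ``P`` and uniform."""
    p = dist.probabilities
    M = dist.config.n_patterns
    pe = np.full(M, 1.0 / M)
    m = 0.5 * (p + pe)
    raw = _shannon(m) - 0.5 * _shannon(p) - 0.5 * _shannon(pe)
    q = q0(dist.config.D) * raw
    # raw can round to ~ -1e-17 when P is numerically uniform
    return max(q, 0.0)


def statistical_complexity(dist: OrdinalDistribution) -> ComplexityResult:
    """Entropy, divergence and statistical complexity ``C = S * Q``."""
    s = permutation_entropy(dist)
    q = jensen_shannon(dist)
    return ComplexityResult(entropy=s, divergence=q, complexity=s * q, q0=q0(dist.config.D))
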
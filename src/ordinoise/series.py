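"""Lightweight time-series container carrying provenance metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class TimeSeries:
    """Ordered scalar samples plus a record of how they were produced.

    ``meta`` holds whatever is needed to regenerate the series (generator
    name, parameters, seed) or, for data read from disk, its source path.
    All analysis functions in this package accept either a ``TimeSeries``
    or a bare array.
    """

    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"time series must be 1-D, got shape {self.values.shape}")

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        if dtype is not None:
            return self.values.astype(dtype)
        return self.values

    def __getitem__(self, item):
        return self.values[item]


def as_values(series) -> np.ndarray:
    """Coerce a ``TimeSeries`` or array-like to a 1-D float array."""
    if isinstance(series, TimeSeries):
        return series.values
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"time series must be 1-D, got shape {arr.shape}")
    return arr
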
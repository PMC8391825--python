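"""Deterministic benchmark systems: 1-D chaotic maps and continuous flows.

Maps
----
logistic       x -> r x (1 - x)
beta_x         x -> beta x (mod 1)     (generalised Bernoulli shift)
schuster       x -> x + x**z (mod 1)   (intermittent, 1/f**z spectrum)

For the maps the Lyapunov exponent is estimated as the orbit average of
``ln |f'(x)|``; for the beta_x map this equals ``ln(beta)`` exactly.

Integer beta needs care: in binary floating point, multiplication by a
power of two is exact, so the float64 orbit of ``x -> 2x mod 1`` loses one
significand bit per step and collapses to the fixed point 0 within ~53
iterations.  We therefore iterate integer-beta orbits exactly in
fixed-point big-integer arithmetic (the working precision grows as
``n*log2(beta)`` bits so no information is ever discarded); for
non-integer beta the rounding of ordinary float64 arithmetic keeps orbits
generic and we use the fast path.

Flows
-----
Lorenz, Roessler, a resonant three-wave interaction (complex amplitudes;
the observable is |C1|) and the Hindmarsh-Rose bursting neuron, integrated
with fixed-step RK4.  Flows are reduced to scalar series by taking the
sequence of strict local maxima of one variable (``maxima_series``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .series import TimeSeries

__all__ = [
    "MAP_FAMILIES",
    "FLOW_FAMILIES",
    "iterate_map",
    "lyapunov_1d",
    "Trajectory",
    "integrate_flow",
    "maxima_series",
    "FlowDivergenceError",
]

# fixed, reproducible default initial conditions (generic irrationals)
_MAP_X0 = {"logistic": 1.0 / math.sqrt(7.0), "beta_x": 1.0 / math.sqrt(5.0), "schuster": 1.0 / math.e}
_MAP_BURN_IN = {"logistic": 1000, "beta_x": 1000, "schuster": 10_000}

MAP_FAMILIES = ("logistic", "beta_x", "schuster")


def _check_map(family: str, parameter: float) -> None:
    if family not in MAP_FAMILIES:
        raise ValueError(f"unknown map family {family!r}; choose from {MAP_FAMILIES}")
    if family == "logistic" and not 0.0 < parameter <= 4.0:
        raise ValueError(f"logistic map needs 0 < r <= 4 to stay in [0, 1], got r={parameter}")
    if family == "beta_x" and parameter <= 0.0:
        raise ValueError(f"beta_x map needs beta > 0, got {parameter}")
    if family == "schuster" and parameter <= 0.0:
        raise ValueError(f"schuster map needs z > 0, got {parameter}")


def _resolve_x0(family: str, x0, seed) -> float:
    if x0 is None:
        if seed is not None:
            x0 = float(np.random.default_rng(seed).uniform(1e-6, 1.0 - 1e-6))
        else:
            x0 = _MAP_X0[family]
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"initial condition must lie in (0, 1), got {x0}")
    return float(x0)


def _iterate_beta_exact(beta: int, x0: float, total: int) -> np.ndarray:
    """Exact fixed-point orbit of x -> beta*x mod 1 for integer beta.

    The shift map reveals ~log2(beta) bits of the initial condition per
    step, so a 53-bit float x0 is exhausted within a few dozen iterations
    (for beta = 2 the float64 orbit collapses onto the fixed point 0).
    We extend x0 to full working precision (``total*log2(beta) + 64``
    bits): the leading 53 bits come from x0 itself, the rest from a PRNG
    seeded deterministically by x0, making the orbit an exact, seed-free
    reproducible iterate of a generic initial condition near x0.
    """
    bits_per_step = max(math.log2(beta), 0.0)
    B = 64 + math.ceil(total * bits_per_step)
    mask = (1 << B) - 1
    frac = int(x0 * 9007199254740992.0)  # top 53 bits
    pad_bits = B - 53
    pad_rng = np.random.default_rng(frac)  # deterministic function of x0
    pad = int.from_bytes(pad_rng.bytes(pad_bits // 8 + 8), "big") & ((1 << pad_bits) - 1)
    k = (frac << pad_bits) | pad
    out = np.empty(total, dtype=float)
    shift = B - 53
    for i in range(total):
        out[i] = (k >> shift) / 9007199254740992.0  # / 2**53
        k = (beta * k) & mask
    return out


def _iterate_float(family: str, p: float, x0: float, total: int) -> np.ndarray:
    out = np.empty(total, dtype=float)
    x = x0
    if family == "logistic":
        for i in range(total):
            out[i] = x
            x = p * x * (1.0 - x)
    elif family == "beta_x":
        for i in range(total):
            out[i] = x
            x = (p * x) % 1.0
    else:  # schuster
        for i in range(total):
            out[i] = x
            x = (x + x**p) % 1.0
            if x == 0.0:  # absorbing in floating point; reinject generic value
                x = _MAP_X0["schuster"]
    return out


def _map_orbit(family: str, parameter: float, n: int, x0, burn_in, seed) -> np.ndarray:
    _check_map(family, parameter)
    if burn_in is None:
        burn_in = _MAP_BURN_IN[family]
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    x0 = _resolve_x0(family, x0, seed)
    total = burn_in + n
    if family == "beta_x" and float(parameter).is_integer():
        orbit = _iterate_beta_exact(int(parameter), x0, total)
    else:
        orbit = _iterate_float(family, float(parameter), x0, total)
    return orbit[burn_in:]


def iterate_map(
    family: str,
    parameter: float,
    n: int,
    x0: float | None = None,
    burn_in: int | None = None,
    seed=None,
) -> TimeSeries:
    """Post-transient orbit of one of the 1-D benchmark maps.

    ``x0`` takes precedence; otherwise ``seed`` draws a random initial
    condition; otherwise a fixed generic constant is used, so runs are
    reproducible without a seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values = _map_orbit(family, parameter, n, x0, burn_in, seed)
    return TimeSeries(
        values,
        meta={
            "generator": family,
            "parameter": float(parameter),
            "n": n,
            "burn_in": burn_in if burn_in is not None else _MAP_BURN_IN[family],
        },
    )


def _map_derivative(family: str, p: float, x: np.ndarray) -> np.ndarray:
    if family == "logistic":
        return p * (1.0 - 2.0 * x)
    if family == "beta_x":
        return np.full_like(x, p)
    # schuster: d/dx (x + x**z) = 1 + z x**(z-1)
    with np.errstate(divide="ignore"):
        return 1.0 + p * np.power(x, p - 1.0, where=x > 0, out=np.full_like(x, np.inf))


def lyapunov_1d(
    family: str,
    parameter: float,
    n_terms: int = 1_000_000,
    x0: float | None = None,
    burn_in: int | None = None,
    seed=None,
) -> float:
    """Lyapunov exponent of a 1-D map: orbit average of ln |f'(x)|, in nats/iteration.

    Orbit points where ``f'(x) = 0`` (measure zero) are skipped with a
    warning.  For the beta_x map the result is exactly ``ln(beta)``.
    """
    if family == "beta_x":
        _check_map(family, parameter)
        return math.log(parameter)  # |f'| = beta everywhere
    orbit = _map_orbit(family, parameter, n_terms, x0, burn_in, seed)
    deriv = np.abs(_map_derivative(family, float(parameter), orbit))
    zero = deriv == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} orbit point(s) with f'(x)=0 skipped in Lyapunov sum",
            RuntimeWarning,
            stacklevel=2,
        )
        deriv = deriv[~zero]
    return float(np.mean(np.log(deriv)))


# ---------------------------------------------------------------------------
# continuous flows


class FlowDivergenceError(RuntimeError):
    """Raised when an integrated trajectory leaves the finite domain."""


@dataclass
class Trajectory:
    """Fixed-step trajectory: times, state columns and their names."""

    family: str
    times: np.ndarray
    values: np.ndarray  # shape (n_steps, n_vars)
    names: tuple[str, ...]
    dt: float

    def column(self, variable: str) -> np.ndarray:
        try:
            j = self.names.index(variable)
        except ValueError:
            raise KeyError(
                f"trajectory of {self.family!r} has variables {self.names}, not {variable!r}"
            ) from None
        return self.values[:, j]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "t", self.times)
        return df


_FLOW_DEFAULTS: dict[str, dict] = {
    "lorenz": {
        "params": {"sigma": 16.0, "R": 45.92, "b": 4.0},
        "state": np.array([1.0, 1.0, 1.0]),
        "names": ("x", "y", "z"),
        "dt": 0.01,
    },
    "rossler": {
        "params": {"a": 0.2, "b": 0.2, "c": 5.7},
        "state": np.array([1.0, 1.0, 1.0]),
        "names": ("x", "y", "z"),
        "dt": 0.01,
    },
    "three_waves": {
        "params": {"gamma1": 1.0, "gamma2": -17.0, "gamma3": -17.0, "delta": 2.0},
        "state": np.array([1.0 + 0.1j, 0.5 + 0.2j, 0.5 - 0.1j]),
        "names": ("abs_C1", "abs_C2", "abs_C3"),
        "dt": 0.01,
    },
    "hindmarsh_rose": {
        # slow variable (r = 0.006) needs long horizons, hence the larger step
        "params": {"a": 1.0, "b": 3.0, "c": 1.0, "d": 5.0, "s": 4.0, "xr": -1.6, "r": 0.006, "I": 3.25},
        "state": np.array([-1.0, 0.0, 2.0]),
        "names": ("x", "y", "z"),
        "dt": 0.05,
    },
}

FLOW_FAMILIES = tuple(_FLOW_DEFAULTS)


def _flow_rhs(family: str, p: dict):
    if family == "lorenz":
        def rhs(u):
            x, y, z = u
            return np.array([p["sigma"] * (y - x), x * (p["R"] - z) - y, x * y - p["b"] * z])
    elif family == "rossler":
        def rhs(u):
            x, y, z = u
            return np.array([-y - z, x + p["a"] * y, p["b"] + z * (x - p["c"])])
    elif family == "three_waves":
        def rhs(u):
            c1, c2, c3 = u
            return np.array(
                [
                    p["gamma1"] * c1 + c2 * c3,
                    p["gamma2"] * c2 - c1 * np.conj(c3) + 1j * p["delta"] * c2,
                    p["gamma3"] * c3 - c1 * np.conj(c2),
                ]
            )
    elif family == "hindmarsh_rose":
        def rhs(u):
            x, y, z = u
            return np.array(
                [
                    y - p["a"] * x**3 + p["b"] * x**2 - z + p["I"],
                    p["c"] - p["d"] * x**2 - y,
                    p["r"] * (p["s"] * (x - p["xr"]) - z),
                ]
            )
    else:
        raise ValueError(f"unknown flow family {family!r}; choose from {FLOW_FAMILIES}")
    return rhs


def integrate_flow(
    family: str,
    t_total: float,
    dt: float | None = None,
    t_transient: float | None = None,
    params: dict | None = None,
    initial_state=None,
) -> Trajectory:
    """Fixed-step RK4 integration with the leading transient discarded.

    ``t_transient`` defaults to 10% of ``t_total``.  Raises
    ``FlowDivergenceError`` (reporting the blow-up time) if the state
    becomes non-finite.
    """
    spec = _FLOW_DEFAULTS.get(family)
    if spec is None:
        raise ValueError(f"unknown flow family {family!r}; choose from {FLOW_FAMILIES}")
    p = dict(spec["params"])
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown parameter(s) for {family!r}: {sorted(unknown)}")
        p.update(params)
    if dt is None:
        dt = spec["dt"]
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_transient is None:
        t_transient = 0.1 * t_total
    if not 0 <= t_transient < t_total:
        raise ValueError("need 0 <= t_transient < t_total")

    u = np.array(initial_state if initial_state is not None else spec["state"])
    rhs = _flow_rhs(family, p)
    n_steps = int(round(t_total / dt))
    n_skip = int(round(t_transient / dt))
    kept = n_steps - n_skip
    out = np.empty((kept, 3), dtype=float)
    is_complex = family == "three_waves"
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n_steps):
            k1 = rhs(u)
            k2 = rhs(u + 0.5 * dt * k1)
            k3 = rhs(u + 0.5 * dt * k2)
            k4 = rhs(u + dt * k3)
            u = u + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(u)):
                raise FlowDivergenceError(f"{family} trajectory diverged at t = {(i + 1) * dt:.4f}")
            if i >= n_skip:
                out[i - n_skip] = np.abs(u) if is_complex else u
    times = (np.arange(kept) + n_skip + 1) * dt
    return Trajectory(family=family, times=times, values=out, names=spec["names"], dt=dt)


def maxima_series(trajectory: Trajectory, variable: str, min_count: int | None = None) -> TimeSeries:
    """Values at strict local maxima of one variable, in temporal order.

    A point is a maximum if it exceeds both neighbours (three-point
    comparison); plateaus and monotone segments contribute nothing.  If
    ``min_count`` is given and fewer maxima are found, raises an error
    naming the count.
    """
    y = trajectory.column(variable)
    peak = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    values = y[1:-1][peak]
    if min_count is not None and values.size < min_count:
        raise ValueError(
            f"found only {values.size} local maxima of {variable!r}; need at least {min_count}"
        )
    return TimeSeries(
        values,
        meta={"generator": f"{trajectory.family}_maxima", "variable": variable, "dt": trajectory.dt},
    )
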
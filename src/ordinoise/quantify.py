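"""The determinism quantifier Omega and the end-to-end analysis pipeline.

Given a series ``x`` of length ``n``:

1. compute its ordinal distribution, normalised permutation entropy ``S``
   and statistical complexity ``C``;
2. feed the ordinal probabilities to a trained regressor, which returns
   the effective flicker exponent ``alpha_e``;
3. generate length-matched flicker-noise series with ``alpha = alpha_e``
   and average their permutation entropy, ``S_FN``;
4. form the relative entropy difference

       Omega = |S_FN - S| / S_FN.

Flicker noise is fully stochastic, so ``Omega ~ 0`` marks the series as
mainly stochastic; a series with underlying determinism has an ordinal
distribution unlike any flicker noise and sits at a finite entropy
distance from the matched reference, giving ``Omega`` well above the
flicker-noise null.  No universal threshold exists — it depends strongly
on the series length — so :func:`fn_null_threshold` computes a
length-matched suggestion (mean + 3 sd of Omega over pure flicker noise)
instead of hard-coding one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generators import flicker_noise
from .ordinal import OrdinalConfig, ordinal_distribution, permutation_entropy, statistical_complexity
from .regressor import RegressorModel, predict
from .series import as_values

__all__ = [
    "AnalysisResult",
    "SweepResult",
    "omega",
    "analyze",
    "classify",
    "fn_null_threshold",
    "sweep",
    "MAINLY_STOCHASTIC",
    "MAINLY_DETERMINISTIC",
]

MAINLY_STOCHASTIC = "mainly_stochastic"
MAINLY_DETERMINISTIC = "mainly_deterministic"

DEFAULT_N_REF = 10


@dataclass
class AnalysisResult:
    """The reduced feature pair (alpha_e, S) and derived quantifiers."""

    alpha_e: float
    entropy: float
    entropy_fn_ref: float
    omega: float
    complexity: float
    divergence: float
    n: int
    config: OrdinalConfig
    n_ref: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "alpha_e": self.alpha_e,
            "entropy": self.entropy,
            "entropy_fn_ref": self.entropy_fn_ref,
            "omega": self.omega,
            "complexity": self.complexity,
            "divergence": self.divergence,
            "n": self.n,
            "config": self.config.to_dict(),
            "n_ref": self.n_ref,
            "seed": self.seed,
        }


def omega(
    entropy: float,
    alpha_e: float,
    n: int,
    config: OrdinalConfig | None = None,
    n_ref: int = DEFAULT_N_REF,
    seed=None,
) -> tuple[float, float]:
    """Relative entropy distance to a matched flicker-noise reference.

    Returns ``(Omega, S_FN)`` where ``S_FN`` is the mean permutation
    entropy over ``n_ref`` freshly generated flicker-noise series of the
    same length ``n`` with ``alpha = alpha_e``.  ``n_ref = 1`` reproduces
    the single-reference recipe; the ensemble default tames the noise of
    a single realisation.
    """
    if not math.isfinite(alpha_e):
        raise ValueError(f"alpha_e must be finite, got {alpha_e}")
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    config = config or OrdinalConfig()
    rng = np.random.default_rng(seed)
    pes = [
        permutation_entropy(ordinal_distribution(flicker_noise(alpha_e, n, seed=rng), config))
        for _ in range(n_ref)
    ]
    s_fn = float(np.mean(pes))
    return abs(s_fn - entropy) / s_fn, s_fn


def analyze(
    series,
    model: RegressorModel,
    config: OrdinalConfig | None = None,
    n_ref: int = DEFAULT_N_REF,
    seed=None,
    clip: bool = True,
    warn_length: bool = True,
) -> AnalysisResult:
    """Full pipeline: ordinal distribution -> (S, C) -> alpha_e -> Omega.

    The regressor should have been trained on series of the same length:
    ordinal probabilities carry a strong finite-sample length dependence,
    so a mismatch skews ``alpha_e`` (a warning is emitted unless
    ``warn_length=False``).  The flicker reference for Omega is always
    matched to the *analyzed* series length.
    """
    x = as_values(series)
    config = config or model.config
    n = x.size
    trained_n = model.meta.get("series_length")
    if warn_length and trained_n is not None and trained_n != n:
        warnings.warn(
            f"series length {n} differs from the model's training length {trained_n}; "
            "alpha_e is biased for mismatched lengths — prefer a model trained at the "
            "analyzed length",
            UserWarning,
            stacklevel=2,
        )
    dist = ordinal_distribution(x, config)
    cx = statistical_complexity(dist)
    alpha_e = predict(model, dist, clip=clip)
    om, s_fn = omega(cx.entropy, alpha_e, n, config, n_ref=n_ref, seed=seed)
    return AnalysisResult(
        alpha_e=alpha_e,
        entropy=cx.entropy,
        entropy_fn_ref=s_fn,
        omega=om,
        complexity=cx.complexity,
        divergence=cx.divergence,
        n=n,
        config=config,
        n_ref=n_ref,
        seed=None if seed is None or not np.isscalar(seed) else int(seed),
    )


def classify(result, threshold: float) -> str:
    """Label a series by comparing its Omega against a threshold.

    ``result`` may be an :class:`AnalysisResult` or a bare Omega value.
    The threshold is a deliberate user choice — see
    :func:`fn_null_threshold` for a length-calibrated suggestion.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    om = result.omega if isinstance(result, AnalysisResult) else float(result)
    return MAINLY_DETERMINISTIC if om > threshold else MAINLY_STOCHASTIC


def fn_null_threshold(
    n: int,
    model: RegressorModel,
    config: OrdinalConfig | None = None,
    alphas=(0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    replicates: int = 5,
    n_ref: int = DEFAULT_N_REF,
    seed=None,
) -> float:
    """Suggested Omega threshold: mean + 3 sd under pure flicker noise.

    Runs the full pipeline on ``replicates`` flicker-noise series of
    length ``n`` for each exponent in ``alphas`` and returns the mean
    plus three standard deviations of the resulting Omega values — the
    level that pure noise of this length rarely exceeds.
    """
    config = config or model.config
    rng = np.random.default_rng(seed)
    oms = []
    for alpha in alphas:
        for _ in range(replicates):
            s = flicker_noise(alpha, n, seed=rng)
            res = analyze(s, model, config, n_ref=n_ref, seed=rng, warn_length=False)
            oms.append(res.omega)
    return float(np.mean(oms) + 3.0 * np.std(oms))


@dataclass
class SweepResult:
    """Per-grid-point replicate summaries of a parameter sweep."""

    parameter: str
    grid: list
    table: pd.DataFrame
    replicates: int
    seed: int | None = None
    failures: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep(
    parameter: str,
    grid,
    make_series,
    model: RegressorModel,
    replicates: int = 5,
    config: OrdinalConfig | None = None,
    n_ref: int = DEFAULT_N_REF,
    seed: int = 0,
    lyapunov=None,
    warn_length: bool = False,
) -> SweepResult:
    """Analyze replicate series over a parameter grid.

    ``make_series(value, seed)`` must return a :class:`TimeSeries` for
    one grid point; ``lyapunov(value)``, if given, attaches a Lyapunov
    exponent column (1-D maps only).  Each grid point reports the mean
    and standard deviation over replicates of entropy, alpha_e, Omega and
    complexity; replicate failures are recorded and the sweep continues.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or model.config
    ss = np.random.SeedSequence(seed)
    rows = []
    failures = []
    for value in grid:
        per = {"entropy": [], "alpha_e": [], "omega": [], "complexity": []}
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            try:
                series = make_series(value, np.random.default_rng(child))
                res = analyze(
                    series, model, config, n_ref=n_ref,
                    seed=np.random.default_rng(child.spawn(1)[0]),
                    warn_length=warn_length,
                )
            except Exception as exc:  # noqa: BLE001 - record and continue
                failures.append({"value": value, "replicate": rep, "error": str(exc)})
                continue
            per["entropy"].append(res.entropy)
            per["alpha_e"].append(res.alpha_e)
            per["omega"].append(res.omega)
            per["complexity"].append(res.complexity)
        row = {parameter: value, "n_ok": len(per["entropy"]), "n_failed": replicates - len(per["entropy"])}
        for key, vals in per.items():
            row[f"{key}_mean"] = float(np.mean(vals)) if vals else np.nan
            row[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        if lyapunov is not None:
            try:
                row["lyapunov"] = float(lyapunov(value))
            except Exception as exc:  # noqa: BLE001
                row["lyapunov"] = np.nan
                failures.append({"value": value, "replicate": "lyapunov", "error": str(exc)})
        rows.append(row)
    return SweepResult(
        parameter=parameter,
        grid=grid,
        table=pd.DataFrame(rows),
        replicates=replicates,
        seed=seed,
        failures=failures,
    )
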
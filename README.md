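# ordinoise

Ordinal-pattern machine learning for quantifying temporal correlations
and discriminating chaos from noise in scalar time series.

## The problem

Given a single measured series — a neural recording, an optical
intensity trace, the output of an unknown dynamical system — two basic
questions are surprisingly hard: *how strong are its temporal
correlations?* and *is it mainly deterministic or mainly stochastic?*
`ordinoise` answers both by reducing the series to two interpretable
features built from Bandt–Pompe ordinal patterns.

A window of `D` consecutive samples (default `D = 6`) is mapped to the
permutation that sorts it; sliding the window over a series of length
`N` yields `N − (D−1)·lag` patterns whose relative frequencies form the
ordinal distribution `P = {P(i); i = 1…D!}`. From `P` we compute the
normalised permutation entropy

    S = − Σᵢ P(i) ln P(i) / ln(D!)   ∈ [0, 1]

and the statistical complexity `C = S·Q(P, Pₑ)`, where `Q` is the
Jensen–Shannon divergence to the uniform distribution `Pₑ`, normalised
so that a point mass gives `Q = 1`.

The reference model is flicker noise (FN): a Gaussian process with power
spectrum `∝ 1/f^α`, where `α` measures correlation strength (`α = 0`
white, `α = 2` Brownian-like). The two features are:

1. **αₑ** — a single-hidden-layer feed-forward network
   (`X′ = f(W·X + b)`, `αₑ = f′(W′·X′ + b′)`) is trained on the `D!`
   ordinal probabilities of FN series with known `α` (grid `[0, 3]` step
   0.05, 20 series per `α`, `N = 2¹⁴` by default). Fed the ordinal
   probabilities of *any* series, it returns the exponent of the FN
   process whose ordinal statistics the series most resembles.
2. **Ω** — generate FN series with `α = αₑ` and the same length, average
   their permutation entropy `S_FN`, and form the relative difference

       Ω = |S_FN − S| / S_FN.

   Pure noise of any colour lands on the FN entropy curve, so `Ω ≈ 0`;
   a deterministic rule forbids orderings that no FN process forbids,
   displacing `S` from `S_FN` and making `Ω` large.

The package also ships the full benchmark suite used to validate the
method: colored-noise, uniform-noise, random-walk and noisy-sine
generators, the logistic / β-shift / Schuster maps with exact
big-integer orbits and Lyapunov estimation, and the Lorenz, Rössler,
three-wave and Hindmarsh–Rose flows with maxima-sequence extraction.

## Worked example

```python
import numpy as np
from ordinoise import (build_training_set, train, analyze, classify,
                       fn_null_threshold, iterate_map, uniform_noise)

N = 2**13
model = train(build_training_set(alpha_grid=np.arange(0, 3.001, 0.2),
                                 series_per_alpha=10, series_length=N,
                                 seed=1), seed=1)
threshold = fn_null_threshold(N, model, seed=5)   # 0.1020

for name, series in [("beta-shift beta=2 ", iterate_map("beta_x", 2, N)),
                     ("logistic r=4      ", iterate_map("logistic", 4.0, N)),
                     ("beta-shift beta=10", iterate_map("beta_x", 10, N)),
                     ("uniform noise     ", uniform_noise(N, seed=8))]:
    r = analyze(series, model, seed=9, warn_length=False)
    print(f"{name}: S={r.entropy:.4f} alpha_e={r.alpha_e:.2f} "
          f"Omega={r.omega:.5f} -> {classify(r, threshold)}")
```

prints

```
beta-shift beta=2 : S=0.7006  alpha_e=1.14  Omega=0.26622  -> mainly_deterministic
logistic r=4      : S=0.6276  alpha_e=0.00  Omega=0.36799  -> mainly_deterministic
beta-shift beta=10: S=0.9835  alpha_e=0.30  Omega=0.00734  -> mainly_stochastic
uniform noise     : S=0.9935  alpha_e=0.11  Omega=0.00084  -> mainly_stochastic
```

Moderately chaotic maps sit far from every FN entropy (`Ω` 30–400× the
noise floor) and are labelled deterministic. The β = 10 shift is the
documented blind spot: its orbit is so chaotic that the ordinal
distribution is noise-like (`S ≈ 0.98`), `Ω` drops below the
FN-calibrated null, and determinism goes undetected.

More narrative walk-throughs live in `examples/` (one script per
capability), and the same workflow is scriptable from a shell:

```
ordinoise train --seed 1 -o model.json
ordinoise simulate --kind beta_x --parameter 2 -n 16384 --seed 2 -o x.csv
ordinoise analyze --input x.csv --model model.json --threshold 0.01
ordinoise sweep --system beta_x --param beta --grid 1:10:0.5 --model model.json -o sweep.csv
```

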
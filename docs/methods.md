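# Methods

## The model

`ordinoise` characterises a scalar series by two features derived from
its ordinal-pattern statistics.

**Ordinal symbolisation.** A window of `D` samples spaced `lag` apart is
replaced by the permutation that sorts it ascending, identified by the
lexicographic (Lehmer) rank of the stable argsort, so ties resolve to
the earlier index. Sliding at unit step over a series of length `N`
gives `n_windows = N − (D−1)·lag` patterns; their relative frequencies
form the distribution `P` over the `D!` pattern slots. Ordinal patterns
depend only on ranks, so every quantifier downstream is exactly
invariant under strictly increasing transforms of the values — in
particular under the affine normalisations used by the generators.

**Quantifiers.** Normalised permutation entropy
`S = −Σ P ln P / ln(D!)` (natural log, `0·ln 0 := 0`, no pseudocounts);
Jensen–Shannon disequilibrium
`Q = Q₀·[H((P+Pₑ)/2) − H(P)/2 − H(Pₑ)/2]` against the uniform
distribution `Pₑ`, with
`Q₀ = −2·{((D!+1)/D!)·ln(D!+1) − 2·ln(2·D!) + ln(D!)}⁻¹` chosen so a
point mass gives exactly `Q = 1` (verified numerically in the tests);
statistical complexity `C = S·Q`, zero at both entropy extremes.

**The regressor.** A single-hidden-layer network (128 tanh units,
identity output) maps the `D!` ordinal probabilities of flicker noise —
Gaussian `1/f^α` noise — to the generating exponent `α`. The default
training set covers `α ∈ [0, 3]` in steps of 0.05 with 20 independent
series per grid point at `N = 2¹⁴`; this range contains every effective
exponent the benchmark systems produce (white noise 0, random walk
≈ 1.75, Brownian-like 2). Features are standardised per pattern (mean
and scale stored with the model); outputs are clipped to the training
label hull by default, since extrapolation of a dense network outside
its labels is meaningless. Applied to an arbitrary series, the returned
`αₑ` is the correlation exponent of the FN process whose ordinal
statistics the input most resembles.

**The determinism quantifier.** For an analysed series with entropy `S`
and estimate `αₑ`, the package generates `n_ref` fresh FN series of the
*same length* with `α = αₑ`, averages their permutation entropies into
`S_FN`, and reports `Ω = |S_FN − S| / S_FN`. `n_ref` defaults to 10; a
single realisation (`n_ref = 1`, also exposed) makes `Ω` noticeably
noisier without changing its meaning. Length matching is essential:
finite-sample entropy bias depends strongly on `N`, and comparing
entropies computed at different lengths produces spurious `Ω`. For
continuous flows, the length matched is that of the maxima sequence
actually analysed, not the raw trajectory.

**Classification.** No universal `Ω` threshold exists — the quantifier's
null level scales with the entropy bias at the given length — so
`classify` requires an explicit threshold and `fn_null_threshold`
computes a length-calibrated suggestion: mean + 3 sd of `Ω` over pure FN
series spanning the training grid. At `N = 2¹⁴` this suggestion is a few
times 10⁻², dominated by the residual α-recovery error at the steep
high-α end of the entropy curve.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `D` | 6 | pattern length; 720 slots. Larger D needs exponentially more data |
| `lag` | 1 | in-pattern sample spacing (multiscale lags out of scope) |
| α grid | 0:3:0.05 | training exponents (dimensionless) |
| series/α | 20 | training replicates per grid point |
| `N` | 2¹⁴ | training and analysis series length (samples) |
| `hidden_units` | 128 | hidden layer width |
| `l2_penalty` | 10.0 | ridge strength of the fit (see below) |
| `n_ref` | 10 | FN realisations averaged into `S_FN` |

## Numerical choices

- **Flicker synthesis** is frequency-domain: independent Gaussian
  Fourier coefficients scaled by `f^(−α/2)`, zero DC (zero mean),
  real Nyquist bin with doubled variance, inverse rFFT, unit-variance
  rescale. The expected log-log periodogram slope is `−α`; the tests
  check the fitted slope to ±0.1 over 10 seeds.
- **Optimiser.** The network is fitted by full-batch L-BFGS on
  ridge-penalised MSE rather than a stochastic optimiser: at this
  training-set size (1220 rows × 720 collinear features) quasi-Newton
  converges in a few hundred iterations and roughly halves the held-out
  recovery error relative to Adam with early stopping. A 90/10
  train/validation split (seeded permutation) is kept and the validation
  MSE is stored in the model metadata. The fairly strong default ridge
  penalty is selected on held-out α recovery; it also keeps predictions
  stable for inputs off the FN manifold. Training is deterministic given
  the seed.
- **Integer β-shift orbits.** In binary floating point, `x → 2x mod 1`
  is an exact bit shift: the orbit discards one significand bit per step
  and collapses onto 0 within ~53 iterations, and every integer β
  exhausts a 53-bit seed value similarly fast. Orbits for integer β are
  therefore iterated exactly in fixed-point big-integer arithmetic with
  `64 + n·log₂β` bits of precision, the initial condition extended below
  its float bits by a PRNG keyed to the initial condition itself (runs
  are reproducible without a seed). Non-integer β uses plain float64,
  where rounding keeps orbits generic. The shift map's Lyapunov exponent
  `ln β` is returned in closed form since `|f′| = β` everywhere.
- **Schuster map** near `x = 0` produces laminar phases that lengthen
  rapidly with `z`; the default burn-in is 10⁴ iterations and an orbit
  that lands exactly on the absorbing 0 (possible only in floating
  point) is reinjected at a generic constant.
- **Flows** are integrated with fixed-step RK4 — `dt = 0.01` for
  Lorenz/Rössler/three-wave, `dt = 0.05` for Hindmarsh–Rose, whose slow
  variable (`r = 0.006`) needs long horizons — with the first 10% of the
  horizon discarded as transient. Maxima sequences are insensitive to
  these choices; a step-halving test guards them. Divergence raises an
  error naming the blow-up time. The Hindmarsh–Rose defaults use the
  canonical bursting values `d = 5`, `I = 3.25` alongside `a = c = 1`,
  `b = 3`, `s = 4`, `x_r = −8/5`, `r = 0.006`.
- **Maxima** are strict three-point local maxima; plateaus and monotone
  segments contribute nothing.
- **Window count.** The sliding-window count at unit step is
  `N − (D−1)·lag`; the off-by-one relative to conventions that quote
  `N − D` windows is negligible at the default `N = 2¹⁴` but is fixed
  here once, since the count enters the entropy bias.
- **Serialisation.** Models are single JSON files (weights, activations,
  ordinal config, training metadata, format version); CLI outputs print
  floats with 17 significant digits so reruns are byte-identical and
  end-to-end determinism is testable.

## What the synthetic benchmarks do and do not show

The generators reproduce the study conditions the method was designed
around: stationary Gaussian colored noise, memoryless uniform noise,
integrated noise, chaotic maps spanning weak to extreme chaoticity,
intermittency, noisy periodicity, and chaotic flows reduced to maxima
sequences. They are clean, stationary, and exactly seeded. Real
recordings add features deliberately absent here — measurement noise
with structure, nonstationarity and drift, missing samples, quantisation
with heavy ties — so passing tests demonstrate correctness of the method
under its stated assumptions, not performance on any particular
experimental dataset. Tie handling is deterministic (earlier index
first) and is observable with integer-valued inputs.

## Known limitations

- Highly chaotic signals whose ordinal distribution is already uniform
  (e.g. the β = 10 shift, `S ≈ 0.99` at `N = 2¹⁴`) are indistinguishable
  from noise by construction; `Ω` falls below the FN null and
  determinism is not detected. This failure mode is asserted, not
  hidden.
- `αₑ` is only meaningful relative to the training length; analysing a
  series of a different length triggers a loud warning, and short series
  inflate `Ω` even for pure noise (the false-determinism artifact the
  length sweep exhibits).
- One model serves one ordinal configuration; `D ≠ 6` or `lag ≠ 1`
  require retraining.
- The Ω threshold suggestion is a calibration convenience, not a
  decision theory; borderline series deserve replicates and both
  features, not a single label.
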
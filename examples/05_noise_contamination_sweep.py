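"""Noise-contamination sweeps: when does determinism fade from view?

Mixes a sinusoid (two frequencies) and flicker noise with increasing
fractions eta of uniform white noise, and tabulates the mean Omega and
alpha_e per grid point.
"""

import numpy as np

from ordinoise import (
    build_training_set,
    flicker_noise,
    mix,
    sine_series,
    sweep,
    train,
    uniform_noise,
)

N = 2**13
model = train(build_training_set(alpha_grid=np.arange(0.0, 3.001, 0.2), series_per_alpha=10,
                                 series_length=N, seed=1), seed=1)
etas = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]

print("sine + uniform noise (Omega per eta):")
for freq in (0.01, 0.1):
    tau = 2.0 * np.pi / freq
    res = sweep("eta", etas,
                lambda eta, rng: mix(sine_series(tau, N), uniform_noise(N, seed=rng), eta),
                model, replicates=3, seed=2)
    row = "  ".join(f"{v:.4f}" for v in res.table["omega_mean"])
    print(f"  omega={freq:5.2f}:  {row}")

small_etas = [0.0, 0.01, 0.03, 0.1, 0.3, 1.0]
print(f"\nflicker (alpha=2) + uniform noise, eta = {small_etas}:")
res = sweep("eta", small_etas,
            lambda eta, rng: mix(flicker_noise(2.0, N, seed=rng), uniform_noise(N, seed=rng), eta),
            model, replicates=3, seed=3)
print("  alpha_e:", "  ".join(f"{v:.3f}" for v in res.table["alpha_e_mean"]))
print("  Omega  :", "  ".join(f"{v:.5f}" for v in res.table["omega_mean"]))

print("\nA fast sinusoid keeps a deterministic signature (Omega above the")
print("noise floor) to larger eta than a slow one.  For two mixed noises")
print("Omega stays near zero everywhere — both components are stochastic —")
print("while alpha_e slides from 2 to 0; the slide is fast because the")
print("smooth local increments of alpha=2 noise are easily overwhelmed.")
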
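"""Benchmark signal generators and their defining statistics.

Generates flicker noise (checking its spectral slope against the target
exponent), the beta-shift and Schuster maps (with Lyapunov exponents),
and a Hindmarsh-Rose bursting trajectory reduced to its spike-maxima
sequence.
"""

import math

import numpy as np
from scipy.signal import periodogram

from ordinoise import flicker_noise, integrate_flow, iterate_map, lyapunov_1d, maxima_series

print("flicker noise, N=2**14 (log-log periodogram slope should be -alpha):")
for alpha in (0.0, 1.0, 2.0):
    slopes = []
    for seed in range(5):
        f, p = periodogram(flicker_noise(alpha, 2**14, seed=seed).values)
        m = f > 0
        slopes.append(np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0])
    print(f"  alpha={alpha}: fitted slope {np.mean(slopes):+.3f}")

print("\n1-D chaotic maps (lambda = mean ln|f'| along the orbit):")
for family, p, exact in [("beta_x", 2.0, math.log(2)), ("beta_x", 10.0, math.log(10)),
                         ("logistic", 4.0, math.log(2))]:
    lam = lyapunov_1d(family, p, n_terms=200_000)
    print(f"  {family} param={p}: lambda={lam:.4f} (exact {exact:.4f})")

traj = integrate_flow("hindmarsh_rose", t_total=2000.0)
spikes = maxima_series(traj, "x")
print(f"\nHindmarsh-Rose: {len(spikes)} spike maxima from t=2000 of bursting dynamics;")
print("the maxima sequence is how continuous flows are fed to the ordinal analysis.")
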
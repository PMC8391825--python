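"""Ordinal-pattern quantifiers: entropy and complexity of noise vs chaos.

Encodes two series of 2**14 samples — uniform white noise and the fully
chaotic logistic map — into D=6 ordinal-pattern distributions and prints
the normalised permutation entropy S, Jensen-Shannon disequilibrium Q
and statistical complexity C = S*Q.
"""

from ordinoise import (
    OrdinalConfig,
    iterate_map,
    ordinal_distribution,
    statistical_complexity,
    uniform_noise,
)

config = OrdinalConfig(D=6, lag=1)

for name, series in [
    ("uniform white noise", uniform_noise(2**14, seed=1)),
    ("logistic map r=4   ", iterate_map("logistic", 4.0, 2**14)),
]:
    dist = ordinal_distribution(series, config)
    c = statistical_complexity(dist)
    occupied = int((dist.counts > 0).sum())
    print(f"{name}: S={c.entropy:.4f}  Q={c.divergence:.4f}  C={c.complexity:.4f}  "
          f"patterns occupied {occupied}/720")

print()
print("White noise fills all 720 patterns evenly (S near 1, C near 0);")
print("the chaotic map forbids many orderings, so S drops and C is large —")
print("structure that a histogram of the values alone would not reveal.")
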
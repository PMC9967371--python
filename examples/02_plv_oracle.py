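"""The PLV estimator against its closed-form oracle.

Phase differences drawn von Mises(0, kappa) have population phase
locking value I1(kappa)/I0(kappa) — a ratio of modified Bessel
functions. The sample PLV of a long synthetic phase pair should land on
that value, which is how the estimator is validated without any real
data.
"""
import numpy as np

from plvconnect import bessel_ratio_plv, generate_coupled_phase_pair, plv_pair

print(f"{'kappa':>6} {'target I1/I0':>13} {'sample PLV':>11} {'error':>8}")
for kappa in (0.0, 0.5, 1.0, 2.0, 5.0):
    target = bessel_ratio_plv(kappa)
    p1, p2 = generate_coupled_phase_pair(90_000, kappa, 0.05, seed=42)
    est = plv_pair(p1, p2)
    print(f"{kappa:>6.1f} {target:>13.4f} {est:>11.4f} {est - target:>+8.4f}")

print()
print("kappa = 0 is uncoupled: the tiny positive sample PLV is the")
print(f"finite-sample resultant bias, ~sqrt(pi)/(2 sqrt(N)) = "
      f"{np.sqrt(np.pi) / (2 * np.sqrt(90_000)):.4f}")
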
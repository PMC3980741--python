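"""Scale-space laws: fractal lengths, walls, and log-periodic fitting.

Evaluates the solutions of the scale differential equations and recovers
log-periodic parameters from a noisy synthetic event series.
"""

import numpy as np

import macroquant as mq

# a fractal coordinate: scale-independent part L0 plus power-law divergence
p = mq.ScaleLawParams(L0=1.0, lam=1.0, tau_F=1.0)
for eps in (10.0, 1.0, 0.1, 0.01):
    print(f"L(eps={eps:>5}) = {mq.fractal_length(eps, p):8.2f}")
print("-> below the transition scale lam the measured length diverges "
      "as (lam/eps)^tau_F; above it, L -> L0.\n")

# scale harmonic oscillator: an impassable wall scale (a 'membrane')
posc = mq.ScaleLawParams(lam0=1.0, lam1=0.1, tau0=1.0)
inner = mq.ScaleLawParams(lam0=1.0, lam1=0.1, tau0=1.0)
outer = mq.ScaleLawParams(tau_F=0.0, lam=0.1)
for r in (1e-4, 0.05, 0.099, 0.5):
    D_eff = mq.wall_dimension_profile(r, inner, outer)
    print(f"effective fractal dimension at r={r:>6}: {D_eff:8.2f}")
print("-> constant dimension inside, divergence at the wall scale "
      "(the 'membrane'), constant outside.\n")

# log-periodic fit: recover (nu, omega, b) from a noisy series
series = mq.logperiodic_series(nu=0.5, b=0.3, omega=6.0, noise=0.01, n=50, seed=0)
fit = mq.fit_log_periodic(series, seed=1, n_permutations=200)
print(f"log-periodic fit: omega = {fit.params.omega:.3f} (true 6), "
      f"nu = {fit.params.nu:.3f} (true 0.5), b = {fit.params.b_lp:.3f} (true 0.3)")
print(f"permutation p-value of the oscillation: {fit.p_value:.3f}")
print("-> the oscillatory correction cos(omega ln eps) is detected and its "
      "frequency recovered within a fraction of a percent.")
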
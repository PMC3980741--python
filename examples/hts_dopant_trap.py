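"""Cuprate superconductivity: dopant-density wells trapping electron pairs."""

import numpy as np

import macroquant as mq

# a dopant site is a dip in the static charge density n_d
grid = mq.GridSpec(extent=(20.0,), points=(300,))
nd = mq.gaussian_dip_density(grid, depth=0.8, width=1.0)
model = mq.DopantModel(n_d=nd, grid=grid, hbar=1.0, m_e=1.0)

Qd = mq.dopant_quantum_potential(model)
x = grid.axes()[0]
print(f"Q_d minimum at x = {x[np.nanargmin(Qd)]:.2f} (dip center at 10.00), "
      f"depth {np.nanmin(Qd):.2f}")
bound = mq.dopant_bound_states(model, n_states=6)
print(f"bound states in the dopant well: {bound.n_states}, "
      f"energies {np.round(bound.energies, 3)}")
print("-> the density modulation alone creates a quantum-potential well "
      "deep enough to trap a pair; a uniform density traps nothing.\n")

# the counting arithmetic at optimal doping
print(f"superfluid fraction 2/(8+2) = {mq.superfluid_fraction(2, 8):.1f}")
lo = mq.well_side_length(0.155, 8, 3.9)
hi = mq.well_side_length(0.155, 10, 3.9)
print(f"well side for 8-10 charges at p = 0.155: {lo:.0f}-{hi:.0f} Angstrom")
print("-> matches the observed ~30 Angstrom LDOS modulation size and the "
      "measured 0.2 superfluid fraction.")
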
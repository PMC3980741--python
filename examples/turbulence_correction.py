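"""Lagrangian turbulence: K41 fractal fluctuations and the acceleration-variance correction."""

import macroquant as mq

# K41 velocity-path ensemble: delta_v ~ |delta_t|^(1/2)
stats = mq.lagrangian_velocity_simulator(D_v=1.0, dt=1e-3, n_steps=4000,
                                         n_paths=30, seed=42)
print(f"structure-function scaling exponent: {stats.scaling_exponent:.3f} (K41: 1)")
print(f"<delta v^2>/delta t over 2 D_v:      {stats.diffusion_ratio:.3f} (exact: 1)")
print(f"sigma_da / sigma_a at resolution dt: {stats.sigma_da / stats.sigma_a:.2f}")
print("-> acceleration and its increment are the same order: the "
      "two-valuedness of the velocity derivative is visible in the paths.\n")

# the velocity-space quantum potential and its integrated force
D_v, sigma_v = 1.0, 1.0
print(f"Q_v at v=0: {mq.velocity_quantum_potential(0.0, sigma_v, D_v):.1f} "
      f"(repulsive core, zero at v = sqrt(6) sigma_v)")
print(f"position force at x=2: {mq.position_quantum_force(2.0, D_v, sigma_v):.1f} "
      "(linear, repulsive harmonic)\n")

# the printed laboratory numbers: R_lambda = 690 von Karman flow
ratio = mq.intermediate_ratio(0.071, 87.0, 0.039)
frac = mq.classical_fraction(0.071, 87.0, 0.039)
a0c = mq.a0_geometric_correction(4.5, 6.2)
print(f"L/(sigma_a T_L^2) = {ratio:.2f}, square = {ratio**2:.2f} (~1/3)")
print(f"classical variance fraction 1 - L^2/(sigma_a^2 T_L^4) = {frac:.2f} (~2/3)")
print(f"sqrt(1 - a0_DNS/a0_exp) = {a0c:.2f}")
print("-> the geometric (quantum-potential) term accounts for the gap "
      "between simulated (a0 ~ 4.5) and measured (a0 ~ 6.2) acceleration "
      "variance: 0.52 predicted vs 0.54 from the flow geometry.")
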
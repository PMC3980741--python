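"""Worked quantitative applications: Lagrangian turbulence and HTS dopant traps.

**Turbulence.** In the Lagrangian K41 regime velocity increments scale as
``delta_v ~ |delta_t|^(1/2)`` — the same critical fractal-fluctuation law
that underlies the macroquantum construction, transposed to velocity space.
The velocity-space constant is fixed by the energy dissipation rate,
``2 D_v = C0 eps`` (C0 the Kolmogorov constant, literature range 4-9), and
equals ``sigma_v^2 / T_L`` in terms of the velocity dispersion and the
Lagrangian integral time.  For a Gaussian velocity distribution the
velocity-space quantum potential is
``Q_v = -D_v^2 (v^2 - 6 sigma_v^2) / (2 sigma_v^4)``; its force, integrated
in time, is the repulsive harmonic term ``F = (D_v^2 / sigma_v^4) x`` which
adds a geometric contribution to the acceleration variance,
``sigma_a^2 = (sigma_a)_cl^2 + D_v^4/sigma_v^8 sigma_x^2``, hence
``(sigma_a)_cl^2 / sigma_a^2 = 1 - L^2/(sigma_a^2 T_L^4)`` with
``sigma_x ~ L`` the Lagrangian length scale.

**HTS.** In cuprate superconductors the static part of the doping-induced
charge density ``n_d`` creates a microscopic quantum potential
``Q_d = -(hbar^2/2m) Lap(sqrt n_d)/sqrt(n_d)`` whose wells can trap electron
pairs; the mobile fraction obeys a Schrodinger equation in ``phi + Q_d``.
With 4 dopant defects bringing 8 charges plus one trapped pair, the
superfluid fraction is 2/(8+2) = 0.2 at optimal doping, and at doping
p = 0.155 = 1/6.5 the 8-10 charges in a well occupy ``sqrt(n/p)`` lattice
units per side (7.2-8.1 in units of d_CuO = 3.9 Angstrom, i.e. 28-32 A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import (
    EigenSolution,
    GridSpec,
    MacroParams,
    PotentialSpec,
    stationary_states,
)
from .errors import ConfigurationError, DomainError, RegimeError
from .representations import quantum_potential

__all__ = [
    "TurbulenceParams",
    "DopantModel",
    "LagrangianStats",
    "dv_from_k41",
    "velocity_quantum_potential",
    "position_quantum_force",
    "acceleration_variance_total",
    "classical_fraction",
    "intermediate_ratio",
    "a0_geometric_correction",
    "lagrangian_velocity_simulator",
    "dopant_quantum_potential",
    "dopant_bound_states",
    "superfluid_fraction",
    "well_side_length",
]


@dataclass
class TurbulenceParams:
    """K41 quantities (SI units: m, s).

    ``D_v`` is the velocity-space macroquantum constant; consistency
    requires ``2 D_v = C0 * eps_diss`` and ``D_v = sigma_v^2 / T_L`` when
    the respective fields are set.
    """

    C0: float | None = None
    eps_diss: float | None = None
    D_v: float | None = None
    sigma_v: float | None = None
    T_L: float | None = None
    L_int: float | None = None
    sigma_a: float | None = None
    a0_dns: float | None = None
    a0_exp: float | None = None
    nu_visc: float | None = None

    def __post_init__(self):
        for name in (
            "C0", "eps_diss", "D_v", "sigma_v", "T_L", "L_int",
            "sigma_a", "a0_dns", "a0_exp", "nu_visc",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.D_v is None and self.C0 is not None and self.eps_diss is not None:
            self.D_v = dv_from_k41(self.C0, self.eps_diss)
        elif (
            self.D_v is not None
            and self.C0 is not None
            and self.eps_diss is not None
            and not np.isclose(2.0 * self.D_v, self.C0 * self.eps_diss)
        ):
            raise ConfigurationError("2 D_v = C0 * eps_diss violated")
        if self.D_v is None and self.sigma_v is not None and self.T_L is not None:
            self.D_v = self.sigma_v**2 / self.T_L
        elif (
            self.D_v is not None
            and self.sigma_v is not None
            and self.T_L is not None
            and not np.isclose(self.D_v, self.sigma_v**2 / self.T_L)
        ):
            raise ConfigurationError("D_v = sigma_v^2 / T_L violated")


def dv_from_k41(C0: float, eps_diss: float) -> float:
    """Velocity-space constant from the K41 relation ``D_v = C0 * eps / 2``."""
    if C0 <= 0 or eps_diss <= 0:
        raise DomainError("C0 and eps_diss must be positive")
    return 0.5 * C0 * eps_diss


def velocity_quantum_potential(v, sigma_v: float, D_v: float):
    """``Q_v = -D_v^2 (v^2 - 6 sigma_v^2) / (2 sigma_v^4)``.

    Closed form of the quantum potential of a centered isotropic 3D Gaussian
    velocity distribution (unit inertial parameter); positive at the center
    (+3 D_v^2/sigma_v^2), zero at |v| = sqrt(6) sigma_v, confining beyond.
    """
    if sigma_v <= 0:
        raise DomainError("sigma_v must be positive")
    v = np.asarray(v, dtype=float)
    return -(D_v**2) * (v**2 - 6.0 * sigma_v**2) / (2.0 * sigma_v**4)


def position_quantum_force(x, D_v: float, sigma_v: float):
    """Time-integrated quantum force ``F(x) = (D_v^2 / sigma_v^4) x``.

    A linear repulsive (same sign as x) harmonic-oscillator-type force per
    unit mass — the geometric correction missing from classical DNS.
    """
    if sigma_v <= 0:
        raise DomainError("sigma_v must be positive")
    return (D_v**2 / sigma_v**4) * np.asarray(x, dtype=float)


def acceleration_variance_total(
    sigma_a_cl: float, D_v: float, sigma_v: float, sigma_x: float
) -> float:
    """``sigma_a^2 = (sigma_a)_cl^2 + D_v^4 / sigma_v^8 * sigma_x^2``."""
    if min(sigma_a_cl, D_v, sigma_v, sigma_x) <= 0:
        raise DomainError("all inputs must be positive")
    return sigma_a_cl**2 + D_v**4 / sigma_v**8 * sigma_x**2


def intermediate_ratio(L_int: float, sigma_a: float, T_L: float) -> float:
    """Dimensionless ``L / (sigma_a T_L^2)`` — the square root of the
    geometric correction fraction."""
    if min(L_int, sigma_a, T_L) <= 0:
        raise DomainError("all inputs must be positive")
    return L_int / (sigma_a * T_L**2)


def classical_fraction(L_int: float, sigma_a: float, T_L: float) -> float:
    """Classical share of the acceleration variance:
    ``(sigma_a)_cl^2 / sigma_a^2 = 1 - L^2 / (sigma_a^2 T_L^4)``."""
    r = intermediate_ratio(L_int, sigma_a, T_L)
    frac = 1.0 - r**2
    if frac < 0:
        raise RegimeError("geometric correction exceeds the total variance")
    return frac


def a0_geometric_correction(a0_dns: float, a0_exp: float) -> float:
    """``sqrt(1 - a0_DNS / a0_exp)``: the share of the normalized
    acceleration variance attributed to the geometric (quantum-potential)
    term, from DNS vs experimental values of a0."""
    if a0_dns <= 0 or a0_exp <= 0:
        raise DomainError("a0 values must be positive")
    if a0_dns > a0_exp:
        raise RegimeError("a0_dns exceeds a0_exp: no geometric deficit")
    return float(np.sqrt(1.0 - a0_dns / a0_exp))


@dataclass
class LagrangianStats:
    """Summary statistics of a simulated Lagrangian velocity ensemble."""

    velocities: np.ndarray  # (n_paths, n_steps + 1)
    dt: float
    D_v: float
    structure_lags: np.ndarray
    structure_values: np.ndarray  # <delta v^2>(lag)
    scaling_exponent: float
    diffusion_ratio: float  # <delta v^2>/delta t at the smallest lag / (2 D_v)
    sigma_a: float  # dispersion of dv/dt at resolution dt
    sigma_da: float  # dispersion of acceleration increments at resolution dt
    forward_minus_backward_rms: float  # rms of d+X/dt - d-X/dt
    second_derivative_rms: float  # rms of X'' * |dt| (same quantity, Taylor)


def lagrangian_velocity_simulator(
    D_v: float,
    dt: float,
    n_steps: int,
    n_paths: int,
    friction: float | None = None,
    seed: int | np.random.Generator = 0,
    max_lag_decades: float = 2.0,
) -> LagrangianStats:
    """Simulate K41 velocity paths ``dV = dv + zeta sqrt(2 D_v) dt^(1/2)``.

    The fractal fluctuation dominates at small lags: the second-order
    Lagrangian structure function obeys ``<delta v^2> = 2 D_v * delta_t``
    (exponent 1 in ``delta_t``, i.e. delta_v ~ |delta_t|^(1/2)).  An
    optional Langevin friction ``dv = -friction * v dt`` bounds the variance
    at large times without changing the small-lag scaling.  Also reported:
    the acceleration dispersion and its increment dispersion at the sampling
    resolution (same order of magnitude — the two-valuedness signature) and
    the forward/backward derivative pair, which differ by ``X'' |dt|``.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.zeros(n_paths)
    traj = np.empty((n_paths, n_steps + 1))
    traj[:, 0] = v
    sq = np.sqrt(2.0 * D_v * dt)
    for k in range(n_steps):
        dv = -friction * v * dt if friction else 0.0
        v = v + dv + sq * rng.standard_normal(n_paths)
        traj[:, k + 1] = v

    n_lags = int(max_lag_decades / np.log10(2.0)) + 1
    lags = np.unique(np.round(np.logspace(0, max_lag_decades, 24)).astype(int))
    lags = lags[lags < n_steps // 2]
    s2 = np.array(
        [np.mean((traj[:, lag:] - traj[:, :-lag]) ** 2) for lag in lags]
    )
    slope = np.polyfit(np.log(lags * dt), np.log(s2), 1)[0]
    diffusion_ratio = float(s2[0] / (lags[0] * dt) / (2.0 * D_v))

    a = np.diff(traj, axis=1) / dt
    da = np.diff(a, axis=1)
    sigma_a = float(a.std())
    sigma_da = float(da.std())
    # d+X/dt - d-X/dt at interior samples equals the discrete X'' * |dt|
    fwd = (traj[:, 2:] - traj[:, 1:-1]) / dt
    bwd = (traj[:, 1:-1] - traj[:, :-2]) / dt
    diff_fb = fwd - bwd
    second = (traj[:, 2:] - 2 * traj[:, 1:-1] + traj[:, :-2]) / dt**2 * dt
    return LagrangianStats(
        velocities=traj,
        dt=dt,
        D_v=D_v,
        structure_lags=lags * dt,
        structure_values=s2,
        scaling_exponent=float(slope),
        diffusion_ratio=diffusion_ratio,
        sigma_a=sigma_a,
        sigma_da=sigma_da,
        forward_minus_backward_rms=float(np.sqrt(np.mean(diff_fb**2))),
        second_derivative_rms=float(np.sqrt(np.mean(second**2))),
    )


# ---------------------------------------------------------------------------
# HTS dopant-trap model


@dataclass
class DopantModel:
    """Static dopant-charge density and microscopic constants.

    The dopant fraction of the charge fluid is assumed static (zero velocity
    and time derivative); its density fluctuations alone build the interior
    potential well.  ``hbar`` and the carrier mass select the microscopic
    branch of the theory (S0 = hbar, D = hbar / 2 m_e).
    """

    n_d: np.ndarray | Callable
    grid: GridSpec
    hbar: float = 1.0
    m_e: float = 1.0
    phi_ext: np.ndarray | float = 0.0

    def density_on_grid(self) -> np.ndarray:
        if callable(self.n_d):
            nd = np.asarray(self.n_d(*self.grid.meshgrid()), dtype=float)
        else:
            nd = np.asarray(self.n_d, dtype=float)
        if nd.shape != self.grid.shape:
            raise ConfigurationError("n_d shape does not match grid")
        if np.any(nd < 0):
            raise DomainError("n_d must be nonnegative")
        if nd.max() <= 0:
            raise DomainError("n_d is identically zero")
        return nd

    @property
    def macro_params(self) -> MacroParams:
        # S0 = hbar <=> D = hbar / (2 m_e); then 2 m D^2 = hbar^2 / (2 m_e)
        return MacroParams(D=self.hbar / (2.0 * self.m_e), m=self.m_e)


def dopant_quantum_potential(model: DopantModel) -> np.ndarray:
    """``Q_d = -(hbar^2 / 2 m_e) Lap(sqrt n_d) / sqrt(n_d)``.

    A local minimum of the dopant density (a dopant site) produces a
    potential well in Q_d around it: the trap that binds Cooper pairs.
    The dopant density is a bulk modulation observed through the grid
    window, so the edge treatment extrapolates past the boundary rather
    than assuming the density vanishes there.
    """
    nd = model.density_on_grid()
    return quantum_potential(nd, model.macro_params, model.grid, edge="extrapolate")


def dopant_bound_states(model: DopantModel, n_states: int = 4) -> EigenSolution:
    """Stationary states of the mobile fraction in ``phi_ext + Q_d``.

    Solves ``-(hbar^2/2m) Lap psi + (phi + Q_d) psi = E psi`` and returns
    only the bound states: energies below the asymptotic (edge-averaged)
    total potential.  An empty result is a valid outcome (no trap).
    """
    Qd = dopant_quantum_potential(model)
    Qd = np.nan_to_num(Qd, nan=0.0)
    phi = np.broadcast_to(
        np.asarray(model.phi_ext, dtype=float), model.grid.shape
    )
    total = phi + Qd
    edge = np.concatenate([total.ravel()[:1], total.ravel()[-1:]])
    if model.grid.ndim == 1:
        asymptote = float(np.mean([total[0], total[-1]]))
    else:
        border = np.ones(model.grid.shape, dtype=bool)
        border[(slice(1, -1),) * model.grid.ndim] = False
        asymptote = float(total[border].mean())
    sol = stationary_states(
        PotentialSpec(phi=total), model.grid, model.macro_params, n_states
    )
    keep = sol.energies < asymptote
    return EigenSolution(
        energies=sol.energies[keep],
        states=[s for s, k in zip(sol.states, keep) if k],
    )


def superfluid_fraction(n_paired: int, n_total_charges: int) -> float:
    """Superfluid-to-normal ratio ``n_paired / (n_total_charges + n_paired)``.

    With one trapped pair (2 electrons) per optimal 4-defect/8-charge
    configuration: 2/(8+2) = 0.2.
    """
    if n_paired < 0 or n_total_charges <= 0 or n_paired > n_total_charges + n_paired:
        raise DomainError("need 0 <= n_paired and positive total charges")
    return n_paired / (n_total_charges + n_paired)


def well_side_length(p_doping: float, n_charges: int, d_unit: float) -> float:
    """Side of a potential well holding ``n_charges`` at doping ``p``:
    ``sqrt(n_charges / p) * d_unit`` (each charge occupies 1/p unit cells)."""
    if not (0.0 < p_doping <= 1.0):
        raise DomainError("doping fraction must lie in (0, 1]")
    if n_charges < 1 or d_unit <= 0:
        raise DomainError("need n_charges >= 1 and positive lattice unit")
    return float(np.sqrt(n_charges / p_doping) * d_unit)
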
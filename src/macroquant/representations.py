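"""Exact interconversion among the equivalent representations of the dynamics.

One and the same geodesic equation of a fractal space can be written as:

* a **wave** (Schrodinger) equation for ``psi = sqrt(P) exp(i theta)``;
* a **hydrodynamic** system — continuity plus an Euler equation for
  ``(P, V)`` with ``V = 2 D grad(theta)`` and an extra quantum-type potential
  ``Q = -2 m D^2 Lap(sqrt P)/sqrt P``;
* a **two-fluid** system for the real and imaginary parts of the complex
  velocity ``V - i U`` with ``U = D grad(ln P)``;
* a **diffusive** system — a forward Fokker-Planck equation for
  ``(P, v_plus)`` with ``v_plus = V + D grad(ln P)`` and a velocity-dependent
  potential ``Q_plus = -m D (v_plus . grad ln P + D Lap ln P)``.

Reversing the sign of Q turns the self-organizing dynamics into ordinary
diffusion (the "diffusion potential"), which is the hydrodynamic face of the
heat equation under the change of variable ``V = v - D grad(ln P)``.

Node handling: all logarithmic/ratio quantities are singular where P
vanishes; cells with ``P < floor * max(P)`` (default floor 1e-12) are masked
(NaN in returned potential/velocity fields) and excluded from residual
norms.  Phase reconstruction integrates along a spanning tree of the grid
and verifies every elementary loop circulation, since only potential
(curl-free) flows admit a single-valued wave function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import (
    GridSpec,
    MacroParams,
    PotentialSpec,
    WaveField,
    apply_laplacian,
    evolve,
    gradient,
)
from .errors import (
    ConfigurationError,
    DomainError,
    NumericalBlowupError,
    RepresentationError,
)

__all__ = [
    "HydroField",
    "TwoFluidField",
    "DiffusiveField",
    "PathEnsemble",
    "wave_to_hydro",
    "hydro_to_wave",
    "wave_to_diffusive",
    "diffusive_to_wave",
    "quantum_potential",
    "quantum_potential_log_form",
    "quantum_potential_plus",
    "diffusion_potential",
    "classical_to_hydro",
    "energy_field",
    "energy_field_diffusive",
    "evolve_hydro",
    "evolve_fokker_planck",
    "two_fluid",
    "geodesic_residual",
    "make_fractal_paths",
    "gibbs_entropy",
]

DENSITY_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# containers


@dataclass
class HydroField:
    """Probability density P and curl-free velocity V (one component per axis)."""

    P: np.ndarray
    V: np.ndarray  # shape (ndim,) + grid.shape
    grid: GridSpec
    params: MacroParams
    t: float = 0.0
    mask: np.ndarray | None = None  # True where fields are reliable

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.P.shape != self.grid.shape:
            raise ConfigurationError("P shape does not match grid")
        if self.V.shape != (self.grid.ndim,) + self.grid.shape:
            raise ConfigurationError("V must have one component per axis")
        if np.any(self.P < 0):
            raise DomainError("P must be nonnegative")
        tot = self.P.sum() * self.grid.cell_volume
        if tot <= 0:
            raise DomainError("P must have positive integral")
        self.P = self.P / tot
        if self.mask is None:
            self.mask = self.P > DENSITY_FLOOR * self.P.max()


@dataclass
class TwoFluidField:
    """Real and imaginary parts (V, U) of the complex velocity V - iU."""

    V: np.ndarray
    U: np.ndarray
    grid: GridSpec
    params: MacroParams
    mask: np.ndarray | None = None
    residual_V: float | None = None  # relative residual of the V-equation
    residual_U: float | None = None  # relative residual of the U-equation


@dataclass
class DiffusiveField:
    """Density P with forward velocity v_plus (diffusion coefficient D)."""

    P: np.ndarray
    v_plus: np.ndarray  # shape (ndim,) + grid.shape
    grid: GridSpec
    params: MacroParams
    t: float = 0.0
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.v_plus = np.asarray(self.v_plus, dtype=float)
        if self.P.shape != self.grid.shape:
            raise ConfigurationError("P shape does not match grid")
        if self.v_plus.shape != (self.grid.ndim,) + self.grid.shape:
            raise ConfigurationError("v_plus must have one component per axis")
        tot = self.P.sum() * self.grid.cell_volume
        if tot <= 0:
            raise DomainError("P must have positive integral")
        self.P = self.P / tot
        if self.mask is None:
            self.mask = self.P > DENSITY_FLOOR * self.P.max()

    @property
    def v_minus(self) -> np.ndarray:
        """Backward velocity ``v_minus = v_plus - 2 D grad(ln P)``."""
        glnP = _grad_log(self.P, self.grid)
        return self.v_plus - 2.0 * self.params.D * glnP


@dataclass
class PathEnsemble:
    """Sampled fractal paths ``dX = v dt + zeta sqrt(2 D) |dt|^(1/2)``."""

    positions: np.ndarray  # (n_paths, n_steps + 1, ndim)
    dt: float
    params: MacroParams

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.positions, axis=1)

    def msd(self) -> np.ndarray:
        """Mean squared displacement from the origin at each time."""
        disp = self.positions - self.positions[:, :1]
        return (disp**2).sum(axis=-1).mean(axis=0)


# ---------------------------------------------------------------------------
# differential helpers (floored, mask-aware)


def _floored(P: np.ndarray, floor: float = DENSITY_FLOOR) -> np.ndarray:
    pmax = P.max()
    if pmax <= 0:
        raise DomainError("density is identically zero")
    return np.maximum(P, floor * pmax)


def _grad_log(P: np.ndarray, grid: GridSpec) -> np.ndarray:
    return np.stack(gradient(np.log(_floored(P)), grid))


def _mask_of(P: np.ndarray, floor: float = DENSITY_FLOOR) -> np.ndarray:
    return P > floor * P.max()


def _reliable_mask(P: np.ndarray, floor: float = DENSITY_FLOOR) -> np.ndarray:
    """Cells above the floor whose full finite-difference stencil is too.

    Derivative-based quantities are only trustworthy where no neighbor has
    been floored, so the raw mask is eroded by one cell.
    """
    from scipy.ndimage import binary_erosion

    raw = _mask_of(P, floor)
    structure = np.ones((3,) * P.ndim, dtype=bool)
    return binary_erosion(raw, structure=structure, border_value=True)


def _apply_mask(field_arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.array(field_arr, dtype=float, copy=True)
    out[..., ~mask] = np.nan
    return out


def _lap_extrapolated(f: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Laplacian with linear extrapolation past box walls.

    For log-density fields the wall value is not zero (ln P is large and
    negative there), so the Dirichlet stencil of :func:`apply_laplacian`
    would inject huge spurious curvature at the edge cells.
    """
    if grid.boundary == "periodic":
        return apply_laplacian(f, grid)
    out = np.zeros_like(f, dtype=float)
    for ax, dx in enumerate(grid.spacing):
        pad = [(0, 0)] * f.ndim
        pad[ax] = (1, 1)
        fp = np.pad(f, pad, mode="reflect", reflect_type="odd")
        sl_p = [slice(None)] * f.ndim
        sl_m = [slice(None)] * f.ndim
        sl_p[ax] = slice(2, None)
        sl_m[ax] = slice(0, -2)
        out += (fp[tuple(sl_p)] - 2.0 * f + fp[tuple(sl_m)]) / dx**2
    return out


def _q_floored(P: np.ndarray, grid: GridSpec, params: MacroParams) -> np.ndarray:
    """Quantum potential on the floored density (no NaNs; for internal use)."""
    s = np.sqrt(_floored(P))
    return -2.0 * params.m * params.D**2 * apply_laplacian(s, grid) / s


# ---------------------------------------------------------------------------
# potentials


def quantum_potential(
    P: np.ndarray,
    params: MacroParams,
    grid: GridSpec,
    edge: Literal["dirichlet", "extrapolate"] = "dirichlet",
) -> np.ndarray:
    """Macroquantum potential ``Q = -2 m D^2 Lap(sqrt P) / sqrt P``.

    Masked (NaN) where P is below the density floor.  The identical form
    applies to any density-like field, e.g. a chemical concentration or a
    velocity-space probability density.  ``edge`` selects the boundary
    treatment on box grids: ``dirichlet`` for confined states (P vanishes
    at the walls), ``extrapolate`` for bulk densities observed through a
    finite window (P continues smoothly past the edge).
    """
    P = np.asarray(P, dtype=float)
    if edge == "extrapolate":
        s = np.sqrt(_floored(P))
        Q = -2.0 * params.m * params.D**2 * _lap_extrapolated(s, grid) / s
    else:
        Q = _q_floored(P, grid, params)
    return _apply_mask(Q, _reliable_mask(P))


def quantum_potential_log_form(
    P: np.ndarray, params: MacroParams, grid: GridSpec
) -> np.ndarray:
    """Same potential via ``Q = -m D^2 {Lap ln P + (1/2)(grad ln P)^2}``."""
    P = np.asarray(P, dtype=float)
    lnP = np.log(_floored(P))
    g = np.stack(gradient(lnP, grid))
    Q = -params.m * params.D**2 * (
        apply_laplacian(lnP, grid) + 0.5 * (g**2).sum(axis=0)
    )
    return _apply_mask(Q, _reliable_mask(P))


def diffusion_potential(
    P: np.ndarray, params: MacroParams, grid: GridSpec
) -> np.ndarray:
    """Sign-reversed quantum potential ``+2 m D^2 Lap(sqrt P)/sqrt P = -Q``.

    Subjecting a fluid to this potential yields the hydrodynamic picture of
    ordinary diffusion: self-organization runs exactly in reverse.
    """
    return -quantum_potential(P, params, grid)


def quantum_potential_plus(d: DiffusiveField) -> np.ndarray:
    """Velocity-dependent potential ``Q+ = -m D (v+ . grad ln P + D Lap ln P)``."""
    D, m = d.params.D, d.params.m
    lnP = np.log(_floored(d.P))
    g = np.stack(gradient(lnP, d.grid))
    Qp = -m * D * ((d.v_plus * g).sum(axis=0) + D * apply_laplacian(lnP, d.grid))
    return _apply_mask(Qp, _reliable_mask(d.P))


def energy_field(h: HydroField, phi: np.ndarray) -> np.ndarray:
    """Pointwise energy ``E = (1/2) m V^2 + Q + phi`` (NaN at masked cells)."""
    Q = quantum_potential(h.P, h.params, h.grid)
    return 0.5 * h.params.m * (h.V**2).sum(axis=0) + Q + phi


def energy_field_diffusive(d: DiffusiveField, phi: np.ndarray) -> np.ndarray:
    """Pointwise energy ``E = (1/2) m v+^2 + phi + Q+`` — equals the hydro form."""
    Qp = quantum_potential_plus(d)
    return 0.5 * d.params.m * (d.v_plus**2).sum(axis=0) + phi + Qp


# ---------------------------------------------------------------------------
# representation maps


def wave_to_hydro(w: WaveField) -> HydroField:
    """``P = |psi|^2`` and ``V = 2 D grad(theta) = 2 D Im(grad psi / psi)``."""
    w = w.normalized()
    P = w.density
    mask = _mask_of(P)
    psi_safe = np.where(np.abs(w.psi) > 0, w.psi, 1.0)
    V = 2.0 * w.params.D * np.stack(
        [np.imag(g / psi_safe) for g in gradient(w.psi, w.grid)]
    )
    V[..., ~mask] = 0.0
    return HydroField(P=P, V=V, grid=w.grid, params=w.params, t=w.t, mask=mask)


def _integrate_phase(Vred: np.ndarray, grid: GridSpec, loop_tol: float) -> np.ndarray:
    """Integrate a reduced gradient field (V / 2D) to a scalar phase.

    Spanning-tree integration: along axis 0 first, then along each remaining
    axis row by row.  Every elementary plaquette circulation is checked
    against ``loop_tol``; a violation means the flow is not potential.
    """
    ndim = grid.ndim
    dxs = grid.spacing

    def edge(g, axis, dx):
        # trapezoid edge integral from node k to node k+1 along `axis`
        lo = np.take(g, range(0, g.shape[axis] - 1), axis=axis)
        hi = np.take(g, range(1, g.shape[axis]), axis=axis)
        return 0.5 * (lo + hi) * dx

    # elementary plaquette circulations (all axis pairs)
    for a in range(ndim):
        for b in range(a + 1, ndim):
            da = edge(Vred[a], a, dxs[a])  # edges along a
            db = edge(Vred[b], b, dxs[b])  # edges along b
            # circ = da(.,j) + db(i+1,.) - da(.,j+1) - db(i,.)
            da_j0 = np.take(da, range(0, da.shape[b] - 1), axis=b)
            da_j1 = np.take(da, range(1, da.shape[b]), axis=b)
            db_i0 = np.take(db, range(0, db.shape[a] - 1), axis=a)
            db_i1 = np.take(db, range(1, db.shape[a]), axis=a)
            circ = da_j0 + db_i1 - da_j1 - db_i0
            worst = np.abs(circ).max() if circ.size else 0.0
            if worst > loop_tol:
                raise RepresentationError(
                    "flow is not potential: elementary loop circulation "
                    f"{worst:.3e} rad exceeds {loop_tol:.1e}"
                )

    def cumtrap(g, axis, dx):
        mid = edge(g, axis, dx)
        zeros = np.zeros_like(np.take(g, [0], axis=axis))
        return np.concatenate([zeros, np.cumsum(mid, axis=axis)], axis=axis)

    # spanning tree rooted at the origin: theta(i0, i1, ...) accumulates the
    # axis-0 integral on the (.,0,...,0) line, then the axis-1 integral on
    # the (i0,.,0,...) plane, and so on
    acc = np.zeros(grid.shape)
    for ax in range(ndim):
        contrib = cumtrap(Vred[ax], ax, dxs[ax])
        sl = [slice(None)] * ndim
        for later in range(ax + 1, ndim):
            sl[later] = slice(0, 1)
        acc = acc + np.broadcast_to(contrib[tuple(sl)], grid.shape)
    return acc


def hydro_to_wave(h: HydroField, loop_tol: float = 1e-6) -> WaveField:
    """Reconstruct ``psi = sqrt(P) exp(i theta)`` (up to one global phase).

    Admissible only for potential motion: every elementary grid-loop
    circulation of ``V / 2D`` must fall below ``loop_tol`` radians.
    """
    Vred = h.V / (2.0 * h.params.D)
    theta = _integrate_phase(Vred, h.grid, loop_tol)
    psi = np.sqrt(h.P) * np.exp(1j * theta)
    return WaveField(psi, h.grid, h.params, t=h.t).normalized()


def wave_to_diffusive(w: WaveField) -> DiffusiveField:
    """``v_plus = V + D grad(ln P)``; the backward field is the
    ``v_minus`` property of the returned object."""
    h = wave_to_hydro(w)
    glnP = _grad_log(h.P, w.grid)
    v_plus = h.V + w.params.D * glnP
    v_plus[..., ~h.mask] = 0.0
    return DiffusiveField(
        P=h.P, v_plus=v_plus, grid=w.grid, params=w.params, t=w.t, mask=h.mask
    )


def diffusive_to_wave(d: DiffusiveField, loop_tol: float = 1e-6) -> WaveField:
    """Reconstruct ``psi = P^{(1-i)/2} exp(i theta_plus)`` with
    ``v_plus = 2 D grad(theta_plus)``.

    Equivalent to ``sqrt(P) exp(i (theta_plus - ln P / 2))``, i.e. the usual
    modulus with phase ``theta = theta_plus - (1/2) ln P``.

    Numerically the integration uses the decomposition ``theta_plus = theta
    + ln sqrt(P)``: the singular ``ln sqrt P`` part is carried analytically
    and only the smooth velocity ``V = v_plus - D grad(ln P)`` is
    integrated, so nodes do not contaminate the phase.

    The pair (P, v_plus) cannot distinguish the sign of psi across a node
    (both P and v_plus are even around a simple zero); for essentially-real
    reconstructions in 1D the continuity of dpsi/dx forces the sign to
    alternate across each interior zero, and that convention is applied.
    """
    D = d.params.D
    V = d.v_plus - D * _grad_log(d.P, d.grid)
    V[..., ~d.mask] = 0.0
    theta = _integrate_phase(V / (2.0 * D), d.grid, loop_tol)
    psi = np.sqrt(d.P) * np.exp(1j * theta)
    if d.grid.ndim == 1:
        # essentially-real state: recover the nodal sign alternation at
        # interior zeros, detected as deep dips of the log-density
        mask = d.mask
        spread = np.angle(np.exp(1j * (theta[mask] - theta[mask][0])))
        if np.abs(spread).max() < 1e-3:
            from scipy.signal import find_peaks

            lnP = np.log(_floored(d.P))
            nodes, _ = find_peaks(-lnP, prominence=5.0)
            sign = np.ones(len(lnP))
            for s in nodes:
                sign[s + 1:] *= -1.0
            psi = psi * sign
    return WaveField(psi, d.grid, d.params, t=d.t).normalized()


def classical_to_hydro(
    P: np.ndarray, v: np.ndarray, grid: GridSpec, params: MacroParams
) -> HydroField:
    """Map a classical diffusive state to hydro variables: ``V = v - D grad ln P``."""
    P = np.asarray(P, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.shape != (grid.ndim,) + grid.shape:
        raise ConfigurationError("v must have one component per axis")
    V = v - params.D * _grad_log(P, grid)
    mask = _mask_of(P)
    V[..., ~mask] = 0.0
    return HydroField(P=P, V=V, grid=grid, params=params, mask=mask)


# ---------------------------------------------------------------------------
# evolutions


def _advect(V: np.ndarray, f: np.ndarray, grid: GridSpec) -> np.ndarray:
    """(V . grad) f for scalar f."""
    g = gradient(f, grid)
    return sum(V[i] * g[i] for i in range(grid.ndim))


def _div(F: np.ndarray, grid: GridSpec) -> np.ndarray:
    return sum(gradient(F[i], grid)[i] for i in range(grid.ndim))


def _lsq_derivatives(x: np.ndarray, f: np.ndarray, window: int):
    """First and second derivatives of scattered 1D samples.

    Local quadratic least squares over a sliding window of ``window``
    points; the projection doubles as a low-pass filter, which is what makes
    trajectory-based quantum hydrodynamics stable (sub-window noise cannot
    feed the tail-amplification of log-density dynamics).  Exact for
    globally quadratic profiles, one-sided windows at the ends.
    """
    n = len(x)
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n - window)
    J = lo[:, None] + np.arange(window)
    dx = x[J] - x[:, None]
    A = np.stack([np.ones_like(dx), dx, dx**2], axis=-1)  # (n, w, 3)
    At = A.transpose(0, 2, 1)
    coef = np.linalg.solve(At @ A, At @ f[J][..., None])[..., 0]
    return coef[:, 1], 2.0 * coef[:, 2]


def evolve_hydro(
    h: HydroField,
    pot: PotentialSpec,
    with_quantum: bool,
    dt: float,
    n_steps: int,
    depth_cap: float = 9.0,
    n_markers: int = 33,
    window: int = 7,
    quantum_sign: float = 1.0,
) -> HydroField:
    """Integrate continuity + Euler, optionally with the quantum potential.

    Lagrangian quantum-trajectory integration (1D): fluid markers carry
    ``(x, V, ln P)`` through

        dx/dt = V,   dV/dt = -(1/m) d(phi + Q)/dx,   d(ln P)/dt = -dV/dx,

    with ``Q = -m D^2 (a'' + a'^2/2)`` from the log-density ``a = ln P``
    (omitted when ``with_quantum`` is off, giving classical pressureless
    flow).  Spatial derivatives come from sliding local quadratic least
    squares, which is exact for Gaussian states and filters sub-window
    noise; markers span the region within ``depth_cap`` e-folds of the
    density maximum — outside it the continuum potential-flow description
    carries no probability and is not integrated.  Marker crossing (a
    caustic, where potential flow fails) terminates with a diagnostic.
    The result is interpolated back onto the original grid.

    ``quantum_sign=-1`` reverses the sign of Q (the "diffusion potential"),
    turning the self-organizing flow into the hydrodynamic picture of
    ordinary diffusion.
    """
    grid, params = h.grid, h.params
    if grid.ndim != 1:
        raise NotImplementedError("hydrodynamic evolution is implemented in 1D")
    m, D = params.m, params.D
    x = grid.axes()[0]
    phi = pot.on_grid(grid)
    dphi = np.gradient(phi, x)

    from scipy.interpolate import CubicSpline

    lnP = np.log(np.maximum(h.P, 1e-300))
    active = lnP >= lnP.max() - depth_cap
    xa = x[active]
    xm = np.linspace(xa.min(), xa.max(), n_markers)
    a = CubicSpline(x, lnP)(xm)
    V = CubicSpline(x, h.V[0])(xm)

    def rhs(xm, V, a):
        if np.any(np.diff(xm) <= 0):
            raise NumericalBlowupError(-1, "marker crossing (caustic)")
        a1, a2 = _lsq_derivatives(xm, a, window)
        if with_quantum:
            Q = -quantum_sign * m * D**2 * (a2 + 0.5 * a1**2)
            Q1, _ = _lsq_derivatives(xm, Q, window)
        else:
            Q1 = 0.0
        V1, _ = _lsq_derivatives(xm, V, window)
        force = -(np.interp(xm, x, dphi) + Q1) / m
        return V, force, -V1

    for step in range(n_steps):
        try:
            k1 = rhs(xm, V, a)
            k2 = rhs(xm + 0.5 * dt * k1[0], V + 0.5 * dt * k1[1], a + 0.5 * dt * k1[2])
            k3 = rhs(xm + 0.5 * dt * k2[0], V + 0.5 * dt * k2[1], a + 0.5 * dt * k2[2])
            k4 = rhs(xm + dt * k3[0], V + dt * k3[1], a + dt * k3[2])
        except NumericalBlowupError as e:
            raise NumericalBlowupError(step, f"caustic at step {step}") from e
        xm = xm + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        V = V + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        a = a + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(V))):
            raise NumericalBlowupError(step)

    # back onto the grid; the region beyond the marker span carries no mass
    inside = (x >= xm[0]) & (x <= xm[-1])
    a_g = np.where(inside, CubicSpline(xm, a)(np.clip(x, xm[0], xm[-1])), a.min() - 60.0)
    P_out = np.where(inside, np.exp(a_g - a.max()), 0.0)
    V_out = np.where(inside, CubicSpline(xm, V)(np.clip(x, xm[0], xm[-1])), 0.0)[None]
    return HydroField(
        P=P_out, V=V_out, grid=grid, params=params, t=h.t + n_steps * dt
    )


def evolve_fokker_planck(
    d: DiffusiveField,
    dt: float,
    n_steps: int,
    sign: Literal["forward", "backward"] = "forward",
    positivity_tol: float = 1e-8,
) -> DiffusiveField:
    """Integrate the forward or backward Fokker-Planck equation.

    Forward: ``dP/dt + div(P v+) = D Lap P`` with the user-supplied forward
    velocity held fixed (standalone mode).  Backward: ``dP/dt + div(P v-)
    = -D Lap P`` with ``v-`` slaved to its defining relation
    ``v- = v+ - 2 D grad ln P`` evaluated on the current density (paired
    mode) — the backward equation cannot found a classical process on its
    own, so it is only ever integrated in this paired form.
    """
    grid, params = d.grid, d.params
    D = params.D

    def rhs(P):
        # the diffusion term is written as div(D grad P) with the same
        # divergence stencil as the drift flux, so the equilibrium identity
        # div(P v+) = D Lap P (v+ = D grad P / P) holds exactly on the grid
        diffusion = D * _div(np.stack(gradient(P, grid)), grid)
        if sign == "forward":
            v = d.v_plus
            diff = diffusion
        elif sign == "backward":
            v = d.v_plus - 2.0 * D * _grad_log(P, grid)
            diff = -diffusion
        else:
            raise ConfigurationError(f"unknown sign {sign!r}")
        return -_div(P[None] * v, grid) + diff

    P = d.P.copy()
    for step in range(n_steps):
        k1 = rhs(P)
        k2 = rhs(P + 0.5 * dt * k1)
        k3 = rhs(P + 0.5 * dt * k2)
        k4 = rhs(P + dt * k3)
        P = P + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if P.min() < -positivity_tol * P.max():
            raise DomainError(f"density went negative at step {step}")
        P = np.maximum(P, 0.0)
        if not np.all(np.isfinite(P)):
            raise NumericalBlowupError(step)
    return DiffusiveField(
        P=P, v_plus=d.v_plus, grid=grid, params=params, t=d.t + n_steps * dt
    )


def gibbs_entropy(P: np.ndarray, grid: GridSpec) -> float:
    """Gibbs entropy ``S = -int P ln P dV`` (floored below the density floor)."""
    P = np.asarray(P, dtype=float)
    Ps = _floored(P)
    return float(-(P * np.log(Ps)).sum() * grid.cell_volume)


# ---------------------------------------------------------------------------
# residual diagnostics


def _relative_norm(
    residual: np.ndarray,
    terms: list[np.ndarray],
    mask: np.ndarray,
    floor: float = 0.0,
) -> float:
    """L2 norm of the residual over the largest constituent term.

    ``floor`` guards the denominator for exact solutions whose individual
    terms all vanish (e.g. a free plane wave): there the natural scale is
    supplied by the caller (m v^2 / L), and the residual is reported
    relative to it instead of 0/0.
    """
    num = np.linalg.norm(residual[..., mask].ravel())
    den = max(np.linalg.norm(t[..., mask].ravel()) for t in terms)
    den = max(den, floor)
    if den == 0:
        return float(num)
    return float(num / den)


def two_fluid(
    w: WaveField,
    pot: PotentialSpec | None = None,
    dt: float = 1e-4,
    mask_floor: float = 1e-5,
) -> TwoFluidField:
    """Extract (V, U) and evaluate the coupled two-fluid equations' residuals.

    The equations checked (one per returned residual, as relative L2 norms
    over the reliable region) are

        (d/dt + V.grad) V = (U.grad + D Lap) U - grad(phi/m)
        (d/dt + V.grad) U = -(U.grad + D Lap) V

    with time derivatives obtained by midpoint differencing along the actual
    Schrodinger evolution under ``pot``.
    """
    w = w.normalized()
    pot = pot if pot is not None else PotentialSpec(0.0)
    grid, params = w.grid, w.params
    D, m = params.D, params.m
    phi = pot.on_grid(grid)

    def fields_of(state: WaveField):
        h = wave_to_hydro(state)
        U = D * _grad_log(h.P, grid)
        return h.V, U, h.P

    V, U, P = fields_of(w)
    w_p = evolve(w, pot, dt, 1)
    # midpoint in time: (t+dt) vs (t-dt); backward step via conjugation trick
    w_back = WaveField(np.conj(w.psi), grid, params, t=w.t)
    w_b = evolve(w_back, pot, dt, 1)
    V_p, U_p, _ = fields_of(w_p)
    V_b, U_b, _ = fields_of(
        WaveField(np.conj(w_b.psi), grid, params, t=w.t - dt)
    )
    dV_dt = (V_p - V_b) / (2.0 * dt)
    dU_dt = (U_p - U_b) / (2.0 * dt)

    mask = P > mask_floor * P.max()
    grad_phi_m = np.stack(gradient(phi / m, grid))

    resid_V = np.empty_like(V)
    resid_U = np.empty_like(U)
    termsV: list[np.ndarray] = []
    termsU: list[np.ndarray] = []
    for i in range(grid.ndim):
        advV = _advect(V, V[i], grid)
        srcV = _advect(U, U[i], grid) + D * apply_laplacian(U[i], grid)
        resid_V[i] = dV_dt[i] + advV - srcV + grad_phi_m[i]
        termsV += [dV_dt[i], advV, srcV, grad_phi_m[i]]
        advU = _advect(V, U[i], grid)
        srcU = _advect(U, V[i], grid) + D * apply_laplacian(V[i], grid)
        resid_U[i] = dU_dt[i] + advU + srcU
        termsU += [dU_dt[i], advU, srcU]

    v_rms = float(np.sqrt(np.mean((V**2 + U**2).sum(axis=0)[mask])))
    floor = np.sqrt(mask.sum()) * m * max(v_rms, D / max(grid.extent)) ** 2 / max(
        grid.extent
    )
    rV = _relative_norm(resid_V, termsV, mask, floor=floor)
    rU = _relative_norm(resid_U, termsU, mask, floor=floor)
    return TwoFluidField(
        V=V, U=U, grid=grid, params=params, mask=mask,
        residual_V=rV, residual_U=rU,
    )


def geodesic_residual(
    w: WaveField,
    pot: PotentialSpec | None = None,
    dt: float = 1e-4,
    mask_floor: float = 1e-5,
) -> float:
    """Relative L2 residual of the covariant geodesic equation.

    Evaluates ``m (d/dt + Vc.grad - i D Lap) Vc + grad phi`` with the complex
    velocity ``Vc = -2 i D grad(ln psi)``, by central finite differences in
    space and time along the Schrodinger evolution under ``pot``.  Vanishes
    for exact solutions; grows by orders of magnitude for corrupted states.
    """
    w = w.normalized()
    pot = pot if pot is not None else PotentialSpec(0.0)
    grid, params = w.grid, w.params
    D, m = params.D, params.m
    phi = pot.on_grid(grid)

    def vc_of(state: WaveField) -> np.ndarray:
        psi_safe = np.where(np.abs(state.psi) > 0, state.psi, 1.0)
        return np.stack(
            [-2j * D * g / psi_safe for g in gradient(state.psi, grid)]
        )

    Vc = vc_of(w)
    w_p = evolve(w, pot, dt, 1)
    w_back = WaveField(np.conj(w.psi), grid, params, t=w.t)
    w_b_raw = evolve(w_back, pot, dt, 1)
    w_b = WaveField(np.conj(w_b_raw.psi), grid, params, t=w.t - dt)
    dVc_dt = (vc_of(w_p) - vc_of(w_b)) / (2.0 * dt)

    P = w.density
    mask = P > mask_floor * P.max()
    grad_phi = np.stack(gradient(phi, grid))
    terms = []
    resid = np.empty_like(Vc)
    for i in range(grid.ndim):
        adv = sum(Vc[k] * gradient(Vc[i], grid)[k] for k in range(grid.ndim))
        lap = apply_laplacian(Vc[i], grid)
        resid[i] = m * (dVc_dt[i] + adv - 1j * D * lap) + grad_phi[i]
        terms += [m * dVc_dt[i], m * adv, m * D * lap, grad_phi[i]]
    num = np.linalg.norm(np.abs(resid)[..., mask].ravel())
    den = max(np.linalg.norm(np.abs(t)[mask].ravel()) for t in terms)
    v_rms = float(np.sqrt(np.mean(np.abs(Vc[..., mask]) ** 2)))
    den = max(
        den,
        np.sqrt(mask.sum()) * m * max(v_rms, D / max(grid.extent)) ** 2
        / max(grid.extent),
    )
    return float(num / den) if den > 0 else float(num)


# ---------------------------------------------------------------------------
# path-level picture


def make_fractal_paths(
    params: MacroParams,
    dt: float,
    n_steps: int,
    n_paths: int,
    seed: int | np.random.Generator = 0,
    drift: float | np.ndarray = 0.0,
    ndim: int = 1,
    allow_zero_D: bool = False,
) -> PathEnsemble:
    """Sample geodesic-ensemble paths ``dX = v dt + zeta sqrt(2 D) |dt|^(1/2)``.

    ``zeta`` is a unit-variance, zero-mean normal deviate: the critical
    fractal-dimension-2 regime in which the mean squared displacement grows
    as ``2 D t``.  With ``allow_zero_D`` and a MacroParams-like D of zero the
    paths are exactly straight (deterministic limit); otherwise D > 0.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D = params.D if not allow_zero_D else max(params.D, 0.0)
    zeta = rng.standard_normal((n_paths, n_steps, ndim))
    steps = np.asarray(drift, dtype=float) * dt + zeta * np.sqrt(2.0 * D * dt)
    pos = np.concatenate(
        [np.zeros((n_paths, 1, ndim)), np.cumsum(steps, axis=1)], axis=1
    )
    return PathEnsemble(positions=pos, dt=dt, params=params)
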
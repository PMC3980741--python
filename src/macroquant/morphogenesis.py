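"""Growth, duplication and hierarchy models built on the macroquantum engine.

Growth from a center under a central potential separates into radial and
angular parts; the stationary angular probability density is
``P(theta, phi) = |Y_lm(theta, phi)|^2``, whose maxima occur at quantized
angles.  Sending matter along those angles — with an azimuthal quantization
``k`` giving an integer number of 'petals' and a constant tension force
bending them — produces flower-like shapes.  Raising the energy of a
confined structure from the ground state to the first excited state jumps
the density from one peak to two with no stable intermediate: a minimal
model of duplication/cell division (and, kept side by side, of branching).
A Schrodinger equation acting in scale space (ln of scale as the position
variable, walls at the extreme scales) quantizes the number of embedded
hierarchy levels, the fundamental mode peaking at the geometric mean of the
extreme scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize_scalar
from scipy.special import sph_harm_y

from .core import (
    EigenSolution,
    GridSpec,
    MacroParams,
    PotentialSpec,
    WaveField,
    count_peaks,
    evolve,
    stationary_states,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "MorphologySpec",
    "ScaleHierarchySpec",
    "DuplicationResult",
    "angular_density",
    "maximal_angles",
    "flower_shape",
    "duplication_simulation",
    "hierarchy_modes",
    "mid_scale",
    "complementary_density",
]


@dataclass(frozen=True)
class MorphologySpec:
    """Angular quantum numbers and petal parameters of a growth solution.

    l, m_q : angular momentum and magnetic quantum numbers, |m_q| <= l.
    k : azimuthal petal quantization (k curves per maximal latitude band).
    tension : constant-magnitude bending force of the petal curves
        (arbitrary units; 0 gives straight rays).
    """

    l: int = 5
    m_q: int = 0
    k: int = 5
    tension: float = 0.0

    def __post_init__(self):
        if self.l < 0 or abs(self.m_q) > self.l:
            raise DomainError("need l >= 0 and |m_q| <= l")
        if self.k < 1:
            raise DomainError("petal quantization k must be >= 1")


@dataclass(frozen=True)
class ScaleHierarchySpec:
    """Extreme scales acting as walls of a box in ln(scale) space."""

    lam_min: float
    lam_max: float
    n_mode: int = 0

    def __post_init__(self):
        if self.lam_min <= 0 or self.lam_max <= 0:
            raise DomainError("scales must be strictly positive")
        if self.lam_min >= self.lam_max:
            raise DomainError("need lam_min < lam_max")
        if self.n_mode < 0:
            raise DomainError("n_mode must be >= 0")


def angular_density(spec: MorphologySpec, theta, phi):
    """Probability density on the sphere, ``P = |Y_lm|^2``.

    ``theta`` is the polar angle in [0, pi], ``phi`` azimuthal in [0, 2 pi);
    normalized so that the integral over the full solid angle is 1.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    Y = sph_harm_y(spec.l, spec.m_q, theta, phi)
    return np.abs(Y) ** 2


def maximal_angles(spec: MorphologySpec, n_grid: int = 2001) -> np.ndarray:
    """Polar angles of the local maxima of ``|Y_lm|^2(theta)``.

    Grid search refined by bounded scalar minimization; pole maxima are
    detected from one-sided behavior.  For m_q = 0 the count is l + 1
    (including both poles).
    """
    th = np.linspace(0.0, np.pi, n_grid)
    dens = angular_density(spec, th, 0.0)
    maxima: list[float] = []
    if dens[0] > dens[1]:
        maxima.append(0.0)
    for i in range(1, n_grid - 1):
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]:
            res = minimize_scalar(
                lambda t: -angular_density(spec, t, 0.0),
                bounds=(th[i - 1], th[i + 1]),
                method="bounded",
                options={"xatol": 1e-10},
            )
            maxima.append(float(res.x))
    if dens[-1] > dens[-2]:
        maxima.append(float(np.pi))
    return np.array(sorted(maxima))


def flower_shape(
    spec: MorphologySpec,
    n_points: int = 50,
    length: float = 1.0,
) -> dict[str, list[np.ndarray]]:
    """Ridge curves of a flower-like morphology.

    For each maximal latitude band of ``|Y_lm|^2``, ``k`` curves are
    launched from the origin at azimuths ``phi_j = 2 pi j / k`` along the
    maximal polar angle, then bent by a constant-magnitude acceleration
    transverse to the launch ray (in the meridian plane containing the
    axis), integrated to quadratic curves.  Curves from the polar bands are
    labelled 'stamen' (up) and 'sepals' (down); non-polar bands give
    'petals'.  Deterministic given the spec.

    Returns a dict mapping label -> list of (n_points, 3) arrays.
    """
    bands = maximal_angles(spec)
    s = np.linspace(0.0, length, n_points)
    out: dict[str, list[np.ndarray]] = {"petals": [], "sepals": [], "stamen": []}
    for theta0 in bands:
        polar = theta0 < 1e-9 or np.pi - theta0 < 1e-9
        phis = [0.0] if polar else [2.0 * np.pi * j / spec.k for j in range(spec.k)]
        for phi0 in phis:
            # launch direction and transverse (increasing-theta) direction
            e_r = np.array(
                [
                    np.sin(theta0) * np.cos(phi0),
                    np.sin(theta0) * np.sin(phi0),
                    np.cos(theta0),
                ]
            )
            e_t = np.array(
                [
                    np.cos(theta0) * np.cos(phi0),
                    np.cos(theta0) * np.sin(phi0),
                    -np.sin(theta0),
                ]
            )
            curve = np.outer(s, e_r) + 0.5 * spec.tension * np.outer(s**2, e_t)
            if theta0 < 1e-9:
                out["stamen"].append(curve)
            elif np.pi - theta0 < 1e-9:
                out["sepals"].append(curve)
            else:
                out["petals"].append(curve)
    return out


@dataclass
class DuplicationResult:
    """Frames of the one-structure -> two-structure transition."""

    s_values: np.ndarray
    densities: list[np.ndarray]
    peak_counts: list[int]
    stationary: list[bool]
    energies: tuple[float, float]
    grid: GridSpec


def duplication_simulation(
    pot: PotentialSpec,
    grid: GridSpec,
    params: MacroParams,
    n_frames: int = 5,
    drift_dt: float = 1e-3,
    drift_steps: int = 200,
    stationary_tol: float = 1e-6,
) -> DuplicationResult:
    """Render the jump from the ground state to the first excited state.

    The transition path is the normalized interpolation
    ``psi(s) ~ cos(pi s/2) psi_0 + sin(pi s/2) psi_1`` — illustrative, since
    only the endpoints are stationary; each frame's stationarity is probed
    by evolving it and measuring the density drift.  First frame has one
    probability peak, last frame two; intermediate frames are transitory.
    """
    sol = stationary_states(pot, grid, params, n_states=2)
    E0, E1 = float(sol.energies[0]), float(sol.energies[1])
    if abs(E1 - E0) < 1e-10 * max(abs(E0), abs(E1), 1.0):
        raise ConfigurationError("degenerate E0 = E1: non-generic potential")
    psi0, psi1 = sol.states[0].psi, sol.states[1].psi
    s_values = np.linspace(0.0, 1.0, n_frames)
    densities, counts, stationary = [], [], []
    for s in s_values:
        psi = np.cos(np.pi * s / 2.0) * psi0 + np.sin(np.pi * s / 2.0) * psi1
        w = WaveField(psi, grid, params).normalized()
        P0 = w.density
        densities.append(P0)
        counts.append(count_peaks(P0))
        w_t = evolve(w, pot, drift_dt, drift_steps)
        drift = np.abs(w_t.density - P0).max() / P0.max()
        stationary.append(bool(drift < stationary_tol))
    return DuplicationResult(
        s_values=s_values,
        densities=densities,
        peak_counts=counts,
        stationary=stationary,
        energies=(E0, E1),
        grid=grid,
    )


def hierarchy_modes(spec: ScaleHierarchySpec, n_grid: int = 1024):
    """Box eigenmode in ln(scale): density and its peak scales.

    Mode ``n`` over ``x = ln(scale)`` between the walls ``ln lam_min`` and
    ``ln lam_max`` has density ``~ sin^2((n+1) pi (x - x_min)/(x_max -
    x_min))`` with ``n + 1`` antinodes: ``n + 1`` embedded hierarchy levels.
    Returns ``(scales, density, peak_scales)``; the fundamental peaks at the
    geometric mean ``sqrt(lam_min lam_max)``.
    """
    x_min, x_max = np.log(spec.lam_min), np.log(spec.lam_max)
    x = np.linspace(x_min, x_max, n_grid)
    n = spec.n_mode
    dens = np.sin((n + 1) * np.pi * (x - x_min) / (x_max - x_min)) ** 2
    dens /= np.trapezoid(dens, x)
    k = np.arange(n + 1)
    x_peaks = x_min + (k + 0.5) * (x_max - x_min) / (n + 1)
    return np.exp(x), dens, np.exp(x_peaks)


def mid_scale(lam_min: float, lam_max: float) -> float:
    """Geometric-mean scale ``sqrt(lam_min * lam_max)`` of a scale interval."""
    if lam_min <= 0 or lam_max <= 0:
        raise DomainError("scales must be strictly positive")
    return float(np.sqrt(lam_min * lam_max))


def complementary_density(
    P: np.ndarray,
    grid: GridSpec,
    threshold: float = 0.1,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Normalized density concentrated on the low-probability 'walls' of P.

    The complement is supported where ``P < threshold * max(P)`` (weight
    ``threshold*max - P`` there, zero elsewhere), lightly smoothed; the two
    densities' high-probability supports are disjoint at the threshold.
    Models the second of two strongly coupled fluids, one peaking in the
    'cells' and the other in the 'walls' between them.
    """
    if not (0.0 < threshold < 1.0):
        raise DomainError("threshold must lie in (0, 1)")
    P = np.asarray(P, dtype=float)
    cut = threshold * P.max()
    walls = np.maximum(cut - P, 0.0)
    if grid.boundary == "box":
        # confined states also vanish at the exterior box walls; those are
        # not inter-cell walls, so drop support components touching the edge
        from scipy.ndimage import label

        lab, n_lab = label(walls > 0)
        border = np.ones(P.shape, dtype=bool)
        border[(slice(1, -1),) * P.ndim] = False
        for comp in np.unique(lab[border]):
            if comp > 0:
                walls[lab == comp] = 0.0
    if walls.max() <= 0:
        raise DomainError("density has no region below threshold (no walls)")
    if smooth_sigma > 0:
        walls = gaussian_filter(walls, smooth_sigma, mode="constant")
    tot = walls.sum() * grid.cell_volume
    return walls / tot
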
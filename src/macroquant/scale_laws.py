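"""Solutions of the scale differential equations and log-periodic fitting.

In scale relativity the length of a fractal coordinate becomes an explicit
function ``L(eps)`` of the resolution ``eps`` at which it is measured.  The
simplest first-order law in the logarithm of resolution,

    dL/d(ln eps) = a + b L,

has the solution ``L(eps) = L0 (1 + (lam/eps)**tau_F)`` combining a
scale-independent part ``L0`` and a self-similar fractal part with "djinn"
``tau_F = D_F - 1`` (variable fractal dimension minus topological dimension).
Second-order laws in scale space add log-periodic oscillations, a constant
"scale acceleration", a scale harmonic oscillator with an impassable wall
scale ``lam1``, and a Lorentz-like law with an invariant limiting scale
``lamH``.  All operations here act on strictly positive resolutions and are
naturally expressed on logarithmic grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    ConfigurationError,
    DegenerateParameterError,
    DomainError,
    FitError,
    ForbiddenScaleError,
    LimitingScaleError,
)

__all__ = [
    "ScaleLawParams",
    "fractal_length",
    "fractal_part_ratio",
    "log_periodic_length",
    "scale_dynamics_length",
    "scale_oscillator_length",
    "wall_dimension_profile",
    "special_relativity_djinn",
    "fit_log_periodic",
    "LogPeriodicFit",
]


@dataclass
class ScaleLawParams:
    """Parameters of the scale-space laws.

    Attributes
    ----------
    L0 : reference (scale-independent) length.
    lam : fractal/classical transition scale, > 0.
    tau_F : djinn tau_F = D_F - 1, dimensionless >= 0.
    a_coef, b_coef : coefficients of the first-order scale ODE
        dL/dln(eps) = a + b L; consistency requires a = tau_F * L0 and
        b = -tau_F, and both are derived from (L0, tau_F) when omitted.
    G : "scale acceleration" coefficient of the second-order linear law.
    lam0 : reference scale of the dynamical laws.
    lam1 : wall scale of the scale harmonic oscillator (impassable).
    tau0 : asymptotic djinn of the oscillator / Lorentzian laws.
    lamH : invariant limiting scale of the special scale-relativity law.
    nu, a_lp, b_lp, omega : power index, amplitude, log-periodic amplitude
        and log-periodic frequency of L = a * eps**nu * (1 + b cos(omega ln eps)).
    """

    L0: float = 1.0
    lam: float = 1.0
    tau_F: float = 0.5
    a_coef: float | None = None
    b_coef: float | None = None
    G: float = 1.0
    lam0: float = 1.0
    lam1: float = 0.1
    tau0: float = 1.0
    lamH: float = 1e-3
    nu: float = 0.0
    a_lp: float = 1.0
    b_lp: float = 0.0
    omega: float = 2.0 * np.pi

    def __post_init__(self) -> None:
        for name in ("lam", "lam0", "lam1", "lamH"):
            if getattr(self, name) <= 0:
                raise DomainError(f"scale field {name!r} must be strictly positive")
        if self.L0 <= 0:
            raise DomainError("L0 must be strictly positive")
        if self.tau_F < 0:
            raise DomainError("tau_F must be >= 0")
        # first-order ODE constants: a = tau_F*L0, b = -tau_F
        if self.b_coef is None:
            self.b_coef = -self.tau_F
        elif not np.isclose(self.tau_F, -self.b_coef):
            raise ConfigurationError(
                f"tau_F = {self.tau_F} inconsistent with b_coef = {self.b_coef} "
                "(requires tau_F = -b)"
            )
        if self.a_coef is None:
            self.a_coef = self.tau_F * self.L0


def _positive(eps, name: str = "eps"):
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0) or not np.all(np.isfinite(eps)):
        raise DomainError(f"{name} must be strictly positive and finite")
    return eps


def fractal_length(eps, params: ScaleLawParams):
    """Length at resolution ``eps``: ``L0 * (1 + (lam/eps)**tau_F)``.

    Monotonically non-increasing in ``eps``; tends to the scale-independent
    ``L0`` above the transition scale and to the pure power law below it.
    """
    eps = _positive(eps)
    return params.L0 * (1.0 + (params.lam / eps) ** params.tau_F)


def fractal_part_ratio(eps1, eps2, params: ScaleLawParams):
    """Ratio of the fractal parts of L at two resolutions.

    Depends only on ``eps2/eps1`` (relativity of scales): equals
    ``(eps2/eps1)**tau_F``.
    """
    eps1 = _positive(eps1, "eps1")
    eps2 = _positive(eps2, "eps2")
    return (eps2 / eps1) ** params.tau_F


def log_periodic_length(eps, params: ScaleLawParams):
    """Second-order scale-wave solution ``a * eps**nu * (1 + b cos(omega ln eps))``."""
    eps = _positive(eps)
    return params.a_lp * eps**params.nu * (
        1.0 + params.b_lp * np.cos(params.omega * np.log(eps))
    )


def scale_dynamics_length(eps, params: ScaleLawParams):
    """Constant "scale acceleration" law.

    Returns ``(tau_F(eps), ln(L/L0))`` with
    ``tau_F = (1/G) ln(lam0/eps)`` and ``ln(L/L0) = (1/2G) ln^2(lam0/eps)``:
    the fractal dimension varies linearly with the logarithm of resolution.
    """
    eps = _positive(eps)
    if params.G == 0:
        raise DegenerateParameterError("G = 0 degenerates the scale-dynamics law")
    u = np.log(params.lam0 / eps)
    return u / params.G, u**2 / (2.0 * params.G)


def scale_oscillator_length(eps, params: ScaleLawParams):
    """Repulsive scale-harmonic-oscillator law (interior branch ``eps < lam1``).

    ``ln(L/L0) = tau0 * sqrt(ln^2(lam0/eps) - ln^2(lam0/lam1))``.

    The band where the square root argument is negative is physically
    forbidden: resolutions larger than the wall scale ``lam1`` (up to its
    mirror) are not reachable, so a :class:`ForbiddenScaleError` is raised
    rather than a complex value returned.  For ``eps << lam0`` the law tends
    to the standard scale-invariant case ``tau0 * ln(lam0/eps)``.
    """
    eps = _positive(eps)
    u2 = np.log(params.lam0 / eps) ** 2
    u1_2 = np.log(params.lam0 / params.lam1) ** 2
    arg = u2 - u1_2
    if np.any(arg < -1e-15 * max(u1_2, 1.0)):
        raise ForbiddenScaleError(
            "resolution inside the forbidden band around the wall scale lam1"
        )
    return params.tau0 * np.sqrt(np.maximum(arg, 0.0))


def special_relativity_djinn(eps, params: ScaleLawParams):
    """Lorentz-like scale law with invariant limiting scale ``lamH``.

    Returns ``(tau_F(eps), ln(L/L0))`` with

        tau_F = tau0 / sqrt(1 - ln^2(lam0/eps)/ln^2(lam0/lamH))
        ln(L/L0) = tau0 * ln(lam0/eps) / sqrt(1 - ...)

    ``lamH`` is impassable: the djinn diverges as ``eps -> lamH``.
    """
    eps = _positive(eps)
    u = np.log(params.lam0 / eps)
    uH2 = np.log(params.lam0 / params.lamH) ** 2
    ratio = u**2 / uH2
    if np.any(ratio >= 1.0):
        raise LimitingScaleError("resolution at or beyond the limiting scale lamH")
    gamma = 1.0 / np.sqrt(1.0 - ratio)
    return params.tau0 * gamma, params.tau0 * u * gamma


def wall_dimension_profile(
    r,
    params_inner: ScaleLawParams,
    params_outer: ScaleLawParams,
    r_plateau: float | None = None,
):
    """Effective fractal dimension versus distance-like scale ``r`` (cell-wall model).

    Three regions: a constant inner dimension ``1 + tau0`` for
    ``r <= r_plateau``, a diverging dimension ``1 + d lnL / d ln(lam0/r)`` of
    the repulsive scale oscillator on ``(r_plateau, lam1)`` — the "membrane",
    where the effective thickness blows up — and a constant outer dimension
    ``1 + tau_F`` of ``params_outer`` for ``r >= lam1``.
    """
    r = _positive(r, "r")
    lam1 = params_inner.lam1
    if r_plateau is None:
        r_plateau = lam1 / 20.0
    if not (0 < r_plateau < lam1):
        raise ConfigurationError(
            "inner plateau must end strictly inside the wall scale lam1"
        )
    if params_outer.lam < lam1 * (1 - 1e-12):
        raise ConfigurationError(
            "outer region (starting at params_outer.lam) overlaps the inner domain"
        )
    d_inner = 1.0 + params_inner.tau0
    d_outer = 1.0 + params_outer.tau_F
    r = np.atleast_1d(r)
    out = np.empty_like(r)
    inner = r <= r_plateau
    outer = r >= lam1
    mid = ~inner & ~outer
    out[inner] = d_inner
    out[outer] = d_outer
    if np.any(mid):
        # slope of the oscillator branch: tau0 * u / sqrt(u^2 - u1^2)
        u = np.log(params_inner.lam0 / r[mid])
        u1 = np.log(params_inner.lam0 / lam1)
        out[mid] = 1.0 + params_inner.tau0 * u / np.sqrt(u**2 - u1**2)
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# log-periodic fitting


@dataclass
class LogPeriodicFit:
    """Result of a log-periodic least-squares fit."""

    params: ScaleLawParams
    phase: float
    residual_norm: float
    sse_power_law: float
    omega_grid: np.ndarray = field(repr=False)
    sse_grid: np.ndarray = field(repr=False)
    p_value: float | None = None


def _profile_linear(x: np.ndarray, y: np.ndarray, omega: float):
    """Least squares of y ~ c0 + nu*x + bc*cos(omega x) + bs*sin(omega x)."""
    A = np.column_stack(
        [np.ones_like(x), x, np.cos(omega * x), np.sin(omega * x)]
    )
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def fit_log_periodic(
    series,
    omega_grid: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    n_permutations: int = 200,
) -> LogPeriodicFit:
    """Fit ``L = a eps**nu (1 + b cos(omega ln eps + phase))`` to samples.

    Log-periodic fits are notoriously multimodal in ``omega``, so the search
    proceeds in two stages: on a grid of candidate ``omega`` the remaining
    parameters are profiled linearly in the ``(ln a, nu, b cos, b sin)``
    parametrization of ``ln L`` (exact for small ``b``), then the best grid
    point seeds a full nonlinear refinement of the exact model.  Significance
    of the ``omega`` peak is assessed by permuting the residuals of the pure
    power-law fit ``n_permutations`` times and re-running the grid profile.

    Parameters
    ----------
    series : (n, 2) array-like of (eps, value) pairs, eps > 0, value > 0.
    omega_grid : candidate frequencies; default ``linspace(1, 15, 200)``.
    seed : int seed or Generator for the permutation test.
    n_permutations : shuffles for the significance score; 0 disables it.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("series must be an (n, 2) array of (eps, value) pairs")
    eps, val = arr[:, 0], arr[:, 1]
    if arr.shape[0] < 8:
        raise FitError("need at least 8 samples")
    if np.any(eps <= 0) or np.any(val <= 0):
        raise FitError("eps and values must be strictly positive")
    if eps.max() / eps.min() < 10.0:
        raise FitError("samples must span at least one decade in eps")
    if np.ptp(val) == 0:
        raise FitError("constant series cannot constrain the model")

    x = np.log(eps)
    y = np.log(val)
    order = np.argsort(x)
    x, y = x[order], y[order]

    if omega_grid is None:
        omega_grid = np.linspace(1.0, 15.0, 200)
    omega_grid = np.asarray(omega_grid, dtype=float)

    sse = np.array([_profile_linear(x, y, w)[1] for w in omega_grid])
    i_best = int(np.argmin(sse))
    w0 = omega_grid[i_best]
    coef0, _ = _profile_linear(x, y, w0)

    def model_resid(p):
        c0, nu, bc, bs, w = p
        osc = 1.0 + bc * np.cos(w * x) + bs * np.sin(w * x)
        if np.any(osc <= 0):
            return np.full_like(x, 1e6)
        return c0 + nu * x + np.log(osc) - y

    sol = least_squares(
        model_resid,
        np.array([coef0[0], coef0[1], coef0[2], coef0[3], w0]),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
    )
    c0, nu, bc, bs, w_fit = sol.x
    b = float(np.hypot(bc, bs))
    phase = float(np.arctan2(-bs, bc))
    residual_norm = float(np.linalg.norm(sol.fun))

    # power-law-only baseline for the permutation null
    A0 = np.column_stack([np.ones_like(x), x])
    coef_pl, *_ = np.linalg.lstsq(A0, y, rcond=None)
    resid_pl = y - A0 @ coef_pl
    sse_pl = float(resid_pl @ resid_pl)

    p_value = None
    if n_permutations > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        obs_gain = (sse_pl - sse.min()) / sse_pl if sse_pl > 0 else 0.0
        count = 0
        trend = A0 @ coef_pl
        for _ in range(n_permutations):
            y_perm = trend + rng.permutation(resid_pl)
            sse_perm = min(
                _profile_linear(x, y_perm, w)[1] for w in omega_grid
            )
            gain = (sse_pl - sse_perm) / sse_pl if sse_pl > 0 else 0.0
            if gain >= obs_gain:
                count += 1
        p_value = (count + 1) / (n_permutations + 1)

    fitted = ScaleLawParams(
        nu=float(nu), a_lp=float(np.exp(c0)), b_lp=b, omega=float(abs(w_fit))
    )
    return LogPeriodicFit(
        params=fitted,
        phase=phase,
        residual_norm=residual_norm,
        sse_power_law=sse_pl,
        omega_grid=omega_grid,
        sse_grid=sse,
        p_value=p_value,
    )
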
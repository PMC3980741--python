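"""Seeded synthetic-fixture generators.

Every module of the package is testable with no external data: densities,
potentials, velocity fields and event series are produced here from a
:class:`FixtureSpec` and a seed, deterministically.  A single global seed
can be threaded to all stochastic components; per-component substreams are
derived with :func:`substream`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

from .core import GridSpec
from .errors import ConfigurationError
from .scale_laws import ScaleLawParams, log_periodic_length

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "gaussian_density",
    "smooth_random_potential",
    "logperiodic_series",
    "vortex_velocity",
    "gaussian_dip_density",
    "substream",
]

FixtureKind = Literal[
    "gaussian_density",
    "smooth_random_potential",
    "logperiodic_series",
    "vortex_velocity",
    "gaussian_dip_density",
]


def substream(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-component substream of a global seed (below 2^31)."""
    ss = np.random.SeedSequence([int(seed) % (2**31), int(index)])
    return np.random.default_rng(ss)


@dataclass
class FixtureSpec:
    """Declarative recipe for a synthetic field or series."""

    kind: FixtureKind
    seed: int = 0
    params: dict = dc_field(default_factory=dict)


def gaussian_density(
    grid: GridSpec, sigma: float = 1.0, center=None
) -> np.ndarray:
    """Normalized isotropic Gaussian density on the grid."""
    coords = grid.meshgrid()
    if center is None:
        center = [0.5 * a for a in grid.extent]
    r2 = sum((x - c) ** 2 for x, c in zip(coords, np.atleast_1d(center)))
    P = np.exp(-r2 / (2.0 * sigma**2))
    return P / (P.sum() * grid.cell_volume)


def smooth_random_potential(
    grid: GridSpec,
    rng: np.random.Generator,
    amplitude: float = 1.0,
    correlation_length: float | None = None,
) -> np.ndarray:
    """Smooth random scalar field (low-pass filtered white noise)."""
    from scipy.ndimage import gaussian_filter

    if correlation_length is None:
        correlation_length = 0.1 * min(grid.extent)
    sig = [correlation_length / dx for dx in grid.spacing]
    noise = rng.standard_normal(grid.shape)
    smooth = gaussian_filter(noise, sig, mode="wrap" if grid.boundary == "periodic" else "nearest")
    rng_span = smooth.max() - smooth.min()
    if rng_span == 0:
        return np.zeros(grid.shape)
    return amplitude * (smooth - smooth.mean()) / smooth.std()


def logperiodic_series(
    nu: float = 0.5,
    b: float = 0.3,
    omega: float = 6.0,
    a: float = 1.0,
    noise: float = 0.01,
    n: int = 50,
    eps_min: float = 0.01,
    eps_max: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """(eps, value) samples of the log-periodic law with multiplicative noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = np.logspace(np.log10(eps_min), np.log10(eps_max), n)
    p = ScaleLawParams(nu=nu, b_lp=b, omega=omega, a_lp=a)
    val = log_periodic_length(eps, p)
    if noise > 0:
        val = val * np.exp(noise * rng.standard_normal(n))
    return np.column_stack([eps, val])


def vortex_velocity(grid: GridSpec, circulation: float = 1.0) -> np.ndarray:
    """Rotational (non-potential) velocity field around the grid center.

    Solid-body rotation: nonzero curl everywhere by construction, so the
    wave-function reconstruction must reject it.
    """
    if grid.ndim < 2:
        raise ConfigurationError("a vortex needs at least 2 dimensions")
    coords = grid.meshgrid()
    cx = [0.5 * a for a in grid.extent]
    x = coords[0] - cx[0]
    y = coords[1] - cx[1]
    V = np.zeros((grid.ndim,) + grid.shape)
    V[0] = -circulation * y
    V[1] = circulation * x
    return V


def gaussian_dip_density(
    grid: GridSpec,
    depth: float = 0.8,
    width: float | None = None,
    base: float = 1.0,
    center=None,
) -> np.ndarray:
    """Uniform density with a Gaussian dip (a dopant-site model)."""
    if not (0.0 < depth < 1.0):
        raise ConfigurationError("depth must lie in (0, 1)")
    coords = grid.meshgrid()
    if center is None:
        center = [0.5 * a for a in grid.extent]
    if width is None:
        width = 0.1 * min(grid.extent)
    r2 = sum((x - c) ** 2 for x, c in zip(coords, np.atleast_1d(center)))
    return base * (1.0 - depth * np.exp(-r2 / (2.0 * width**2)))


def generate_fixture(spec: FixtureSpec, grid: GridSpec | None = None):
    """Dispatch a :class:`FixtureSpec` to its generator (seeded, deterministic)."""
    rng = np.random.default_rng(spec.seed)
    kind = spec.kind
    if kind == "gaussian_density":
        if grid is None:
            raise ConfigurationError("gaussian_density needs a grid")
        return gaussian_density(grid, **spec.params)
    if kind == "smooth_random_potential":
        if grid is None:
            raise ConfigurationError("smooth_random_potential needs a grid")
        return smooth_random_potential(grid, rng, **spec.params)
    if kind == "logperiodic_series":
        return logperiodic_series(seed=rng, **spec.params)
    if kind == "vortex_velocity":
        if grid is None:
            raise ConfigurationError("vortex_velocity needs a grid")
        return vortex_velocity(grid, **spec.params)
    if kind == "gaussian_dip_density":
        if grid is None:
            raise ConfigurationError("gaussian_dip_density needs a grid")
        return gaussian_dip_density(grid, **spec.params)
    raise ConfigurationError(f"unknown fixture kind {kind!r}")
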
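"""Field containers: HDF5 round-trip and flat CSV export.

The hierarchical container stores ``psi_re``, ``psi_im`` and optionally
``phi`` as datasets, with ``D``, ``m``, ``t`` and the grid description as
attributes.  The CSV export is flat text at full double precision (17
significant digits) for 1D/2D fields: ``x[,y], re, im``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import GridSpec, MacroParams, WaveField
from .errors import FormatError

__all__ = ["write_field", "read_field", "write_field_csv", "read_field_csv"]

_REQUIRED_ATTRS = ("D", "m", "t", "extent", "points", "boundary")


def write_field(path: str | Path, w: WaveField, phi: np.ndarray | None = None) -> None:
    """Write a wave field (and optionally its potential) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("psi_re", data=w.psi.real)
        f.create_dataset("psi_im", data=w.psi.imag)
        if phi is not None:
            f.create_dataset("phi", data=np.asarray(phi, dtype=float))
        f.attrs["D"] = w.params.D
        f.attrs["m"] = w.params.m
        f.attrs["t"] = w.t
        f.attrs["extent"] = w.grid.extent
        f.attrs["points"] = w.grid.points
        f.attrs["boundary"] = w.grid.boundary


def read_field(path: str | Path) -> tuple[WaveField, np.ndarray | None]:
    """Read a wave field container; returns (field, phi-or-None)."""
    with h5py.File(path, "r") as f:
        for name in ("psi_re", "psi_im"):
            if name not in f:
                raise FormatError(f"missing dataset {name!r}")
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"missing attribute {attr!r}")
        psi = f["psi_re"][...] + 1j * f["psi_im"][...]
        grid = GridSpec(
            extent=tuple(float(a) for a in f.attrs["extent"]),
            points=tuple(int(n) for n in f.attrs["points"]),
            boundary=str(f.attrs["boundary"]),
        )
        params = MacroParams(D=float(f.attrs["D"]), m=float(f.attrs["m"]))
        phi = f["phi"][...] if "phi" in f else None
        return WaveField(psi, grid, params, t=float(f.attrs["t"])), phi


def write_field_csv(path: str | Path, w: WaveField) -> None:
    """Flat text export ``x[,y], re, im`` at full double precision (1D/2D)."""
    if w.grid.ndim > 2:
        raise FormatError("CSV export supports 1D and 2D fields only")
    coords = w.grid.meshgrid()
    cols = {("x", "y")[i]: c.ravel() for i, c in enumerate(coords)}
    cols["re"] = w.psi.real.ravel()
    cols["im"] = w.psi.imag.ravel()
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_field_csv(
    path: str | Path, grid: GridSpec, params: MacroParams, t: float = 0.0
) -> WaveField:
    """Re-import a CSV export given the grid/params it was written from."""
    df = pd.read_csv(path)
    for col in ("re", "im"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r}")
    psi = (df["re"].to_numpy() + 1j * df["im"].to_numpy()).reshape(grid.shape)
    return WaveField(psi, grid, params, t=t)
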
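"""Structured-grid field container and plain-text exports.

A :class:`FieldMap` couples a node-centred array to the labelled grid it was
computed on (axisymmetric r-z or 3D Cartesian).  Exports are deliberately
plain: legacy-ASCII VTK structured points for volume fields and CSV for
profiles, so results open in ParaView / pandas without binary dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy.interpolate import RegularGridInterpolator

if TYPE_CHECKING:  # pragma: no cover
    from .scenario import Grid

__all__ = ["FieldMap", "write_vtk"]


@dataclass
class FieldMap:
    """Scalar or vector field sampled on a structured grid.

    ``values`` has the grid's node shape, with a trailing component axis for
    vector fields.
    """

    values: np.ndarray
    grid: "Grid"
    name: str = "field"
    units: str = ""

    def __post_init__(self) -> None:
        expected = self.grid.shape
        if self.values.shape not in (expected, expected + (2,), expected + (3,)):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {expected}"
            )

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == len(self.grid.shape) + 1

    def magnitude(self) -> "FieldMap":
        if not self.is_vector:
            return self
        return FieldMap(np.linalg.norm(self.values, axis=-1), self.grid,
                        f"|{self.name}|", self.units)

    def interpolator(self, fill_value: float | None = None):
        """Linear interpolator over the grid axes.

        Axisymmetric grids interpolate in (r, z); 3D grids in (x, y, z).
        Points outside the domain evaluate to the boundary value unless
        ``fill_value`` is given.
        """
        vals = self.magnitude().values if self.is_vector else self.values
        return RegularGridInterpolator(
            self.grid.axes, vals, bounds_error=False,
            fill_value=fill_value, method="linear",
        )

    def max_in_region(self, region: str) -> float:
        mask = self.grid.labels == self.grid.regions[region]
        vals = self.magnitude().values if self.is_vector else self.values
        return float(vals[mask].max())

    def copy_with(self, values: np.ndarray, name: str | None = None,
                  units: str | None = None) -> "FieldMap":
        return FieldMap(values, self.grid, name or self.name,
                        self.units if units is None else units)


def write_vtk(path: str | Path, grid: "Grid", fields: dict[str, np.ndarray]) -> None:
    """Write node-centred scalar fields as a legacy-ASCII VTK structured-points
    file (axisymmetric grids are written as an r-z plane of unit thickness)."""
    path = Path(path)
    axes = grid.axes
    if len(axes) == 2:
        dims = (len(axes[0]), len(axes[1]), 1)
        origin = (axes[0][0], axes[1][0], 0.0)
    else:
        dims = tuple(len(a) for a in axes)
        origin = tuple(a[0] for a in axes)
    h = grid.spacing
    npts = dims[0] * dims[1] * dims[2]
    lines = [
        "# vtk DataFile Version 3.0",
        "menptherm field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        f"ORIGIN {origin[0]:.9e} {origin[1]:.9e} {origin[2]:.9e}",
        f"SPACING {h:.9e} {h:.9e} {h:.9e}",
        f"POINT_DATA {npts}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape != grid.shape:
            raise ValueError(f"field {name!r} shape mismatch")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest: transpose so the first axis varies fastest
        flat = arr.transpose(*reversed(range(arr.ndim))).ravel()
        lines.extend(" ".join(f"{v:.9e}" for v in flat[i:i + 6])
                     for i in range(0, len(flat), 6))
    path.write_text("\n".join(lines) + "\n")
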
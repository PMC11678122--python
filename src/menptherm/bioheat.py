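"""Heat conduction with the Joule source: steady state and transient.

The temperature obeys rho cp dT/dt - div(k grad T) = q with the Joule power
density q from the conduction solve, uniform initial temperature 37 degC and
37 degC held at the far boundary (the model carries no perfusion or
metabolic terms).  Because the conduction chain is linear, the solvers work
on the rise u = T - T_body with homogeneous boundary data and add the body
temperature back.

At nanoparticle scales the thermal diffusion time a^2 rho cp / k is of
order 0.1 us, nine orders below the minutes-long stimulation, so the steady
field is the relevant one for damage integration; the transient solver
(implicit Euler - the explicit stability limit at nanometre grids is
~1e-11 s) exists to verify that equilibration and to support time-varying
sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fd import SolveInfo, far_boundary_flux, solve_diffusion
from .electrostatics import PowerDensityField
from .fields import FieldMap
from .materials import MaterialsRegistry, default_registry
from .scenario import Grid, Scenario

__all__ = [
    "TemperatureField",
    "TemperatureSeries",
    "solve_steady_temperature",
    "solve_transient_temperature",
    "temperature_profile",
    "thermal_conductivity_map",
    "steady_boundary_flux",
]


@dataclass
class TemperatureField:
    """Temperature in kelvin on the grid (steady unless ``time`` is set)."""

    T: FieldMap
    steady: bool = True
    time: float | None = None
    info: SolveInfo | None = None

    @property
    def grid(self) -> Grid:
        return self.T.grid

    def celsius(self) -> np.ndarray:
        return self.T.values - 273.15

    def peak_celsius(self, region: str | None = None) -> float:
        if region is None:
            return float(self.T.values.max()) - 273.15
        return self.T.max_in_region(region) - 273.15


@dataclass
class TemperatureSeries:
    """Transient snapshots, including the initial uniform state at t = 0."""

    times: np.ndarray
    fields: list[FieldMap]
    grid: Grid

    def peak_trace(self) -> np.ndarray:
        return np.array([f.values.max() for f in self.fields])

    def final(self) -> TemperatureField:
        return TemperatureField(self.fields[-1], steady=False,
                                time=float(self.times[-1]))

    def equilibration_time(self, rel_tol: float = 1e-3) -> float:
        """First stored time at which the peak rise is within ``rel_tol`` of
        its final value."""
        trace = self.peak_trace() - self.fields[0].values.max()
        final = trace[-1]
        if final <= 0:
            return 0.0
        ok = np.nonzero(trace >= (1.0 - rel_tol) * final)[0]
        return float(self.times[ok[0]])


def thermal_conductivity_map(grid: Grid,
                             materials: MaterialsRegistry | None = None,
                             scenario: Scenario | None = None) -> np.ndarray:
    """Per-node thermal conductivity; with a scenario given, cells cut by a
    particle's spherical surfaces get a series-effective conductivity so the
    interfaces sit at their exact radii in the radial fluxes."""
    from .electrostatics import _blend_interface

    materials = materials or default_registry()
    k = np.empty(grid.shape)
    for region, code in grid.regions.items():
        k[grid.labels == code] = materials.get(region).k_th
    if scenario is not None:
        k_shell = materials.get("shell").k_th
        k_coat = materials.get("mv_coating").k_th
        k_fluid = materials.get("extracellular_fluid").k_th
        for p in scenario.particles:
            if p.coating_thickness > 0:
                _blend_interface(k, grid, p.center, p.shell_outer_radius,
                                 k_shell, k_coat)
                _blend_interface(k, grid, p.center, p.outer_radius,
                                 k_coat, k_fluid)
            else:
                _blend_interface(k, grid, p.center, p.shell_outer_radius,
                                 k_shell, k_fluid)
    return k


def _volumetric_heat_capacity(grid: Grid, materials: MaterialsRegistry
                              ) -> np.ndarray:
    rc = np.empty(grid.shape)
    for region, code in grid.regions.items():
        m = materials.get(region)
        rc[grid.labels == code] = m.rho * m.cp
    return rc


def _far_boundary_mask(grid: Grid) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    for axis in range(len(grid.shape)):
        sl = [slice(None)] * len(grid.shape)
        if not (grid.kind == "axisymmetric" and axis == 0):
            sl[axis] = 0
            mask[tuple(sl)] = True
        sl[axis] = -1
        mask[tuple(sl)] = True
    return mask


def solve_steady_temperature(
    power: PowerDensityField,
    grid: Grid,
    materials: MaterialsRegistry | None = None,
    scenario: Scenario | None = None,
    rtol: float = 1e-9,
) -> TemperatureField:
    """Steady solution of -div(k grad T) = q, T = 37 degC far away.

    Flux-conservative discretisation with harmonic-mean conductivities at
    region interfaces; the particle interior conducts with its stand-in
    properties (it holds no source, so it equilibrates to its surface
    temperature and the exterior field is insensitive to the stand-ins).
    """
    materials = materials or default_registry()
    T_body = scenario.far_field_kelvin if scenario is not None else 310.15
    k = thermal_conductivity_map(grid, materials, scenario)
    mask = _far_boundary_mask(grid)
    values = np.zeros(grid.shape)
    u, info = solve_diffusion(grid, k, mask, values, source=power.q.values,
                              rtol=rtol)
    fm = FieldMap(u + T_body, grid, name="T", units="K")
    return TemperatureField(T=fm, steady=True, info=info)


def solve_transient_temperature(
    power: PowerDensityField,
    grid: Grid,
    materials: MaterialsRegistry | None = None,
    scenario: Scenario | None = None,
    t_end: float = 1e-3,
    dt: float = 1e-6,
    n_store: int = 20,
    rtol: float = 1e-9,
) -> TemperatureSeries:
    """Implicit-Euler integration from the uniform 37 degC initial state.

    Each step solves (rho cp / dt) u_new - div(k grad u_new)
    = (rho cp / dt) u_old + q on the rise u = T - T_body.  The scheme is
    unconditionally stable and approaches the steady solution monotonically
    for a constant source.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    materials = materials or default_registry()
    T_body = scenario.far_field_kelvin if scenario is not None else 310.15
    k = thermal_conductivity_map(grid, materials, scenario)
    rc = _volumetric_heat_capacity(grid, materials)
    mask = _far_boundary_mask(grid)
    zeros = np.zeros(grid.shape)
    q = power.q.values

    n_steps = int(round(t_end / dt))
    store_at = set(np.unique(np.linspace(0, n_steps, min(n_store, n_steps) + 1,
                                         dtype=int)).tolist())
    u = np.zeros(grid.shape)
    times = [0.0]
    fields = [FieldMap(u + T_body, grid, "T", "K")]
    # reaction-diffusion form: (rho cp/dt) u_new - div(k grad u_new) = rhs
    from ._fd import DiffusionSystem

    system = DiffusionSystem(grid, k, mask, zeros, reaction=rc / dt)
    for step in range(1, n_steps + 1):
        rhs = q + rc * u / dt
        u, _ = system.solve(source=rhs, rtol=rtol, x0=u[~mask].ravel()
                            if system.n_unknowns > 400_000 else None)
        if step in store_at:
            times.append(step * dt)
            fields.append(FieldMap(u + T_body, grid, "T", "K"))
    return TemperatureSeries(times=np.array(times), fields=fields, grid=grid)


def steady_boundary_flux(T_field: TemperatureField, grid: Grid,
                         materials: MaterialsRegistry | None = None,
                         scenario: Scenario | None = None) -> float:
    """Conductive power leaving through the far boundary, W.  At steady
    state this balances the total Joule power (energy conservation)."""
    k = thermal_conductivity_map(grid, materials, scenario)
    return far_boundary_flux(grid, k, T_field.T.values)


def temperature_profile(
    T_field: TemperatureField,
    scenario: Scenario,
    n_probes: int = 64,
    max_distance: float = 100e-9,
    n_radii: int = 101,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Temperature decay vs distance from each particle's outer surface.

    Columns: ``particle``, ``distance_from_surface_nm``, ``T_celsius`` (the
    mean over ray directions) plus min/max envelopes.
    """
    from .damage import _eval_points, _ray_directions  # shared probing

    interp = T_field.T.interpolator()
    distances = np.linspace(0.0, max_distance, n_radii)
    rows = []
    for ip, p in enumerate(scenario.particles):
        dirs = _ray_directions(scenario, n_probes, rng)
        for d in distances:
            d_eval = max(d, 2.0 * T_field.grid.spacing)
            pts = np.asarray(p.center)[None, :] \
                + (p.outer_radius + d_eval) * dirs
            vals = _eval_points(interp, pts, T_field.grid)
            ok = np.ones(len(pts), dtype=bool)
            for jq, q_ in enumerate(scenario.particles):
                if jq != ip:
                    ok &= np.linalg.norm(pts - np.asarray(q_.center), axis=1) \
                        > q_.shell_outer_radius
            vals = vals[ok] - 273.15
            rows.append(dict(
                particle=ip,
                distance_from_surface_nm=d * 1e9,
                T_celsius=float(vals.mean()),
                T_celsius_min=float(vals.min()),
                T_celsius_max=float(vals.max()),
            ))
    return pd.DataFrame(rows)
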
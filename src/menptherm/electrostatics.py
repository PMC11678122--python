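"""DC conduction solve around dipole-polarised nanoparticles.

Under a static magnetic field the magnetostrictive core strains the
piezoelectric shell, which presents a dipolar surface potential
V0 cos(theta) on the shell surface (theta measured from the +z field axis
of each particle).  The surrounding conductive media then carry a steady
current J = sigma E with E = -grad V, and deposit the Joule power density
q = sigma |E|^2 that drives the localised heating.

The magnetoelectric constitutive chain that fixes V0 in absolute terms is
inherited from stationary studies that are not part of this model; V0 is
therefore resolved either by calibration against an anchor temperature
(:func:`calibrate_source` - the default for every quantitative result) or by
scaling a reference amplitude with a magnetostriction saturation curve
(field-scaled mode, for qualitative field sweeps).

Closed forms for the uniform-medium and two-layer (coated) sphere are
provided as independent oracles for the numeric solver.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from ._fd import SolveInfo, solve_diffusion
from .fields import FieldMap
from .materials import MaterialsRegistry, default_registry
from .scenario import Grid, Scenario

__all__ = [
    "PotentialField",
    "PowerDensityField",
    "solve_potential",
    "power_density",
    "total_joule_power",
    "dipole_power",
    "uniform_dipole_analytic",
    "two_layer_dipole_analytic",
    "calibrate_source",
    "conductivity_map",
]


@dataclass
class PotentialField:
    """Electric potential with the per-particle dipole amplitudes."""

    V: FieldMap
    boundary: dict[int, float]
    info: SolveInfo | None = None
    #: FV-consistent Joule density (W/m^3): per-cell share of the discrete
    #: dissipation, exactly consistent with the solved fluxes.
    q_fv: np.ndarray | None = None


@dataclass
class PowerDensityField:
    E: FieldMap
    J: FieldMap
    q: FieldMap


def conductivity_map(scenario: Scenario, grid: Grid,
                     materials: MaterialsRegistry | None = None) -> np.ndarray:
    """Per-node electrical conductivity.

    With ``scenario.coating_in_conduction`` false (default) the MV coating
    is electrically transparent: the Joule source is the bare particle's,
    and the coating acts only thermally.
    """
    materials = materials or default_registry()
    sigma = np.empty(grid.shape)
    for region, code in grid.regions.items():
        if region == "mv_coating" and not scenario.coating_in_conduction:
            val = materials.get("extracellular_fluid").sigma
        else:
            val = materials.get(region).sigma
        sigma[grid.labels == code] = val
    if scenario.coating_in_conduction:
        s_coat = materials.get("mv_coating").sigma
        s_fluid = materials.get("extracellular_fluid").sigma
        for p in scenario.particles:
            if p.coating_thickness > 0:
                _blend_interface(sigma, grid, p.center, p.outer_radius,
                                 s_coat, s_fluid)
    return sigma


def _blend_interface(coeff: np.ndarray, grid: Grid, center, radius: float,
                     c_in: float, c_out: float) -> None:
    """Series-resistance homogenisation of cells cut by a spherical material
    interface.

    A node whose radial cell [d - h/2, d + h/2] straddles the interface gets
    the series-effective coefficient h / (w_in/c_in + w_out/c_out), which
    places the interface at its exact radius in the radial two-point fluxes
    and removes most of the voxelisation error there.
    """
    h = grid.spacing
    coords = np.stack(_node_coords(grid), axis=-1)
    if grid.kind == "axisymmetric":
        c = np.array([0.0, center[2]])
    else:
        c = np.asarray(center)
    d = np.linalg.norm(coords - c, axis=-1)
    cut = np.abs(d - radius) < 0.5 * h
    if not cut.any():
        return
    w_in = np.clip(radius - (d[cut] - 0.5 * h), 0.0, h)
    w_out = h - w_in
    coeff[cut] = h / (w_in / c_in + w_out / c_out)


def _dirichlet_data(scenario: Scenario, grid: Grid, V0: dict[int, float]):
    """Dirichlet mask/values: particle interiors (shell surface dipole,
    linearly extended inward) and the far boundary at zero."""
    labels = grid.labels
    mask = (labels == grid.regions["core"]) | (labels == grid.regions["shell"])
    values = np.zeros(grid.shape)
    coords = _node_coords(grid)
    for ip, p in enumerate(scenario.particles):
        own = mask & (grid.owner == ip)
        if not own.any():
            continue
        zc = p.center[2]
        z = coords[-1]
        # harmonic (linear-in-z) interior extension of V0 cos(theta)
        values[own] = V0[ip] * (z[own] - zc) / p.shell_outer_radius
    # far boundary
    bmask = np.zeros(grid.shape, dtype=bool)
    for axis in range(len(grid.shape)):
        sl = [slice(None)] * len(grid.shape)
        if not (grid.kind == "axisymmetric" and axis == 0):
            sl[axis] = 0
            bmask[tuple(sl)] = True
        sl[axis] = -1
        bmask[tuple(sl)] = True
    mask = mask | bmask
    values[bmask] = 0.0
    return mask, values


def _node_coords(grid: Grid) -> tuple[np.ndarray, ...]:
    return tuple(np.meshgrid(*grid.axes, indexing="ij"))


def _cut_link_callback(scenario: Scenario, grid: Grid, V0: dict[int, float]):
    """Shortley-Weller treatment of links crossing a shell surface.

    The link from a fluid node to a particle-interior Dirichlet node is
    shortened to the exact distance to the sphere r = a_p and the boundary
    value becomes V0 cos(theta) at the intersection point.  The fluid-side
    conductivity alone enters the transmissibility (the particle interior is
    not part of the conduction domain).
    """
    coords = _node_coords(grid)
    ndim = len(grid.shape)
    h = grid.spacing
    owner = grid.owner.ravel()
    centers = np.array([p.center for p in scenario.particles])
    radii = np.array([p.shell_outer_radius for p in scenario.particles])
    V0_arr = np.array([V0[i] for i in range(len(scenario.particles))])
    if grid.kind == "axisymmetric":
        # work in the (r, z) plane; particle centre is (0, zc)
        c2d = np.column_stack([np.zeros(len(centers)), centers[:, 2]])
    flat_coords = [c.ravel() for c in coords]

    def callback(u, d, axis, sign, geo, coeff_u, T, val):
        jp = owner[d]
        cut = jp >= 0
        if not cut.any():
            return T, val
        T = T.copy()
        val = np.array(val, dtype=float, copy=True)
        uc = u[cut]
        j = jp[cut]
        a = radii[j]
        if grid.kind == "axisymmetric":
            w = np.column_stack([flat_coords[0][uc], flat_coords[1][uc]]) \
                - c2d[j]
        else:
            w = np.column_stack([fc[uc] for fc in flat_coords]) - centers[j]
        # |w + s*sign*h*e_axis|^2 = a^2  ->  s^2 + 2 B s + C = 0
        B = w[:, axis] * sign / h
        C = (np.einsum("ij,ij->i", w, w) - a ** 2) / h ** 2
        disc = np.sqrt(np.maximum(B * B - C, 0.0))
        s1 = -B - disc
        s2 = -B + disc
        s = np.where((s1 > 0) & (s1 <= 1.0), s1, s2)
        s = np.clip(s, 0.05, 1.0)
        x_int = w.copy()
        x_int[:, axis] += s * sign * h
        # z-component of the intersection in the particle frame
        z_rel = x_int[:, -1]
        T[cut] = coeff_u[cut] * geo[cut] / s
        val[cut] = V0_arr[j] * z_rel / a
        return T, val

    return callback


def solve_potential(
    scenario: Scenario,
    grid: Grid,
    materials: MaterialsRegistry | None = None,
    V0: float | None = None,
    rtol: float = 1e-9,
) -> PotentialField:
    """Solve div(sigma grad V) = 0 with the dipole Dirichlet surfaces.

    ``V0`` overrides the scenario source amplitude (used during
    calibration).  The particle interiors are excluded from the conduction
    domain; the far boundary is grounded (V = 0).
    """
    materials = materials or default_registry()
    if V0 is None:
        V0 = scenario.source.resolved_V0()
    V0_per = {ip: V0 for ip in range(len(scenario.particles))}
    sigma = conductivity_map(scenario, grid, materials)
    mask, values = _dirichlet_data(scenario, grid, V0_per)
    cb = _cut_link_callback(scenario, grid, V0_per)
    V, info = solve_diffusion(grid, sigma, mask, values, source=None,
                              link_callback=cb, rtol=rtol)
    q_fv = _fv_joule_density(scenario, grid, sigma, mask, V, V0_per)
    fm = FieldMap(V, grid, name="V", units="V")
    return PotentialField(V=fm, boundary=V0_per, info=info, q_fv=q_fv)


def _fv_joule_density(scenario, grid, sigma, dmask, V, V0_per) -> np.ndarray:
    """Per-cell Joule density from the discrete link dissipation.

    Each link contributes T (dV)^2, split between its two cells; links into
    a Dirichlet surface (cut links) are assigned wholly to the fluid cell.
    Summed over cells this equals the discrete total dissipation exactly.
    """
    from ._fd import _face_geometry, _pair_indices

    shape = grid.shape
    h = grid.spacing
    sf = sigma.ravel()
    dm = dmask.ravel()
    Vf = V.ravel()
    energy = np.zeros(Vf.size)
    cb = _cut_link_callback(scenario, grid, V0_per)
    for axis in range(len(shape)):
        geo = _face_geometry(grid, axis).ravel()
        iL, iR = _pair_indices(shape, axis)
        cL, cR = sf[iL], sf[iR]
        with np.errstate(divide="ignore", invalid="ignore"):
            harm = np.where(cL + cR > 0, 2 * cL * cR / (cL + cR), 0.0)
        T = harm * geo
        uu = ~dm[iL] & ~dm[iR]
        e = T[uu] * (Vf[iL[uu]] - Vf[iR[uu]]) ** 2
        np.add.at(energy, iL[uu], 0.5 * e)
        np.add.at(energy, iR[uu], 0.5 * e)
        for u_is_left in (True, False):
            if u_is_left:
                m = ~dm[iL] & dm[iR]
                u, d, sign = iL[m], iR[m], +1
            else:
                m = ~dm[iR] & dm[iL]
                u, d, sign = iR[m], iL[m], -1
            if not len(u):
                continue
            T_ud, val = cb(u, d, axis, sign, geo[m], sf[u], T[m],
                           Vf[d])
            np.add.at(energy, u, T_ud * (Vf[u] - val) ** 2)
    vol = grid.node_volumes().ravel()
    q = np.where(dm, 0.0, energy / vol)
    return q.reshape(shape)


def power_density(
    potential: PotentialField,
    materials: MaterialsRegistry | None = None,
    scenario: Scenario | None = None,
) -> PowerDensityField:
    """Electric field, current density and Joule power density maps.

    E is the central-difference gradient of V (for export and probing); the
    power density map q is the flux-consistent finite-volume dissipation
    carried by the potential solve, which integrates to the exact discrete
    total power.  Inside the core/shell (no conduction) all three vanish.
    """
    grid = potential.V.grid
    V = potential.V.values
    h = grid.spacing
    grads = np.gradient(V, h, edge_order=2)
    E = -np.stack(grads, axis=-1)
    interior = (grid.labels == grid.regions["core"]) \
        | (grid.labels == grid.regions["shell"])
    E[interior] = 0.0
    if scenario is not None:
        sigma = conductivity_map(scenario, grid, materials)
    else:
        materials = materials or default_registry()
        sigma = np.empty(grid.shape)
        for region, code in grid.regions.items():
            sigma[grid.labels == code] = materials.get(region).sigma
    sigma = np.where(interior, 0.0, sigma)
    J = sigma[..., None] * E
    if potential.q_fv is not None:
        q = potential.q_fv
    else:
        q = sigma * np.sum(E * E, axis=-1)
    return PowerDensityField(
        E=FieldMap(E, grid, "E", "V/m"),
        J=FieldMap(J, grid, "J", "A/m^2"),
        q=FieldMap(q, grid, "q", "W/m^3"),
    )


def total_joule_power(power: PowerDensityField) -> float:
    """Integral of the Joule density over the domain, W."""
    grid = power.q.grid
    return float((power.q.values * grid.node_volumes()).sum())


def dipole_power(sigma: float, V0: float, a: float) -> float:
    """Closed-form total power of a bare dipole sphere in a uniform medium:
    P = (8 pi / 3) sigma V0^2 a."""
    return 8.0 * math.pi / 3.0 * sigma * V0 ** 2 * a


def uniform_dipole_analytic(r, theta, a: float, V0: float):
    """Exterior l=1 solution for a sphere of radius ``a`` at potential
    V0 cos(theta) in a uniform medium: V = V0 (a/r)^2 cos(theta).

    Returns ``(V, E_r, E_theta)``.
    """
    r = np.asarray(r, dtype=float)
    V = V0 * (a / r) ** 2 * np.cos(theta)
    Er = 2.0 * V0 * a ** 2 / r ** 3 * np.cos(theta)
    Et = V0 * a ** 2 / r ** 3 * np.sin(theta)
    return V, Er, Et


def two_layer_coefficients(a: float, b: float, sigma_coat: float,
                           sigma_fluid: float, V0: float):
    """(A, B, C) of the piecewise l=1 solution: coating
    V = (A r + B/r^2) cos(theta) for a <= r <= b, fluid V = C/r^2 cos(theta),
    with V = V0 cos(theta) at r=a and continuity of V and radial current at
    r=b."""
    if not a < b:
        raise ValueError("need a < b")
    beta = 2.0 * (sigma_coat - sigma_fluid) / (sigma_coat + 2.0 * sigma_fluid)
    B = V0 / (beta * a / b ** 3 + 1.0 / a ** 2)
    A = beta * B / b ** 3
    C = A * b ** 3 + B
    return A, B, C


def two_layer_dipole_analytic(r, theta, a: float, b: float,
                              sigma_coat: float, sigma_fluid: float,
                              V0: float):
    """Closed-form potential and field of the coated (two-layer) sphere.

    Oracle for the numeric solver with ``coating_in_conduction`` enabled; in
    the homogeneous limit sigma_coat = sigma_fluid it reduces to
    :func:`uniform_dipole_analytic`.  Returns ``(V, E_r, E_theta)`` for
    r >= a.
    """
    A, B, C = two_layer_coefficients(a, b, sigma_coat, sigma_fluid, V0)
    r = np.asarray(r, dtype=float)
    coat = r < b
    V = np.where(coat, (A * r + B / r ** 2), C / r ** 2) * np.cos(theta)
    Er = np.where(coat, -(A - 2 * B / r ** 3), 2 * C / r ** 3) * np.cos(theta)
    Et = np.where(coat, (A + B / r ** 3), C / r ** 3) * np.sin(theta)
    return V, Er, Et


def calibrate_source(
    scenario: Scenario,
    anchor_temperature: float | None = None,
    anchor_location: str | None = None,
    grid: Grid | None = None,
    materials: MaterialsRegistry | None = None,
    spacing: float | None = None,
) -> float:
    """Find the dipole amplitude whose steady peak temperature matches the
    anchor.

    The conduction chain is linear in q and q scales as V0^2, so the rise
    above body temperature scales exactly quadratically with V0: a single
    trial solve at V0 = 1 V fixes the calibrated amplitude,
    V0 = sqrt(dT_target / dT_trial).  The scenario's source is updated in
    place and the amplitude returned.
    """
    from .bioheat import solve_steady_temperature  # deferred: cyclic import

    src = scenario.source
    anchor_T = anchor_temperature if anchor_temperature is not None \
        else src.anchor_temperature
    anchor_loc = anchor_location or src.anchor_location
    if anchor_T is None:
        raise ValueError("calibration needs an anchor temperature")
    if anchor_T <= scenario.far_field_celsius:
        raise ValueError(
            f"anchor temperature {anchor_T} degC must exceed the far-field "
            f"{scenario.far_field_celsius} degC")
    if grid is None:
        from .scenario import build_grid
        grid = build_grid(scenario, spacing)
    materials = materials or default_registry()

    pot = solve_potential(scenario, grid, materials, V0=1.0)
    power = power_density(pot, materials, scenario)
    T = solve_steady_temperature(power, grid, materials, scenario)
    dT_trial = _anchor_delta(T.T.values, grid, anchor_loc) \
        - scenario.far_field_kelvin
    if dT_trial <= 0:
        raise RuntimeError("trial solve produced no heating at the anchor")
    V0 = math.sqrt((anchor_T - scenario.far_field_celsius) / dT_trial)
    src.V0 = V0
    src.anchor_temperature = anchor_T
    src.anchor_location = anchor_loc
    return V0


def _anchor_delta(T: np.ndarray, grid: Grid, anchor_location: str) -> float:
    if anchor_location == "surface":
        mask = (grid.labels == grid.regions["core"]) \
            | (grid.labels == grid.regions["shell"])
    elif anchor_location == "fluid_max":
        mask = grid.labels == grid.regions["extracellular_fluid"]
    else:
        raise ValueError("anchor_location must be 'surface' or 'fluid_max'")
    return float(T[mask].max())
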
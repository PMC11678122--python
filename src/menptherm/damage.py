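"""Arrhenius thermal-damage model.

The damaged fraction alpha of a biological material held at absolute
temperature T grows at the Arrhenius rate

    d(alpha)/dt = k(T) = A * exp(-E / (R T))

with A the frequency factor (1/s), E the activation energy (J/mol) and R the
universal gas constant.  The printed model is zeroth order in alpha (the rate
does not slow as material is consumed) and alpha is capped at 1; a
conventional first-order variant d(alpha)/dt = k(T) (1 - alpha), i.e.
alpha = 1 - exp(-k t), is available behind the ``first_order`` flag for
sensitivity analysis.  "Complete" damage means alpha >= DAMAGE_THRESHOLD.

At a temperature held constant in time the integral is closed-form,
alpha(t) = min(1, k(T) t); nanoscale thermal equilibration (~0.1 us) is many
orders of magnitude faster than the minutes-long stimulation, so damage is
normally integrated on the steady temperature field (quasi-steady
treatment).  A trapezoidal integrator over a temperature time series is
provided for genuinely time-varying exposures.

Rates are evaluated in log space, exp(ln A - E/(R T)), so enormous
frequency factors (A ~ 1e42 1/s) and minuscule Boltzmann factors
(E/(R T) ~ 109 at body temperature for the extracellular kinetics) combine
without overflowing intermediates for any admissible parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import FieldMap
from .materials import MaterialsRegistry, default_registry
from .scenario import Grid, Scenario

__all__ = [
    "R_GAS",
    "DAMAGE_THRESHOLD",
    "arrhenius_rate",
    "integrate_damage",
    "damage_profile",
    "damaged_area_fraction",
    "time_to_full_damage",
    "DamageField",
]

#: Universal gas constant, J/(mol K).
R_GAS = 8.314462618

#: alpha at or above this value counts as complete (100%) damage.
DAMAGE_THRESHOLD = 0.999

#: Exposure beyond which a finite time-to-damage is reported, s.
_MAX_EXPOSURE_S = 600.0


def arrhenius_rate(T, E_act: float, A_freq: float):
    """Damage rate k(T) = A exp(-E/(R T)), 1/s.

    Parameters
    ----------
    T:
        Absolute temperature, K (scalar or array).  Must be positive.
    E_act:
        Activation energy, J/mol.
    A_freq:
        Frequency factor, 1/s.  ``A_freq = 0`` gives a zero rate.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0.0):
        raise ValueError("absolute temperature must be positive")
    if A_freq < 0.0 or E_act < 0.0:
        raise ValueError("Arrhenius constants must be non-negative")
    if A_freq == 0.0:
        return np.zeros_like(T) if T.ndim else 0.0
    with np.errstate(under="ignore"):
        log_k = np.log(A_freq) - E_act / (R_GAS * T)
        k = np.exp(log_k)
    return k if T.ndim else float(k)


@dataclass
class DamageField:
    """Damaged-fraction field alpha in [0, 1] with its exposure metadata."""

    alpha: FieldMap
    exposure_time: float
    kinetics_per_region: dict[str, tuple[float, float]] = field(default_factory=dict)
    first_order: bool = False


def _kinetics_maps(grid: Grid, materials: MaterialsRegistry):
    """Per-node (E, A) arrays; regions without kinetics get A = 0."""
    E = np.zeros(grid.shape)
    A = np.zeros(grid.shape)
    table: dict[str, tuple[float, float]] = {}
    for region, code in grid.regions.items():
        m = materials.get(region)
        if not m.has_kinetics:
            continue
        mask = grid.labels == code
        E[mask] = m.E_act
        A[mask] = m.A_freq
        table[region] = (m.E_act, m.A_freq)
    return E, A, table


def integrate_damage(
    T_field,
    t_end: float,
    materials: MaterialsRegistry | None = None,
    *,
    grid: Grid | None = None,
    first_order: bool = False,
) -> DamageField:
    """Integrate the damage law over ``t_end`` seconds of exposure.

    ``T_field`` is either a steady :class:`~menptherm.bioheat.TemperatureField`
    (closed-form integral per node) or a
    :class:`~menptherm.bioheat.TemperatureSeries` (trapezoidal quadrature of
    the rate over the stored snapshots, clamped to ``t_end``).  Kinetics are
    selected per node from the region labels; regions without registered
    kinetics (particle core/shell) stay at alpha = 0.
    """
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    materials = materials or default_registry()

    snapshots = getattr(T_field, "fields", None)
    if snapshots is not None:  # temperature time series
        g = grid or T_field.grid
        E, A, table = _kinetics_maps(g, materials)
        times = np.asarray(T_field.times, dtype=float)
        keep = times <= t_end + 1e-12
        times = times[keep]
        rates = [_safe_rate(s.values, E, A)
                 for s, k in zip(snapshots, keep) if k]
        omega = np.zeros(g.shape)
        for i in range(1, len(times)):
            omega += 0.5 * (times[i] - times[i - 1]) * (rates[i] + rates[i - 1])
    else:
        g = grid or T_field.grid
        E, A, table = _kinetics_maps(g, materials)
        omega = _safe_rate(T_field.T.values, E, A) * t_end

    if first_order:
        with np.errstate(under="ignore"):
            alpha = -np.expm1(-omega)
    else:
        alpha = np.minimum(omega, 1.0)
    fm = FieldMap(values=alpha, grid=g, name="alpha", units="1")
    return DamageField(alpha=fm, exposure_time=float(t_end),
                       kinetics_per_region=table, first_order=first_order)


def _safe_rate(T, E, A):
    """Vectorised A exp(-E/(R T)) with per-node constants; A = 0 -> 0."""
    T = np.maximum(np.asarray(T, dtype=float), 1e-300)
    out = np.zeros(np.broadcast_shapes(T.shape, np.shape(A)))
    active = np.asarray(A) > 0
    with np.errstate(under="ignore", divide="ignore"):
        logk = np.where(active, np.log(np.where(active, A, 1.0)), -np.inf) \
            - np.asarray(E) / (R_GAS * T)
        out = np.where(active, np.exp(logk), 0.0)
    return out


def damage_profile(
    damage: DamageField,
    scenario: Scenario,
    n_probes: int = 64,
    max_distance: float = 100e-9,
    n_radii: int = 51,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample alpha along outward rays from each particle's outer surface.

    Returns a tidy table with columns ``particle``, ``distance_from_surface_nm``
    and ``alpha`` where, per distance, alpha is reported as min / mean / max
    over ``n_probes`` ray directions (axisymmetric scenarios sweep the polar
    angle; 3D scenarios use quasi-uniform directions on the sphere, seeded by
    ``rng`` if given).
    """
    grid = damage.alpha.grid
    interp = damage.alpha.interpolator()
    distances = np.linspace(0.0, max_distance, n_radii)
    rows = []
    for ip, p in enumerate(scenario.particles):
        R0 = p.outer_radius
        dirs = _ray_directions(scenario, n_probes, rng)
        for d in distances:
            # clamp the first samples clear of the surface: node values within a
            # cell of the interface blend in particle-interior nodes
            d_eval = max(d, 2.0 * grid.spacing)
            pts = np.asarray(p.center)[None, :] + (R0 + d_eval) * dirs
            vals = _eval_points(interp, pts, damage.alpha.grid)
            # discard probes that fall inside a neighbouring particle
            ok = np.ones(len(pts), dtype=bool)
            for jq, q in enumerate(scenario.particles):
                if jq == ip:
                    continue
                ok &= np.linalg.norm(pts - np.asarray(q.center), axis=1) \
                    > q.shell_outer_radius
            vals = vals[ok]
            rows.append(
                dict(particle=ip, distance_from_surface_nm=d * 1e9,
                     alpha_min=float(vals.min()), alpha_mean=float(vals.mean()),
                     alpha_max=float(vals.max()))
            )
    return pd.DataFrame(rows)


def _ray_directions(scenario: Scenario, n: int, rng=None) -> np.ndarray:
    if scenario.symmetry == "axisymmetric_2d":
        theta = np.linspace(0.0, np.pi, n)
        return np.column_stack(
            [np.sin(theta), np.zeros_like(theta), np.cos(theta)]
        )
    if rng is None:
        rng = np.random.default_rng(0)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _eval_points(interp, pts: np.ndarray, grid: Grid) -> np.ndarray:
    if grid.kind == "axisymmetric":
        r = np.hypot(pts[:, 0], pts[:, 1])
        return interp(np.column_stack([r, pts[:, 2]]))
    return interp(pts)


def damaged_area_fraction(
    damage: DamageField,
    scenario: Scenario,
    *,
    plane: str = "z",
    plane_coord: float = 0.0,
    window: tuple[tuple[float, float], tuple[float, float]] | None = None,
    pad: float = 300e-9,
    resolution: int = 400,
    threshold: float = DAMAGE_THRESHOLD,
) -> float:
    """Percent of a planar window (particle interiors excluded) with
    alpha >= ``threshold``.

    The default window is the bounding box of the particle centres on the
    section plane, padded by ``pad`` on every side (the analysis window used
    for cluster sections; the published comparison fixes only that the same
    window is applied to both configurations).
    """
    axes = {"x": (1, 2), "y": (0, 2), "z": (0, 1)}[plane]
    normal = {"x": 0, "y": 1, "z": 2}[plane]
    centers = np.array([p.center for p in scenario.particles])
    if window is None:
        lo = centers[:, list(axes)].min(axis=0) - pad
        hi = centers[:, list(axes)].max(axis=0) + pad
        window = ((lo[0], hi[0]), (lo[1], hi[1]))
    (u0, u1), (v0, v1) = window
    if not (u1 > u0 and v1 > v0):
        raise ValueError("empty section window")
    u = np.linspace(u0, u1, resolution)
    v = np.linspace(v0, v1, resolution)
    U, V = np.meshgrid(u, v, indexing="ij")
    pts = np.zeros((U.size, 3))
    pts[:, axes[0]] = U.ravel()
    pts[:, axes[1]] = V.ravel()
    pts[:, normal] = plane_coord
    alpha = _eval_points(damage.alpha.interpolator(), pts, damage.alpha.grid)
    tissue = np.ones(len(pts), dtype=bool)
    for p in scenario.particles:
        tissue &= np.linalg.norm(pts - np.asarray(p.center), axis=1) > p.outer_radius
    if not tissue.any():
        raise ValueError("section window contains no tissue")
    return 100.0 * float(np.mean(alpha[tissue] >= threshold))


def min_damage_near_surfaces(
    T_field,
    scenario: Scenario,
    t_end: float,
    materials: MaterialsRegistry | None = None,
    max_distance: float = 50e-9,
    n_directions: int = 400,
    n_radii: int = 11,
    rng: np.random.Generator | None = None,
) -> float:
    """Minimum damage fraction over a dense probe shell within
    ``max_distance`` of every particle's coating surface.

    Probes sample the steady temperature (linear interpolation) on rays
    around each particle; the damaged fraction follows from the closed-form
    constant-temperature integral with the extracellular kinetics (the
    coating shares them).  Points inside another particle's shell surface
    are not tissue and are skipped.
    """
    materials = materials or default_registry()
    m = materials.get("extracellular_fluid")
    if rng is None:
        rng = np.random.default_rng(0)
    interp = T_field.T.interpolator()
    grid = T_field.grid
    worst = np.inf
    for p in scenario.particles:
        dirs = rng.normal(size=(n_directions, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for dist in np.linspace(0.0, max_distance, n_radii):
            pts = np.asarray(p.center) + (p.outer_radius + dist) * dirs
            ok = np.ones(len(pts), dtype=bool)
            for q in scenario.particles:
                ok &= np.linalg.norm(pts - np.asarray(q.center), axis=1) \
                    > q.shell_outer_radius
            T = _eval_points(interp, pts[ok], grid)
            k = arrhenius_rate(T, m.E_act, m.A_freq)
            worst = min(worst, float(np.minimum(k * t_end, 1.0).min()))
    return worst


def cytokine_damage(
    T_field,
    scenario: Scenario,
    t_end: float,
    materials: MaterialsRegistry | None = None,
) -> list[dict]:
    """Damage of each bound cytokine: local temperature, rate, damaged
    fraction at ``t_end`` and time to complete denaturation.

    The complex is sub-grid at typical 3D resolutions, so it is treated as a
    passive probe: the steady temperature is sampled at the cytokine centre
    and the antibody-cytokine Arrhenius kinetics applied in closed form.
    """
    materials = materials or default_registry()
    m = materials.get("antibody_cytokine")
    interp = T_field.T.interpolator()
    rows = []
    for c in scenario.complexes:
        p = scenario.particles[c.anchor_particle]
        pos = c.cytokine_center(p)
        Tc = float(_eval_points(interp, pos[None, :], T_field.grid)[0])
        k = arrhenius_rate(Tc, m.E_act, m.A_freq)
        rows.append({
            "anchor_particle": c.anchor_particle,
            "T_celsius": Tc - 273.15,
            "rate_per_s": k,
            "alpha_at_t_end": min(1.0, k * t_end),
            "time_to_full_damage_s": time_to_full_damage(Tc, m.E_act,
                                                         m.A_freq),
        })
    return rows


def time_to_full_damage(
    T,
    E_act: float,
    A_freq: float,
    threshold: float = DAMAGE_THRESHOLD,
):
    """Seconds of constant-temperature exposure until alpha reaches
    ``threshold``; ``np.inf`` where the rate cannot reach it within the
    10-minute protocol (k * 600 s < threshold)."""
    k = arrhenius_rate(T, E_act, A_freq)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.where(k * _MAX_EXPOSURE_S < threshold, np.inf, threshold / k)
    return float(t) if t.ndim == 0 else t
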
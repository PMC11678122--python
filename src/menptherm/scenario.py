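"""Scenario construction: the modelled geometries and their labelled grids.

Three settings are modelled, mirroring the in-silico study designs:

* a single core-shell nanoparticle, optionally wrapped in a 30 nm
  microvesicle-membrane (MV) coating, treated axisymmetrically in r-z;
* a cluster of three MV-coated 120 nm particles with 30 nm surface-to-surface
  gaps, in two qualitatively distinct layouts (collinear and equilateral
  triangle) on a 3D Cartesian grid;
* the same cluster with an antibody-cytokine complex (10 x 5 nm ellipsoid
  plus 5 nm sphere) attached at one of two linking sites that bracket the
  local temperature range: site A faces the hot inter-particle region,
  site B points away from the cluster.

Conventions: SI metres, the z-axis is the applied-DC-field / dipole axis,
the origin sits at the (first) particle centre.  Scenario construction is
fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "NM",
    "ParticleSpec",
    "ComplexSpec",
    "SourceSpec",
    "Scenario",
    "Grid",
    "single_particle_scenario",
    "cluster_scenario",
    "conjugated_cluster_scenario",
    "build_grid",
    "langevin_saturation",
]

NM = 1e-9

#: Fixed region label codes used on every grid.
REGION_CODES = {
    "extracellular_fluid": 0,
    "mv_coating": 1,
    "shell": 2,
    "core": 3,
    "antibody_cytokine": 4,
}

DEFAULT_SHELL_THICKNESS = 20 * NM
DEFAULT_COATING_THICKNESS = 30 * NM
DEFAULT_CLUSTER_GAP = 30 * NM
BODY_TEMPERATURE_C = 37.0


def langevin_saturation(H: float, H_sat: float = 1.0, steepness: float = 5.0) -> float:
    """Default magnetostriction saturation curve s(H), normalised to
    s(H_sat) = 1.

    A Langevin shape L(x) = coth(x) - 1/x captures the qualitative behaviour
    of the core's strain response: negligible output at 50 mT, substantial at
    300 mT, saturated at 1 T.  Used only by the field-scaled source mode;
    calibrated mode bypasses it.
    """
    if H <= 0.0:
        return 0.0

    def L(x: float) -> float:
        return 1.0 / math.tanh(x) - 1.0 / x

    return L(steepness * H / H_sat) / L(steepness)


@dataclass(frozen=True)
class ParticleSpec:
    """One core-shell particle, optionally MV-coated."""

    center: tuple[float, float, float]
    core_diameter: float
    shell_thickness: float = DEFAULT_SHELL_THICKNESS
    coating_thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.core_diameter <= 0 or self.shell_thickness <= 0:
            raise ValueError("particle dimensions must be positive")
        if self.coating_thickness < 0:
            raise ValueError("coating thickness cannot be negative")

    @property
    def core_radius(self) -> float:
        return 0.5 * self.core_diameter

    @property
    def shell_outer_radius(self) -> float:
        """Radius of the piezoelectric shell surface (the dipole surface)."""
        return self.core_radius + self.shell_thickness

    @property
    def outer_radius(self) -> float:
        return self.shell_outer_radius + self.coating_thickness

    @property
    def outer_diameter(self) -> float:
        return 2.0 * self.outer_radius


@dataclass(frozen=True)
class ComplexSpec:
    """Antibody-cytokine complex anchored on a particle's coating surface.

    The antibody ellipsoid (semi-axes ``antibody_semi_axes``, major axis
    radial) touches the coating outer surface along ``site_direction``; the
    cytokine sphere is tangent to the antibody's distal tip.
    """

    anchor_particle: int
    site_direction: tuple[float, float, float]
    antibody_semi_axes: tuple[float, float, float] = (5 * NM, 2.5 * NM, 2.5 * NM)
    cytokine_diameter: float = 5 * NM

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.site_direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            object.__setattr__(self, "site_direction",
                               tuple(np.asarray(self.site_direction) / n))

    def antibody_center(self, particle: ParticleSpec) -> np.ndarray:
        d = np.asarray(self.site_direction)
        return np.asarray(particle.center) + (
            particle.outer_radius + self.antibody_semi_axes[0]) * d

    def cytokine_center(self, particle: ParticleSpec) -> np.ndarray:
        d = np.asarray(self.site_direction)
        reach = (particle.outer_radius + 2 * self.antibody_semi_axes[0]
                 + 0.5 * self.cytokine_diameter)
        return np.asarray(particle.center) + reach * d


@dataclass
class SourceSpec:
    """How the dipole surface-potential amplitude V0 is set.

    calibrated mode (default): V0 is solved for so that the steady maximum
    temperature at ``anchor_location`` equals ``anchor_temperature``; the
    linear conduction chain makes dT proportional to V0**2, so one trial
    solve suffices.  field_scaled mode: V0 = V0_ref * s(applied_field) with
    ``s`` a monotone saturation curve, s(1 T) = 1.
    """

    mode: Literal["calibrated", "field_scaled"] = "calibrated"
    applied_field: float = 1.0  # tesla; 1 T reaches core saturation
    anchor_temperature: float | None = None  # degC, calibrated mode
    anchor_location: Literal["surface", "fluid_max"] = "surface"
    V0: float | None = None  # volts; resolved at run time
    V0_ref: float | None = None  # volts at saturation, field_scaled mode
    saturation_curve: Callable[[float], float] = langevin_saturation

    def resolved_V0(self) -> float:
        if self.mode == "field_scaled":
            if self.V0_ref is None:
                raise ValueError("field_scaled mode requires V0_ref")
            return self.V0_ref * self.saturation_curve(self.applied_field)
        if self.V0 is None:
            raise ValueError(
                "calibrated source not yet resolved; run calibrate_source first")
        return self.V0


@dataclass
class Scenario:
    """Complete geometric + source description of one modelled setting."""

    particles: list[ParticleSpec]
    source: SourceSpec
    complexes: list[ComplexSpec] = dc_field(default_factory=list)
    symmetry: Literal["axisymmetric_2d", "full_3d"] = "full_3d"
    domain_half_width: float | None = None  # auto if None
    far_field_celsius: float = BODY_TEMPERATURE_C
    #: whether the MV coating participates in the DC conduction solve.  The
    #: default keeps it electrically transparent - the Joule source is the
    #: one of the bare particle, and the coating acts through its thermal
    #: properties only (see docs/methods.md for the rationale).
    coating_in_conduction: bool = False
    name: str = "scenario"

    def __post_init__(self) -> None:
        if not self.particles:
            raise ValueError("scenario needs at least one particle")
        if self.symmetry == "axisymmetric_2d":
            if len(self.particles) != 1:
                raise ValueError("axisymmetric scenarios take exactly one particle")
            cx, cy, _ = self.particles[0].center
            if cx != 0.0 or cy != 0.0:
                raise ValueError("axisymmetric particle must sit on the z-axis")
        for i, p in enumerate(self.particles):
            for q in self.particles[i + 1:]:
                d = np.linalg.norm(np.asarray(p.center) - np.asarray(q.center))
                if d < p.outer_radius + q.outer_radius:
                    raise ValueError("particle coated surfaces overlap")
        for c in self.complexes:
            if not 0 <= c.anchor_particle < len(self.particles):
                raise ValueError("complex anchored to unknown particle")

    @property
    def far_field_kelvin(self) -> float:
        return self.far_field_celsius + 273.15

    @property
    def max_outer_radius(self) -> float:
        return max(p.outer_radius for p in self.particles)

    def min_coating_gap(self) -> float:
        """Closest coating-to-coating distance between particle pairs."""
        gaps = [
            np.linalg.norm(np.asarray(p.center) - np.asarray(q.center))
            - p.outer_radius - q.outer_radius
            for i, p in enumerate(self.particles)
            for q in self.particles[i + 1:]
        ]
        return min(gaps) if gaps else math.inf


# ---------------------------------------------------------------------------
# scenario factories
# ---------------------------------------------------------------------------

def single_particle_scenario(
    core_diameter: float,
    coated: bool = False,
    source: SourceSpec | None = None,
    *,
    shell_thickness: float = DEFAULT_SHELL_THICKNESS,
    coating_thickness: float = DEFAULT_COATING_THICKNESS,
    domain_half_width: float | None = None,
    name: str | None = None,
) -> Scenario:
    """One particle on the symmetry axis, modelled axisymmetrically."""
    p = ParticleSpec(
        center=(0.0, 0.0, 0.0),
        core_diameter=core_diameter,
        shell_thickness=shell_thickness,
        coating_thickness=coating_thickness if coated else 0.0,
    )
    return Scenario(
        particles=[p],
        source=source or SourceSpec(),
        symmetry="axisymmetric_2d",
        domain_half_width=domain_half_width,
        name=name or f"single_{core_diameter/NM:.0f}nm{'_coated' if coated else ''}",
    )


def _cluster_particles(configuration: str, gap: float) -> list[ParticleSpec]:
    p0 = ParticleSpec((0.0, 0.0, 0.0), 80 * NM,
                      coating_thickness=DEFAULT_COATING_THICKNESS)
    spacing = 2 * p0.outer_radius + gap  # centre-to-centre
    if configuration == "config-1":
        centers = [(0.0, 0.0, 0.0), (spacing, 0.0, 0.0), (-spacing, 0.0, 0.0)]
    elif configuration == "config-2":
        rc = spacing / math.sqrt(3.0)  # circumradius of the equilateral triangle
        centers = [
            (rc, 0.0, 0.0),
            (-0.5 * rc, 0.5 * math.sqrt(3.0) * rc, 0.0),
            (-0.5 * rc, -0.5 * math.sqrt(3.0) * rc, 0.0),
        ]
    else:
        raise ValueError("configuration must be 'config-1' or 'config-2'")
    return [replace(p0, center=c) for c in centers]


def cluster_scenario(
    configuration: Literal["config-1", "config-2"],
    source: SourceSpec | None = None,
    *,
    gap: float = DEFAULT_CLUSTER_GAP,
    domain_half_width: float | None = None,
) -> Scenario:
    """Three MV-coated 120 nm particles, 30 nm coating-to-coating gaps.

    config-1 lays the particles collinearly along x; config-2 places them on
    an equilateral triangle in the x-y plane (centroid at the origin).  Both
    honour the same gap; they differ in how the damaged region distributes.
    """
    return Scenario(
        particles=_cluster_particles(configuration, gap),
        source=source or SourceSpec(),
        symmetry="full_3d",
        domain_half_width=domain_half_width,
        name=f"cluster_{configuration}",
    )


def conjugated_cluster_scenario(
    site: Literal["A", "B"],
    source: SourceSpec | None = None,
    *,
    configuration: Literal["config-1", "config-2"] = "config-2",
    gap: float = DEFAULT_CLUSTER_GAP,
    domain_half_width: float | None = None,
) -> Scenario:
    """Cluster plus one antibody-cytokine complex at linking site A or B.

    Site A sits on the particle surface facing the cluster centroid (the hot
    inter-particle pocket); site B faces outward on a different particle (the
    coolest surface direction).  The two bracket the temperatures a randomly
    placed complex would see.
    """
    sc = cluster_scenario(configuration, source, gap=gap,
                          domain_half_width=domain_half_width)
    centers = np.array([p.center for p in sc.particles])
    centroid = centers.mean(axis=0)
    if site == "A":
        anchor = 0
        d = centroid - centers[anchor]
    elif site == "B":
        anchor = 1
        d = centers[anchor] - centroid
    else:
        raise ValueError("site must be 'A' or 'B'")
    n = np.linalg.norm(d)
    if n == 0.0:  # anchor at the centroid (collinear middle particle)
        anchor = 1 if site == "A" else 2
        d = (centroid - centers[anchor]) if site == "A" else (centers[anchor] - centroid)
        n = np.linalg.norm(d)
    sc.complexes = [ComplexSpec(anchor_particle=anchor,
                                site_direction=tuple(d / n))]
    sc.name = f"conjugated_{configuration}_site{site}"
    return sc


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

DEFAULT_SPACING = {"axisymmetric_2d": 2 * NM, "full_3d": 6 * NM}

#: margin of fluid kept between the outermost coated surface and the far
#: boundary, as a multiple of the largest outer radius
_FAR_MARGIN_FACTOR = 4.0
_MIN_HALF_WIDTH_FACTOR = 6.0


@dataclass
class Grid:
    """Node-centred structured grid with region labels.

    ``axes`` is (r, z) for axisymmetric grids (r >= 0) or (x, y, z) for 3D
    grids; ``labels`` assigns every node exactly one :data:`REGION_CODES`
    entry; ``owner`` is the index of the particle whose core/shell/coating
    claims the node, -1 in the fluid (complex nodes keep the owner of their
    anchor particle).
    """

    kind: Literal["axisymmetric", "cartesian3d"]
    spacing: float
    axes: tuple[np.ndarray, ...]
    labels: np.ndarray
    owner: np.ndarray
    regions: dict[str, int]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.axes)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def node_volumes(self) -> np.ndarray:
        """Finite-volume cell sizes, m^3 (axisymmetric cells include 2*pi*r)."""
        h = self.spacing
        if self.kind == "cartesian3d":
            return np.full(self.shape, h ** 3)
        r, z = self.axes
        r_out = r + 0.5 * h
        r_in = np.maximum(r - 0.5 * h, 0.0)
        ring = math.pi * (r_out ** 2 - r_in ** 2) * h
        return np.broadcast_to(ring[:, None], self.shape).copy()

    def region_volume(self, region: str) -> float:
        return float(self.node_volumes()[self.labels == self.regions[region]].sum())

    def node_coordinates(self) -> tuple[np.ndarray, ...]:
        return tuple(np.meshgrid(*self.axes, indexing="ij"))


def _half_widths(scenario: Scenario, spacing: float) -> tuple[float, ...]:
    R = scenario.max_outer_radius
    if scenario.domain_half_width is not None:
        L = scenario.domain_half_width
        if L < _MIN_HALF_WIDTH_FACTOR * R * (1.0 - 1e-12):
            raise ValueError(
                f"domain_half_width must be >= {_MIN_HALF_WIDTH_FACTOR:.0f} x "
                f"largest outer radius ({_MIN_HALF_WIDTH_FACTOR * R:.3g} m)")
        widths = (L,) * (2 if scenario.symmetry == "axisymmetric_2d" else 3)
    else:
        centers = np.array([p.center for p in scenario.particles])
        if scenario.symmetry == "axisymmetric_2d":
            extent = np.array([0.0, abs(centers[0, 2])])
        else:
            extent = np.abs(centers).max(axis=0)
        widths = tuple(
            max(_MIN_HALF_WIDTH_FACTOR * R, e + R + _FAR_MARGIN_FACTOR * R)
            for e in extent
        )
    # snap up to a whole number of cells
    return tuple(spacing * math.ceil(w / spacing) for w in widths)


def _axis(L: float, h: float) -> np.ndarray:
    n = int(round(L / h))
    return np.linspace(0.0, n * h, n + 1)


def _mirrored_axis(L: float, h: float) -> np.ndarray:
    """Axis through zero that is bitwise symmetric under negation, so
    symmetric geometries discretise symmetrically."""
    pos = _axis(L, h)
    return np.concatenate([-pos[:0:-1], pos])


def build_grid(scenario: Scenario, spacing: float | None = None) -> Grid:
    """Label a structured grid for ``scenario``.

    Refuses spacings that cannot resolve the thinnest layer (the 20 nm
    piezoelectric shell needs at least ~3 cells across).  The far boundary
    sits at least six outer radii from every particle so the homogeneous
    far-field conditions approximate an unbounded medium.
    """
    if spacing is None:
        spacing = DEFAULT_SPACING[scenario.symmetry]
    thinnest = min(p.shell_thickness for p in scenario.particles)
    if spacing > thinnest / 3.0:
        raise ValueError(
            f"spacing {spacing:.3g} m too coarse: the {thinnest:.3g} m shell "
            f"needs spacing <= {thinnest / 3.0:.3g} m")

    if scenario.symmetry == "axisymmetric_2d":
        Lr, Lz = _half_widths(scenario, spacing)
        r = _axis(Lr, spacing)
        z = _mirrored_axis(Lz, spacing)
        axes: tuple[np.ndarray, ...] = (r, z)
        R, Z = np.meshgrid(r, z, indexing="ij")
        coords = np.stack([R, np.zeros_like(R), Z], axis=-1)
        kind = "axisymmetric"
    else:
        Lx, Ly, Lz = _half_widths(scenario, spacing)
        x = _mirrored_axis(Lx, spacing)
        y = _mirrored_axis(Ly, spacing)
        z = _mirrored_axis(Lz, spacing)
        axes = (x, y, z)
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        coords = np.stack([X, Y, Z], axis=-1)
        kind = "cartesian3d"

    labels = np.full(coords.shape[:-1], REGION_CODES["extracellular_fluid"],
                     dtype=np.uint8)
    owner = np.full(coords.shape[:-1], -1, dtype=np.int16)

    for ip, p in enumerate(scenario.particles):
        d = np.linalg.norm(coords - np.asarray(p.center), axis=-1)
        if p.coating_thickness > 0:
            m = d <= p.outer_radius
            labels[m] = REGION_CODES["mv_coating"]
            owner[m] = ip
        m = d <= p.shell_outer_radius
        labels[m] = REGION_CODES["shell"]
        owner[m] = ip
        m = d <= p.core_radius
        labels[m] = REGION_CODES["core"]

    for c in scenario.complexes:
        p = scenario.particles[c.anchor_particle]
        u = np.asarray(c.site_direction)
        for center, kind_ in ((c.antibody_center(p), "ellipsoid"),
                              (c.cytokine_center(p), "sphere")):
            rel = coords - center
            if kind_ == "ellipsoid":
                a_par, a_perp, _ = c.antibody_semi_axes
                par = rel @ u
                perp2 = np.einsum("...i,...i->...", rel, rel) - par ** 2
                inside = (par / a_par) ** 2 + perp2 / a_perp ** 2 <= 1.0
            else:
                inside = np.linalg.norm(rel, axis=-1) <= 0.5 * c.cytokine_diameter
            inside &= labels == REGION_CODES["extracellular_fluid"]
            labels[inside] = REGION_CODES["antibody_cytokine"]
            owner[inside] = c.anchor_particle

    return Grid(kind=kind, spacing=spacing, axes=axes, labels=labels,
                owner=owner, regions=dict(REGION_CODES))
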
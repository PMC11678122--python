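"""Material, thermal and denaturation-kinetics constants for the modelled regions.

The biological domains (extracellular fluid, microvesicle-membrane coating,
antibody-cytokine complex) carry the full set of electrical, thermal and
Arrhenius constants.  The particle interior (cobalt-ferrite core, barium-
titanate shell) enters only the heat-conduction solve, through literature-
typical stand-in thermal properties: the interior holds no Joule source, so
any reasonably conductive stand-in leaves it near-isothermal and the fields
outside the shell surface are insensitive to the exact values.

All quantities are stored in SI units; activation energies in J/mol
(frequency-factor / activation-energy pairs follow the protein-denaturation
convention of the Arrhenius damage model, see :mod:`menptherm.damage`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Mapping

import yaml

__all__ = [
    "MaterialProps",
    "MaterialsRegistry",
    "default_registry",
    "get_material",
    "UnknownRegionError",
]


class UnknownRegionError(KeyError):
    """Raised when a region label is not present in the registry."""


@dataclass(frozen=True)
class MaterialProps:
    """Constants for one region.

    Parameters
    ----------
    name:
        Region label.
    sigma:
        Electrical conductivity, S/m.
    eps_r:
        Relative permittivity (dimensionless).  Carried for completeness;
        the DC conduction solve is governed by ``sigma`` alone and never
        reads it.
    rho:
        Mass density, kg/m^3.
    k_th:
        Thermal conductivity, W/(m K).
    cp:
        Specific heat capacity, J/(kg K).
    E_act:
        Arrhenius activation energy for thermal damage, J/mol, or ``None``
        for non-biological regions where damage is not defined.
    A_freq:
        Arrhenius frequency factor, 1/s, or ``None`` likewise.
    """

    name: str
    sigma: float
    eps_r: float
    rho: float
    k_th: float
    cp: float
    E_act: float | None = None
    A_freq: float | None = None

    def __post_init__(self) -> None:
        for attr in ("sigma", "rho", "k_th", "cp"):
            if not getattr(self, attr) > 0.0:
                raise ValueError(f"{self.name}: {attr} must be strictly positive")
        if self.eps_r < 1.0:
            raise ValueError(f"{self.name}: eps_r must be >= 1")
        if (self.E_act is None) != (self.A_freq is None):
            raise ValueError(f"{self.name}: E_act and A_freq must be set together")
        if self.E_act is not None and not (self.E_act > 0.0 and self.A_freq > 0.0):
            raise ValueError(f"{self.name}: Arrhenius constants must be positive")

    @property
    def has_kinetics(self) -> bool:
        return self.E_act is not None


#: Regions every registry must define.  ``core`` and ``shell`` are thermal
#: stand-ins for the particle interior; the remaining three are the
#: biological domains.
REQUIRED_REGIONS = (
    "extracellular_fluid",
    "mv_coating",
    "antibody_cytokine",
    "core",
    "shell",
)

# Biological domains: electrical conductivity (S/m), relative permittivity,
# density (kg/m^3), thermal conductivity (W/m K), specific heat (J/kg K),
# activation energy (J/mol; printed tables use kJ/mol), frequency factor (1/s).
_DEFAULTS = (
    MaterialProps("extracellular_fluid", 2.0, 109.0, 1006.0, 0.60, 3997.0,
                  281.0e3, 2.97e42),
    MaterialProps("mv_coating", 0.3, 80.0, 1380.0, 0.547, 3890.0,
                  281.0e3, 2.97e42),
    MaterialProps("antibody_cytokine", 0.16, 3.23, 1350.0, 0.3, 1200.0,
                  178.0e3, 1.42e26),
    # Particle interior stand-ins (configurable; no damage kinetics).  The
    # conductivities keep the interior effectively isothermal relative to the
    # surrounding fluid (k an order of magnitude above water); sigma/eps_r are
    # nominal placeholders - the interior is excluded from the conduction
    # solve by the dipole Dirichlet surface.
    MaterialProps("core", 1e-6, 1.0, 5300.0, 4.5, 700.0),
    MaterialProps("shell", 1e-6, 1.0, 6020.0, 4.5, 500.0),
)


class MaterialsRegistry:
    """Unit-checked lookup of :class:`MaterialProps` by region label."""

    def __init__(self, materials: Mapping[str, MaterialProps] | None = None):
        if materials is None:
            materials = {m.name: m for m in _DEFAULTS}
        missing = [r for r in REQUIRED_REGIONS if r not in materials]
        if missing:
            raise ValueError(f"registry missing required regions: {missing}")
        self._materials = dict(materials)

    def get(self, region: str) -> MaterialProps:
        try:
            return self._materials[region]
        except KeyError:
            raise UnknownRegionError(
                f"unknown region {region!r}; registered: {sorted(self._materials)}"
            ) from None

    __getitem__ = get

    def __contains__(self, region: str) -> bool:
        return region in self._materials

    def regions(self) -> tuple[str, ...]:
        return tuple(self._materials)

    def with_overrides(self, **overrides: Mapping[str, float]) -> "MaterialsRegistry":
        """Return a copy with per-region field overrides.

        ``registry.with_overrides(core={"k_th": 3.0})``
        """
        mats = dict(self._materials)
        for region, fields in overrides.items():
            mats[region] = replace(self.get(region), **fields)
        return MaterialsRegistry(mats)

    # -- config-file (de)serialization ------------------------------------
    _UNIT_KEYS = {
        "sigma": "sigma_S_per_m",
        "eps_r": "eps_r",
        "rho": "rho_kg_per_m3",
        "k_th": "k_th_W_per_mK",
        "cp": "cp_J_per_kgK",
        "E_act": "E_act_J_per_mol",
        "A_freq": "A_freq_per_s",
    }

    def to_dict(self) -> dict:
        out: dict = {}
        for name, m in self._materials.items():
            d = asdict(m)
            d.pop("name")
            out[name] = {self._UNIT_KEYS[k]: v for k, v in d.items() if v is not None}
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, float]]) -> "MaterialsRegistry":
        inv = {v: k for k, v in cls._UNIT_KEYS.items()}
        mats = {}
        for name, fields in data.items():
            kwargs = {inv[k]: v for k, v in fields.items()}
            mats[name] = MaterialProps(name=name, **kwargs)
        return cls(mats)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "MaterialsRegistry":
        return cls.from_dict(yaml.safe_load(text))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MaterialsRegistry)
            and self._materials == other._materials
        )


def default_registry() -> MaterialsRegistry:
    """The registry with the published biological constants and the particle
    stand-ins."""
    return MaterialsRegistry()


def get_material(region: str) -> MaterialProps:
    """Look one region up in the default registry."""
    return default_registry().get(region)
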
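"""Shared fixtures: solved fields are session-scoped because the PDE solves
dominate the suite's runtime."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import menptherm as mt
from menptherm import bioheat, electrostatics as es
from menptherm.scenario import NM

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return mt.default_registry()


@pytest.fixture(scope="session")
def uncoated_fine():
    """Bare 100 nm particle, h = 2 nm, wide domain (10 outer radii) so the
    far-boundary truncation is negligible at the oracle probe radii."""
    a = 50 * NM
    s = mt.single_particle_scenario(60 * NM, coated=False,
                                    domain_half_width=10 * a)
    g = mt.build_grid(s, 2 * NM)
    pot = es.solve_potential(s, g, V0=1.0)
    power = es.power_density(pot, scenario=s)
    T = bioheat.solve_steady_temperature(power, g, scenario=s)
    return dict(scenario=s, grid=g, pot=pot, power=power, T=T, a=a, V0=1.0)


@pytest.fixture(scope="session")
def coated_two_layer():
    """Coated 100 nm particle with the coating electrically active
    (two-layer conduction), for oracle-equivalence checks."""
    a, b = 50 * NM, 80 * NM
    s = mt.single_particle_scenario(60 * NM, coated=True,
                                    domain_half_width=10 * b)
    s.coating_in_conduction = True
    g = mt.build_grid(s, 2 * NM)
    pot = es.solve_potential(s, g, V0=1.0)
    return dict(scenario=s, grid=g, pot=pot, a=a, b=b, V0=1.0)


def _cluster_solution(configuration: str):
    """Calibrated cluster temperature field: the amplitude comes from a
    single coated 120 nm particle anchored at a 65 degC extracellular
    maximum, solved axisymmetrically; the 3D cluster inherits it."""
    single = mt.single_particle_scenario(80 * NM, coated=True)
    g1 = mt.build_grid(single, 2 * NM)
    V0 = es.calibrate_source(single, 65.0, "fluid_max", grid=g1)
    cluster = mt.cluster_scenario(configuration)
    cluster.source.V0 = V0
    grid = mt.build_grid(cluster)  # default 3D spacing, 6 nm
    pot = es.solve_potential(cluster, grid, V0=V0)
    power = es.power_density(pot, scenario=cluster)
    T = bioheat.solve_steady_temperature(power, grid, scenario=cluster)
    return dict(scenario=cluster, grid=grid, T=T, V0=V0, power=power)


@pytest.fixture(scope="session")
def cluster_config2():
    return _cluster_solution("config-2")


@pytest.fixture(scope="session")
def cluster_config1():
    return _cluster_solution("config-1")


@pytest.fixture
def rng():
    return np.random.default_rng(20241219)
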
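"""Conduction solve vs closed-form oracles, power integrals, calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import menptherm as mt
from menptherm import bioheat, electrostatics as es
from menptherm.scenario import NM, ParticleSpec, Scenario, SourceSpec
from menptherm._fd import box_net_flux


def _probe(pot, grid, r, theta):
    itp = pot.V.interpolator()
    pts = np.column_stack([r * np.sin(theta), r * np.cos(theta)])
    return itp(pts)


class TestUniformDipoleOracle:
    def test_zero_amplitude_gives_zero_fields(self):
        s = mt.single_particle_scenario(60 * NM, coated=False,
                                        domain_half_width=300 * NM)
        g = mt.build_grid(s, 4 * NM)
        pot = es.solve_potential(s, g, V0=0.0)
        assert np.all(pot.V.values == 0.0)
        power = es.power_density(pot, scenario=s)
        assert np.all(power.E.values == 0.0)
        assert np.all(power.q.values == 0.0)

    @pytest.mark.parametrize("r_over_a", [1.5, 2.0])
    def test_potential_matches_closed_form(self, uncoated_fine, r_over_a):
        """V = V0 (a/r)^2 cos(theta) within 1% of the l=1 exterior harmonic."""
        a = uncoated_fine["a"]
        theta = np.linspace(0.05, np.pi - 0.05, 25)
        Vn = _probe(uncoated_fine["pot"], uncoated_fine["grid"],
                    r_over_a * a, theta)
        Va, _, _ = es.uniform_dipole_analytic(r_over_a * a, theta, a, 1.0)
        assert np.max(np.abs(Vn - Va)) / np.max(np.abs(Va)) < 0.01

    def test_error_decreases_with_refinement(self):
        a = 50 * NM
        errs = []
        for h in (4 * NM, 2 * NM):
            s = mt.single_particle_scenario(60 * NM, coated=False,
                                            domain_half_width=10 * a)
            g = mt.build_grid(s, h)
            pot = es.solve_potential(s, g, V0=1.0)
            theta = np.linspace(0.05, np.pi - 0.05, 25)
            # probe close to the surface, where discretisation (not the
            # far-boundary truncation, ~(r/R)^3) dominates the error
            Vn = _probe(pot, g, 1.2 * a, theta)
            Va, _, _ = es.uniform_dipole_analytic(1.2 * a, theta, a, 1.0)
            errs.append(np.max(np.abs(Vn - Va)) / np.max(np.abs(Va)))
        assert errs[1] < errs[0]

    def test_surface_pole_field_magnitude(self, uncoated_fine):
        """|E| at the pole just off the surface approaches 2 V0 / a
        (4e4 V/m for V0 = 1 mV, a = 50 nm)."""
        a = uncoated_fine["a"]
        g = uncoated_fine["grid"]
        Emag = uncoated_fine["power"].E.magnitude()
        itp = Emag.interpolator()
        # a couple of cells off the pole to stay clear of the cut layer
        r_probe = a + 3 * g.spacing
        E_here = float(itp([[0.0, r_probe]])[0])
        expected = 2.0 / a * (a / r_probe) ** 3  # V0 = 1 V
        assert E_here == pytest.approx(expected, rel=0.05)
        # scaled to V0 = 1 mV at the surface itself: 2 V0/a = 4e4 V/m
        assert 2.0 * 1e-3 / a == pytest.approx(4e4)


class TestPower:
    def test_total_power_matches_closed_form(self, uncoated_fine):
        """Integral of sigma |grad V|^2 equals (8 pi/3) sigma V0^2 a
        within 1%."""
        P = es.total_joule_power(uncoated_fine["power"])
        Pa = es.dipole_power(2.0, 1.0, uncoated_fine["a"])
        assert P == pytest.approx(Pa, rel=0.01)

    def test_closed_form_reference_value(self):
        # sigma = 2 S/m, V0 = 1 mV, a = 50 nm
        assert es.dipole_power(2.0, 1e-3, 50 * NM) \
            == pytest.approx(8.3776e-13, rel=1e-4)

    def test_power_halving_spacing_changes_under_2pct(self):
        a = 50 * NM
        P = []
        for h in (4 * NM, 2 * NM):
            s = mt.single_particle_scenario(60 * NM, coated=False,
                                            domain_half_width=6 * a)
            g = mt.build_grid(s, h)
            pot = es.solve_potential(s, g, V0=1.0)
            P.append(es.total_joule_power(es.power_density(pot, scenario=s)))
        assert abs(P[1] / P[0] - 1.0) < 0.02

    def test_q_nonnegative_zero_inside_and_symmetric(self, uncoated_fine):
        g = uncoated_fine["grid"]
        q = uncoated_fine["power"].q.values
        assert q.min() >= 0.0
        interior = (g.labels == g.regions["core"]) \
            | (g.labels == g.regions["shell"])
        assert np.all(q[interior] == 0.0)
        # theta -> pi - theta symmetry: q(r, z) = q(r, -z)
        nz = q.shape[1]
        assert nz % 2 == 1
        assert np.allclose(q, q[:, ::-1], rtol=1e-6, atol=q.max() * 1e-9)

    def test_discrete_conservation_box(self, uncoated_fine):
        """Net current through a closed surface enclosing no boundary is a
        vanishing fraction of the dissipated current scale."""
        g = uncoated_fine["grid"]
        s = uncoated_fine["scenario"]
        sigma = es.conductivity_map(s, g)
        V = uncoated_fine["pot"].V.values
        # a box in the fluid, straddling neither the particle nor the boundary
        nr, nz = g.shape
        lo = (nr // 3, nz // 2 - nr // 6)
        hi = (2 * nr // 3, nz // 2 + nr // 6)
        assert not ((g.labels[lo[0]:hi[0], lo[1]:hi[1]]
                     != g.regions["extracellular_fluid"]).any())
        net = box_net_flux(g, sigma, V, lo, hi)
        # scale: total dipole current magnitude through a hemisphere
        scale = es.dipole_power(2.0, 1.0, uncoated_fine["a"])  # sigma V^2 a
        assert abs(net) < 1e-6 * scale


class TestTwoLayerOracle:
    def test_homogeneous_limit_reduces_to_uniform(self):
        r = np.linspace(60e-9, 400e-9, 50)
        th = 0.7
        V2, Er2, Et2 = es.two_layer_dipole_analytic(r, th, 50e-9, 80e-9,
                                                    2.0, 2.0, 1.0)
        V1, Er1, Et1 = es.uniform_dipole_analytic(r, th, 50e-9, 1.0)
        assert np.allclose(V2, V1)
        assert np.allclose(Er2, Er1)
        assert np.allclose(Et2, Et1)

    def test_far_field_dipole_decay(self):
        _, Er1, _ = es.two_layer_dipole_analytic(1e-6, 0.3, 50e-9, 80e-9,
                                                 0.3, 2.0, 1.0)
        _, Er2, _ = es.two_layer_dipole_analytic(2e-6, 0.3, 50e-9, 80e-9,
                                                 0.3, 2.0, 1.0)
        assert Er1 / Er2 == pytest.approx(8.0, rel=1e-6)

    @pytest.mark.parametrize("r_factor", [1.05, 2.0])
    def test_numeric_matches_two_layer_oracle(self, coated_two_layer,
                                              r_factor):
        """Conduction solve with the coating electrically active agrees with
        the piecewise closed form within 2% (probes on the fluid side, clear
        of the interpolation kink at the interface)."""
        b = coated_two_layer["b"]
        a = coated_two_layer["a"]
        theta = np.linspace(0.05, np.pi - 0.05, 25)
        r = r_factor * b
        Vn = _probe(coated_two_layer["pot"], coated_two_layer["grid"], r,
                    theta)
        Va, _, _ = es.two_layer_dipole_analytic(r, theta, a, b, 0.3, 2.0, 1.0)
        assert np.max(np.abs(Vn - Va)) / np.max(np.abs(Va)) < 0.02

    @given(sc=st.floats(0.05, 5.0), sf=st.floats(0.05, 5.0))
    def test_continuity_at_interface(self, sc, sf):
        a, b = 50e-9, 80e-9
        A, B, C = es.two_layer_coefficients(a, b, sc, sf, 1.0)
        # potential continuity at r = b
        assert A * b + B / b ** 2 == pytest.approx(C / b ** 2, rel=1e-9)
        # radial current continuity: sigma_c (A - 2B/b^3) = -2 sigma_f C/b^3
        assert sc * (A - 2 * B / b ** 3) \
            == pytest.approx(-2 * sf * C / b ** 3, rel=1e-9, abs=1e-6)
        # Dirichlet value recovered at r = a
        assert A * a + B / a ** 2 == pytest.approx(1.0, rel=1e-12)


class TestSuperposition:
    def test_three_far_particles_superpose(self):
        """With coating-to-coating gaps of two outer diameters the cluster
        potential approaches the sum of single-particle dipoles (< 5% at
        each surface pole)."""
        core = 40 * NM
        a = 40 * NM  # 20 nm core radius + 20 nm shell
        spacing_c = 2 * a + 4 * a  # gap = 2 outer diameters
        centers = [(-spacing_c, 0.0, 0.0), (0.0, 0.0, 0.0),
                   (spacing_c, 0.0, 0.0)]
        parts = [ParticleSpec(c, core) for c in centers]
        s = Scenario(particles=parts, source=SourceSpec(V0=1.0),
                     symmetry="full_3d")
        g = mt.build_grid(s, 6.5 * NM)
        pot = es.solve_potential(s, g, V0=1.0)
        itp = pot.V.interpolator()
        for c in centers:
            probe = np.array(c) + np.array([0.0, 0.0, a + 2 * g.spacing])
            Vn = float(itp(probe[None, :])[0])
            Va = sum(
                es.uniform_dipole_analytic(
                    np.linalg.norm(probe - np.array(cc)),
                    np.arccos((probe - np.array(cc))[2]
                              / np.linalg.norm(probe - np.array(cc))),
                    a, 1.0)[0]
                for cc in centers)
            assert Vn == pytest.approx(Va, rel=0.05)


class TestCalibration:
    def test_self_consistency_and_quadratic_scaling(self):
        s = mt.single_particle_scenario(60 * NM, coated=False,
                                        domain_half_width=300 * NM)
        g = mt.build_grid(s, 3 * NM)
        V0 = es.calibrate_source(s, 50.0, "surface", grid=g)
        assert V0 > 0
        pot = es.solve_potential(s, g, V0=V0)
        power = es.power_density(pot, scenario=s)
        T = bioheat.solve_steady_temperature(power, g, scenario=s)
        assert T.peak_celsius("shell") == pytest.approx(50.0, abs=0.1)
        # doubling V0 quadruples the rise everywhere
        pot2 = es.solve_potential(s, g, V0=2 * V0)
        power2 = es.power_density(pot2, scenario=s)
        T2 = bioheat.solve_steady_temperature(power2, g, scenario=s)
        rise = T.T.values - 310.15
        rise2 = T2.T.values - 310.15
        assert np.allclose(rise2, 4.0 * rise, rtol=1e-9,
                           atol=1e-9 * rise.max())

    def test_anchor_below_body_temperature_rejected(self):
        s = mt.single_particle_scenario(60 * NM, coated=False)
        with pytest.raises(ValueError, match="exceed"):
            es.calibrate_source(s, 36.0, "surface")
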
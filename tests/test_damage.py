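"""Arrhenius kinetics and damage integration.

Reference rates are frozen from an independent log-domain scalar
computation, k = exp(ln A - E/(R T)), evaluated for the published kinetics
(extracellular/coating: E = 281 kJ/mol, A = 2.97e42 1/s; antibody-cytokine:
E = 178 kJ/mol, A = 1.42e26 1/s).
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import menptherm as mt
from menptherm import bioheat, electrostatics as es
from menptherm.damage import (
    DAMAGE_THRESHOLD,
    R_GAS,
    _safe_rate,
    arrhenius_rate,
    integrate_damage,
    time_to_full_damage,
)
from menptherm.fields import FieldMap
from menptherm.scenario import NM

EXTRA = (281e3, 2.97e42)
CYTO = (178e3, 1.42e26)


def _log_domain_rate(T, E, A):
    """Independent scalar oracle."""
    return math.exp(math.log(A) - E / (R_GAS * T))


class TestArrheniusRate:
    @pytest.mark.parametrize("T,kin,expected", [
        # frozen from the log-domain oracle
        (338.15, EXTRA, 0.116688),  # 65 degC, extracellular
        (333.15, CYTO, 1.75463e-2),  # 60 degC, antibody-cytokine
        (329.15, EXTRA, 7.58888e-3),  # 56 degC, extracellular
    ])
    def test_reference_rates(self, T, kin, expected):
        k = arrhenius_rate(T, *kin)
        assert k == pytest.approx(expected, rel=1e-3)
        assert k == pytest.approx(_log_domain_rate(T, *kin), rel=1e-12)

    def test_body_temperature_rate_underflows_to_negligible(self):
        k = arrhenius_rate(310.15, *EXTRA)
        assert 0.0 <= k < 1e-4
        assert k * 600.0 < 0.01  # <1% damage over the 10-minute protocol

    def test_zero_frequency_factor_gives_zero_rate(self):
        assert arrhenius_rate(350.0, 281e3, 0.0) == 0.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_rate(0.0, *EXTRA)
        with pytest.raises(ValueError):
            arrhenius_rate(-5.0, *EXTRA)

    @given(logA=st.floats(10.0, 100.0), E_kJ=st.floats(50.0, 400.0))
    def test_log_linearity_slope_recovery(self, logA, E_kJ):
        """log k vs 1/T is affine with slope -E/R, recovered to 1e-6
        relative by a least-squares fit."""
        E = E_kJ * 1e3
        A = math.exp(logA)
        T = np.linspace(310.0, 380.0, 30)
        with np.errstate(under="ignore"):
            k = arrhenius_rate(T, E, A)
        mask = k > 0
        slope, intercept = np.polyfit(1.0 / T[mask], np.log(k[mask]), 1)
        assert slope == pytest.approx(-E / R_GAS, rel=1e-6)
        assert intercept == pytest.approx(logA, rel=1e-6)


class TestTimeToFullDamage:
    @pytest.mark.parametrize("T,kin,expected_s", [
        (338.15, EXTRA, 8.561),    # 65 degC -> seconds
        (328.15, CYTO, 151.57),    # 55 degC cytokine -> ~2.5 min
        (329.15, EXTRA, 131.64),   # 56 degC -> ~2.2 min to full damage
    ])
    def test_reference_times(self, T, kin, expected_s):
        assert time_to_full_damage(T, *kin) \
            == pytest.approx(expected_s, rel=2e-3)

    def test_body_temperature_returns_infinity(self):
        assert time_to_full_damage(310.15, *EXTRA) == np.inf
        assert time_to_full_damage(300.0, *CYTO) == np.inf

    def test_vectorised(self):
        t = time_to_full_damage(np.array([310.15, 338.15]), *EXTRA)
        assert np.isinf(t[0]) and np.isfinite(t[1])


def _steady_T_field(values, grid):
    return bioheat.TemperatureField(FieldMap(values, grid, "T", "K"))


@pytest.fixture(scope="module")
def labelled_case():
    s = mt.conjugated_cluster_scenario("B", domain_half_width=540 * NM)
    g = mt.build_grid(s, 6.5 * NM)
    return s, g


class TestIntegrateDamage:
    def test_exact_closed_form_at_constant_temperature(self, labelled_case):
        s, g = labelled_case
        m = mt.get_material("extracellular_fluid")
        # temperature such that k * t_end = 1 exactly at t_end = 60 s
        k_target = 1.0 / 60.0
        T_star = m.E_act / (R_GAS * (math.log(m.A_freq) - math.log(k_target)))
        T = _steady_T_field(np.full(g.shape, T_star), g)
        d = integrate_damage(T, 60.0, grid=g)
        fluid = g.labels == g.regions["extracellular_fluid"]
        assert np.allclose(d.alpha.values[fluid], 1.0, atol=1e-12)

    def test_body_temperature_damage_negligible_after_10min(self,
                                                            labelled_case):
        s, g = labelled_case
        T = _steady_T_field(np.full(g.shape, 310.15), g)
        d = integrate_damage(T, 600.0, grid=g)
        fluid = g.labels == g.regions["extracellular_fluid"]
        assert d.alpha.values[fluid].max() < 0.01
        # the antibody-cytokine kinetics (lower activation energy) accrue a
        # small but nonzero baseline fraction at body temperature
        assert d.alpha.values.max() < 0.1

    def test_kinetics_selected_by_region(self, labelled_case):
        """Antibody/cytokine nodes use the complex kinetics; coating and
        fluid the extracellular kinetics; particle interior none."""
        s, g = labelled_case
        T_star = 335.0
        T = _steady_T_field(np.full(g.shape, T_star), g)
        d = integrate_damage(T, 10.0, grid=g)
        al = d.alpha.values
        k_ex = arrhenius_rate(T_star, *EXTRA)
        k_cy = arrhenius_rate(T_star, *CYTO)
        fluid = g.labels == g.regions["extracellular_fluid"]
        coat = g.labels == g.regions["mv_coating"]
        cyto = g.labels == g.regions["antibody_cytokine"]
        interior = (g.labels == g.regions["core"]) \
            | (g.labels == g.regions["shell"])
        assert np.allclose(al[fluid], min(1, 10 * k_ex))
        assert np.allclose(al[coat], min(1, 10 * k_ex))
        assert np.allclose(al[cyto], min(1, 10 * k_cy))
        assert np.all(al[interior] == 0.0)
        assert d.kinetics_per_region["mv_coating"] == EXTRA

    def test_trapezoidal_quadrature_matches_closed_form(self, labelled_case):
        """For a temperature series constant in time the quadrature path
        equals min(1, k t) to machine precision."""
        s, g = labelled_case
        T_star = 330.0
        times = np.linspace(0.0, 120.0, 7)
        fields = [FieldMap(np.full(g.shape, T_star), g, "T", "K")
                  for _ in times]
        series = bioheat.TemperatureSeries(times=times, fields=fields, grid=g)
        d_series = integrate_damage(series, 120.0, grid=g)
        k_ex = arrhenius_rate(T_star, *EXTRA)
        fluid = g.labels == g.regions["extracellular_fluid"]
        assert np.allclose(d_series.alpha.values[fluid],
                           min(1.0, k_ex * 120.0), rtol=1e-12)

    def test_monotone_in_time_and_temperature(self, labelled_case):
        s, g = labelled_case
        base = np.full(g.shape, 325.0)
        T1 = _steady_T_field(base, g)
        d_60 = integrate_damage(T1, 60.0, grid=g)
        d_300 = integrate_damage(T1, 300.0, grid=g)
        assert np.all(d_300.alpha.values >= d_60.alpha.values - 1e-15)
        T_hot = _steady_T_field(base + 5.0, g)
        d_hot = integrate_damage(T_hot, 60.0, grid=g)
        assert np.all(d_hot.alpha.values >= d_60.alpha.values - 1e-15)

    def test_first_order_variant_bounded_and_close_for_small_kt(
            self, labelled_case):
        s, g = labelled_case
        T = _steady_T_field(np.full(g.shape, 322.0), g)
        d0 = integrate_damage(T, 30.0, grid=g)
        d1 = integrate_damage(T, 30.0, grid=g, first_order=True)
        assert np.all(d1.alpha.values <= d0.alpha.values + 1e-15)
        fluid = g.labels == g.regions["extracellular_fluid"]
        kt = d0.alpha.values[fluid].max()
        assert kt < 0.1  # small-exposure regime
        assert d1.alpha.values[fluid].max() \
            == pytest.approx(-math.expm1(-kt), rel=1e-9)

    def test_nonpositive_exposure_rejected(self, labelled_case):
        s, g = labelled_case
        T = _steady_T_field(np.full(g.shape, 320.0), g)
        with pytest.raises(ValueError):
            integrate_damage(T, 0.0, grid=g)

    @given(T_c=st.floats(38.0, 90.0), t=st.floats(1.0, 600.0))
    def test_alpha_bounded(self, T_c, t):
        with np.errstate(under="ignore"):
            k = _safe_rate(np.array([T_c + 273.15]), np.array([281e3]),
                           np.array([2.97e42]))
        alpha = min(1.0, float(k[0]) * t)
        assert 0.0 <= alpha <= 1.0


class TestProfilesAndAreas:
    def test_uniform_full_damage_gives_flat_profile(self, labelled_case):
        s, g = labelled_case
        from menptherm.damage import DamageField, damage_profile
        d = DamageField(FieldMap(np.ones(g.shape), g, "alpha"), 300.0)
        prof = damage_profile(d, s, n_probes=16, n_radii=11)
        assert np.allclose(prof["alpha_min"], 1.0)
        assert np.allclose(prof["alpha_max"], 1.0)

    def test_profile_monotone_for_isolated_particle(self, uncoated_fine):
        s = uncoated_fine["scenario"]
        g = uncoated_fine["grid"]
        # temperature decays monotonically outward, so alpha must too
        d = integrate_damage(uncoated_fine["T"], 300.0, grid=g)
        from menptherm.damage import damage_profile
        prof = damage_profile(d, s, n_probes=16, n_radii=21)
        vals = prof["alpha_mean"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)

    def test_area_fraction_trivial_cases(self, labelled_case):
        s, g = labelled_case
        from menptherm.damage import (DamageField, damaged_area_fraction)
        none = DamageField(FieldMap(np.zeros(g.shape), g, "alpha"), 300.0)
        assert damaged_area_fraction(none, s, resolution=50) == 0.0
        full = DamageField(FieldMap(np.ones(g.shape), g, "alpha"), 300.0)
        assert damaged_area_fraction(full, s, resolution=50) == 100.0

    def test_empty_window_rejected(self, labelled_case):
        s, g = labelled_case
        from menptherm.damage import DamageField, damaged_area_fraction
        d = DamageField(FieldMap(np.zeros(g.shape), g, "alpha"), 300.0)
        with pytest.raises(ValueError, match="empty"):
            damaged_area_fraction(d, s, window=((0.0, 0.0), (0.0, 1e-7)))
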
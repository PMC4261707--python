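"""Core tubule model: geometry, kinetics, ODE system, steady-state oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgltsim import (Forcing, PhysiologyParams, build_geometry, convert_units,
                     inhibited_reabsorption_rate, ode_rhs, reabsorption_rate,
                     simulate, steady_state_profile, transporter_params)
from sgltsim.model_core import (N_STATE, SimulationError, steady_initial_state)
from sgltsim.units import mgdl_to_mM


class TestGeometry:
    def test_segment_volumes_split_evenly(self, healthy_geom):
        np.testing.assert_allclose(healthy_geom.segment_volumes[:6], 0.00756)
        np.testing.assert_allclose(healthy_geom.segment_volumes[6:], 0.00648)
        # PCT volume sums to VCTX * VPTC * VPCTC, PST to the complement
        assert healthy_geom.segment_volumes[:6].sum() == pytest.approx(0.216 * 0.3 * 0.7)
        assert healthy_geom.segment_volumes[6:].sum() == pytest.approx(0.216 * 0.3 * 0.3)

    def test_outflows_decrease_linearly(self, healthy_geom):
        q = healthy_geom.outflows(6.5)
        assert q[0] == pytest.approx(6.5 * 0.926)
        assert q[-1] == pytest.approx(6.5 * (1 - 9 * 0.074))
        assert np.all(np.diff(q) < 0)

    def test_capacity_assignment(self, healthy_geom, healthy):
        np.testing.assert_allclose(healthy_geom.per_segment_vmax[:6], healthy.vmax2 / 6)
        np.testing.assert_allclose(healthy_geom.per_segment_vmax[6:], healthy.vmax1 / 3)
        np.testing.assert_allclose(healthy_geom.per_segment_km,
                                   [healthy.km2] * 6 + [healthy.km1] * 3)

    def test_t2dm_per_pct_capacity(self, phys, t2dm):
        geom = build_geometry(phys, t2dm)
        assert geom.per_segment_vmax[0] == pytest.approx(110.0 / 6)

    def test_drug_affinities_by_segment(self, healthy_drug_geom, dapa):
        np.testing.assert_allclose(healthy_drug_geom.per_segment_ki,
                                   [dapa.ki2] * 6 + [dapa.ki1] * 3)

    def test_rejects_nonpositive_gfr(self):
        with pytest.raises(ValueError):
            PhysiologyParams(gfr=-1.0)


class TestReabsorptionKinetics:
    @pytest.mark.parametrize("vmax,km,c,expected", [
        (15.583, 4.0, 4.0, 7.79150),      # half saturation at c = km
        (15.583, 4.0, 0.0, 0.0),
        (20.0 / 3.0, 0.5, 5.0, 6.0606),
    ])
    def test_michaelis_menten_values(self, vmax, km, c, expected):
        assert reabsorption_rate(vmax, km, c) == pytest.approx(expected, abs=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            reabsorption_rate(10.0, 4.0, -0.1)
        with pytest.raises(ValueError):
            inhibited_reabsorption_rate(10.0, 4.0, 4.0, -1.0, 0.3)

    def test_no_drug_is_bitwise_plain_path(self):
        plain = reabsorption_rate(15.583, 4.0, 4.0)
        assert inhibited_reabsorption_rate(15.583, 4.0, 4.0, 0.0, 0.3) == plain

    def test_drug_at_ki_doubles_apparent_km(self):
        r = inhibited_reabsorption_rate(15.583, 4.0, 4.0, 0.3, 0.3)
        assert r == pytest.approx(5.1944, abs=1e-4)

    def test_saturating_drug_abolishes_transport(self):
        assert inhibited_reabsorption_rate(15.583, 4.0, 4.0, 1e12, 0.3) < 1e-8

    @given(c=st.floats(0.0, 50.0), cd=st.floats(0.0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_rate_bounded_and_monotone_in_drug(self, c, cd):
        r = inhibited_reabsorption_rate(15.583, 4.0, c, cd, 0.3)
        assert 0.0 <= r < 15.583
        assert r <= inhibited_reabsorption_rate(15.583, 4.0, c, cd / 2, 0.3) + 1e-12


class TestOdeRhs:
    def test_empty_system_is_stationary(self, healthy_drug_geom):
        forcing = Forcing.constant(0.0, 6.5, 0.6, 0.0)
        dydt = ode_rhs(0.0, np.zeros(N_STATE), healthy_drug_geom, forcing)
        np.testing.assert_array_equal(dydt, 0.0)

    def test_steady_state_has_zero_derivatives(self, healthy_geom):
        forcing = Forcing.constant(mgdl_to_mM(250), 6.5, 0.6)
        y = steady_initial_state(healthy_geom, forcing)
        dydt = ode_rhs(0.0, y, healthy_geom, forcing)
        scale = 6.5 * mgdl_to_mM(250)
        # segment and bladder amounts are stationary (the cumulative
        # accumulators grow at constant rate by construction)
        assert np.all(np.abs(dydt[:10]) < 1e-8 * scale)

    def test_no_plasma_drug_keeps_drug_channel_empty(self, healthy_drug_geom):
        forcing = Forcing.constant(mgdl_to_mM(100), 6.5, 0.6, plasma_drug_nM=0.0)
        y = np.zeros(N_STATE)
        y[:9] = 0.01
        dydt = ode_rhs(0.0, y, healthy_drug_geom, forcing)
        np.testing.assert_array_equal(dydt[14:], 0.0)


class TestSteadyStateOracle:
    def test_healthy_normoglycemia_totals(self, healthy_geom):
        # sequential quadratic-root solution at 100 mg/dL, GFR 6.5 L/h
        prof = steady_state_profile(5.551, healthy_geom, 6.5)
        assert prof.sglt2_rate == pytest.approx(33.4, abs=0.5)
        assert prof.sglt1_rate == pytest.approx(2.7, abs=0.3)
        share = prof.sglt2_rate / prof.total_reabsorption_rate
        assert share == pytest.approx(0.92, abs=0.02)

    def test_no_transporters_concentrate_by_water_removal(self, phys):
        trans = transporter_params("healthy").scale_vmax(sglt1=0.0, sglt2=0.0)
        geom = build_geometry(phys, trans)
        prof = steady_state_profile(10.0, geom, 6.5)
        expected = 6.5 * 10.0 / geom.outflows(6.5)
        np.testing.assert_allclose(prof.glucose_concentrations, expected, rtol=1e-9)
        assert prof.uge_rate == pytest.approx(65.0)

    def test_saturating_drug_silences_pct_only(self, phys, healthy, dapa):
        geom = build_geometry(phys, healthy, dapa)
        # exposure far above Ki2 yet well below where SGLT1 (Ki1 1333x
        # weaker) would also shut down
        prof = steady_state_profile(mgdl_to_mM(250), geom, 6.5, c_plasma_drug=3e5)
        assert prof.sglt2_rate < 0.1
        assert prof.sglt1_rate > 6.0   # PST still operating

    def test_luminal_drug_rises_monotonically(self, phys, healthy, dapa):
        geom = build_geometry(phys, healthy, dapa)
        prof = steady_state_profile(mgdl_to_mM(100), geom, 6.5, c_plasma_drug=400.0)
        assert np.all(np.diff(prof.drug_concentrations) > 0)

    @pytest.mark.parametrize("param,direction", [
        ("vmax1", +1), ("vmax2", +1), ("km1", -1), ("km2", -1),
    ])
    def test_total_reabsorption_monotone_in_kinetics(self, phys, healthy,
                                                     param, direction):
        from dataclasses import replace

        base = steady_state_profile(mgdl_to_mM(250), build_geometry(phys, healthy),
                                    6.5).total_reabsorption_rate
        bumped = replace(healthy, **{param: getattr(healthy, param) * 1.2})
        new = steady_state_profile(mgdl_to_mM(250), build_geometry(phys, bumped),
                                   6.5).total_reabsorption_rate
        assert direction * (new - base) > 0

    def test_reabsorption_decreases_with_drug(self, phys, healthy, dapa):
        geom = build_geometry(phys, healthy, dapa)
        totals = [steady_state_profile(mgdl_to_mM(250), geom, 6.5, cd).total_reabsorption_rate
                  for cd in (0.0, 10.0, 100.0, 1000.0)]
        assert np.all(np.diff(totals) < 0)

    def test_threshold_and_splay(self, healthy_geom, healthy):
        # below the renal threshold UGE is negligible ...
        low = steady_state_profile(mgdl_to_mM(80), healthy_geom, 6.5)
        assert low.uge_rate < 0.01
        # ... far above it, UGE approaches filtered minus total capacity
        high = steady_state_profile(mgdl_to_mM(1500), healthy_geom, 6.5)
        asymptote = high.filtered_rate - healthy.vmax1 - healthy.vmax2
        assert high.uge_rate == pytest.approx(asymptote, rel=0.02)


class TestSimulate:
    def test_steady_run_matches_oracle(self, healthy_geom):
        forcing = Forcing.constant(mgdl_to_mM(250), 6.5, 0.6)
        res = simulate(healthy_geom, forcing, np.linspace(0, 12, 25),
                       initial="zeros")
        prof = steady_state_profile(mgdl_to_mM(250), healthy_geom, 6.5)
        np.testing.assert_allclose(res.glucose_concentrations[-1],
                                   prof.glucose_concentrations, rtol=1e-3)

    def test_mass_balance_and_nonnegativity(self, healthy_geom):
        forcing = Forcing.constant(mgdl_to_mM(400), 6.5, 0.6)
        res = simulate(healthy_geom, forcing, np.linspace(0, 8, 17))
        assert res.mass_balance_error() < 1e-6
        assert res.glucose_amounts.min() >= -1e-9

    def test_no_reabsorption_conserves_filtered_mass(self, phys):
        trans = transporter_params("healthy").scale_vmax(sglt1=0.0, sglt2=0.0)
        geom = build_geometry(phys, trans)
        forcing = Forcing.constant(mgdl_to_mM(100), 6.5, 0.6)
        res = simulate(geom, forcing, np.linspace(0, 24, 49), initial="zeros")
        filtered = res.filtered_glucose_cum[-1]
        in_system = (res.glucose_amounts[-1].sum() + res.bladder_glucose[-1]
                     + res.urine_glucose_cum[-1])
        assert in_system == pytest.approx(filtered, rel=1e-8)
        assert res.reabsorbed_glucose_cum[-1] == 0.0

    def test_near_complete_reabsorption_at_normoglycemia(self, healthy_geom):
        forcing = Forcing.constant(5.551, 6.5, 0.6)
        res = simulate(healthy_geom, forcing, np.linspace(0, 24, 49))
        daily_uge_g = convert_units(res.urine_glucose_cum[-1], "mmol", "g")
        assert daily_uge_g < 0.5

    def test_drug_mass_balance(self, healthy_drug_geom):
        forcing = Forcing.constant(mgdl_to_mM(250), 6.5, 0.6, plasma_drug_nM=400.0)
        res = simulate(healthy_drug_geom, forcing, np.linspace(0, 8, 17),
                       initial="zeros")
        assert res.drug_mass_balance_error() < 1e-6

    def test_invalid_grid_rejected(self, healthy_geom):
        forcing = Forcing.constant(5.0, 6.5, 0.6)
        with pytest.raises(ValueError):
            simulate(healthy_geom, forcing, [0.0, 0.0, 1.0])


class TestUnits:
    @pytest.mark.parametrize("value,src,dst,mw,expected", [
        (100.0, "mg/dL", "mM", None, 5.551),
        (1.0, "mmol", "g", None, 0.18016),
        (409.0, "ng/mL", "nM", 409.0, 1000.0),
        (5.551, "mM", "mg/dL", None, 100.0),
    ])
    def test_conversions(self, value, src, dst, mw, expected):
        assert convert_units(value, src, dst, mw=mw) == pytest.approx(expected, abs=0.01)

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            convert_units(1.0, "mg/dL", "furlongs")

    @given(st.floats(0.1, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip(self, value):
        back = convert_units(convert_units(value, "mg/dL", "mM"), "mM", "mg/dL")
        assert back == pytest.approx(value, rel=1e-12)
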
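"""Photon/ATP/NADPH bookkeeping and the light-harvesting cap."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import c4cell as c
from c4cell.biochem import ReactionCurrents
from c4cell.solver import SolverOptions


class TestEnergyBudget:
    @pytest.mark.parametrize(
        "J,photons,cyclic_frac",
        [
            (ReactionCurrents(1, 0, 0), 8.0, 0.0),      # pure Calvin: all linear
            (ReactionCurrents(0, 1, 0), 9.0, 0.2),      # oxygenation: 8 linear + 1 cyclic
            (ReactionCurrents(1, 0, 1), 12.0, 0.5),     # pump ATP met by cyclic flow
        ],
    )
    def test_reference_stoichiometries(self, params, J, photons, cyclic_frac):
        b = c.energy_budget(J, params)
        assert b.total_photons == pytest.approx(photons, rel=1e-12)
        assert b.cyclic_psi_fraction == pytest.approx(cyclic_frac, rel=1e-12)

    @given(
        jc=st.floats(0, 100), jp=st.floats(0, 100), j4=st.floats(0, 100),
    )
    def test_photon_total_is_the_stoichiometric_bill(self, params, jc, jp, j4):
        J = ReactionCurrents(jc, jp, j4)
        b = c.energy_budget(J, params)
        assert b.total_photons == pytest.approx(8 * jc + 9 * jp + 4 * j4, rel=1e-9, abs=1e-9)
        assert 0.0 <= b.cyclic_psi_fraction <= 1.0

    def test_cyclic_atp_is_cheaper_than_linear(self, params):
        # 0.5 ATP per cyclic photon vs 0.375 per linear photon at 4 H+/ATP
        pure_pump = c.energy_budget(ReactionCurrents(0, 0, 1), params)
        assert pure_pump.atp_per_photon == pytest.approx(0.5, rel=1e-12)
        pure_calvin = c.energy_budget(ReactionCurrents(1, 0, 0), params)
        assert pure_calvin.atp_per_photon == pytest.approx(0.375, rel=1e-12)

    def test_alternative_synthase_stoichiometry_preserves_efficacy(self, params):
        """With 14 H+ per 3 ATP the *relative* C4-vs-C3 photon cost is
        nearly unchanged (< 10% shift), even though the absolute photon
        bill and the cyclic share both move."""
        p14 = params.replace(atp_h_ratio=14 / 3)
        J_c4 = ReactionCurrents(16.2, 10.9, 5.0)
        J_c3 = ReactionCurrents(16.2, 10.9, 0.0)
        ratio12 = (c.energy_budget(J_c4, params).total_photons
                   / c.energy_budget(J_c3, params).total_photons)
        ratio14 = (c.energy_budget(J_c4, p14).total_photons
                   / c.energy_budget(J_c3, p14).total_photons)
        assert abs(ratio14 / ratio12 - 1) < 0.10
        # the absolute bill rises with the costlier synthase
        assert c.energy_budget(J_c4, p14).total_photons > c.energy_budget(J_c4, params).total_photons

    def test_negative_currents_rejected(self, params):
        with pytest.raises(ValueError):
            c.energy_budget(ReactionCurrents(-1.0, 0, 0), params)


class TestPhotonCost:
    def test_reference_points(self, params):
        assert c.photon_cost(ReactionCurrents(1, 0, 0), params) == pytest.approx(8.0)
        assert c.photon_cost(ReactionCurrents(1, 0.2, 0), params) == pytest.approx(9.8 / 0.9)
        assert math.isnan(c.photon_cost(ReactionCurrents(1, 2, 0), params))

    @given(jc=st.floats(1e-3, 100), jp=st.floats(0, 100), j4=st.floats(0, 100))
    def test_cost_never_below_the_calvin_floor(self, params, jc, jp, j4):
        cost = c.photon_cost(ReactionCurrents(jc, jp, j4), params)
        if not math.isnan(cost):
            assert cost >= 8.0 - 1e-9


class TestAreaAndDensityMeasures:
    def test_assimilation_per_area(self, geometry):
        assert c.assimilation_per_area(ReactionCurrents(), geometry) == 0.0
        J = ReactionCurrents(10.0, 4.0, 0.0)
        assert c.assimilation_per_area(J, geometry) == pytest.approx(8.0 / geometry.A_cell)

    def test_assimilation_consistent_with_boundary_influx(self, c3_state):
        a = c.assimilation_per_area(c3_state.currents, c3_state.mesh.geometry)
        influx = c.boundary_flux(c3_state, "CO2") / c3_state.mesh.geometry.A_cell
        assert a == pytest.approx(influx, rel=1e-2)

    def test_halving_coverage_halves_area_rate(self, params, geometry):
        g2 = c.build_geometry(params.replace(phi_cov=0.25))
        J = ReactionCurrents(10.0, 0.0, 0.0)
        assert c.assimilation_per_area(J, g2) == pytest.approx(
            0.5 * c.assimilation_per_area(J, geometry), rel=1e-9)

    def test_light_use_density(self, params, geometry, c3_state):
        assert c.light_use_density(ReactionCurrents(), geometry, params) == 0.0
        use = c.light_use_density(c3_state.currents, geometry, params)
        # the C3 calibration point: default-geometry C3 photosynthesis at
        # sigma_p >= 600 um/s needs over 30 mol m^-3 s^-1 of photons
        assert use > 30.0


class TestLightCap:
    def test_unconstrained_when_capacity_is_ample(self, params, mesh_coarse):
        p = params.replace(LHC=200.0)
        state, summary = c.apply_light_cap(p, SolverOptions(), mesh=mesh_coarse)
        assert summary.cap_scale == 1.0

    def test_cap_binds_exactly_at_saturating_pump(self, params, mesh_coarse):
        c_p = c.pepc_for_capacity_ratio(params, mesh_coarse.geometry, 10.0)
        p = params.replace(c_P=c_p, LHC=40.0)
        state, summary = c.apply_light_cap(p, SolverOptions(), mesh=mesh_coarse)
        assert 0.0 < summary.cap_scale < 1.0
        assert abs(summary.light_use - 40.0) / 40.0 < 1e-4
        # energy balance under the cap: photons used = LHC * V_stroma
        budget = c.energy_budget(state.currents, p)
        assert budget.total_photons == pytest.approx(
            40.0 * mesh_coarse.geometry.V_plas, rel=2e-4)
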
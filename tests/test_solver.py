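"""Steady-state solver: analytic fixtures, closures, error behaviour."""

import numpy as np
import pytest

import c4cell as c
from c4cell.solver import SolverError, SolverOptions


SLAB_CASES = [
    # (name, n_left, n_right, layers, sigmas, sigma_left, sigma_right)
    ("single_layer", 1.0, 0.0, [(2.0, 900.0)], [], None, None),
    ("two_layer_membrane", 1.0, 0.0, [(1.0, 900.0), (1.5, 180.0)], [600.0], None, None),
    ("three_layer_end_membrane", 1.0, 0.2,
     [(0.5, 1800.0), (1.0, 900.0), (1.5, 180.0)], [600.0, 1200.0], 200.0, None),
]


@pytest.mark.parametrize("name,nl,nr,layers,sigmas,sl,sr", SLAB_CASES, ids=[x[0] for x in SLAB_CASES])
def test_slab_fv_matches_series_resistance_closed_form(name, nl, nr, layers, sigmas, sl, sr):
    """1D steady diffusion through membranes is exactly a resistor chain."""
    j_exact = c.slab_flux_analytic(nl, nr, layers, sigmas, sl, sr)
    j_fv, z, n = c.solve_slab(nl, nr, layers, sigmas, sl, sr)
    assert j_fv == pytest.approx(j_exact, rel=1e-10)
    # concentrations decrease monotonically along the flux
    assert np.all(np.diff(n) <= 1e-12)


def test_slab_requires_matching_membrane_count():
    with pytest.raises(ValueError):
        c.slab_flux_analytic(1, 0, [(1.0, 100.0), (1.0, 100.0)], [])


class TestHenryEquilibrium:
    def test_null_solution_without_enzymes(self, params, mesh_coarse):
        """No reactions, no sources, bicarbonate-tight membranes: the exact
        uniform Henry equilibrium with zero boundary fluxes."""
        p = params.replace(sigma_pB=0.0, sigma_vB=0.0)
        st = c.solve_steady_state(p, SolverOptions(), mesh=mesh_coarse, enzyme_scale=0.0)
        n_C_eq = params.H_C * params.p_CO2
        n_O_eq = params.H_O * params.p_O2
        assert np.allclose(st.fields[0], n_C_eq, rtol=1e-9)
        assert np.allclose(st.fields[1], n_O_eq, rtol=1e-9)
        supply = params.sigma_c * mesh_coarse.geometry.A_cell * n_C_eq
        assert abs(st.boundary_fluxes["CO2"]) < 1e-6 * supply
        assert abs(st.boundary_fluxes["O2"]) < 1e-6 * supply
        res = c.conservation_residuals(st)
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in res.values())


class TestConvergedState:
    def test_fields_nonnegative_and_residuals_small(self, c3_state):
        assert c3_state.converged
        assert c3_state.fields.min() >= -1e-15
        assert c3_state.residuals["CO2"] < 1e-6
        assert c3_state.residuals["O2"] < 1e-6

    def test_carbon_and_oxygen_closure(self, c3_state):
        J = c3_state.currents
        influx = c.boundary_flux(c3_state, "CO2")
        assert influx == pytest.approx(J.J_Calvin - 0.5 * J.J_phresp, rel=1e-2)
        assert -c.boundary_flux(c3_state, "O2") == pytest.approx(J.J_Calvin, rel=1e-2)
        assert c.boundary_flux(c3_state, "HCO3") == 0.0

    def test_bicarbonate_closure_with_pump(self, c4_state):
        res = c.conservation_residuals(c4_state)
        assert res["bicarbonate"] < 1e-2
        assert res["carbon"] < 1e-2
        assert res["oxygen"] < 1e-2

    def test_bicarbonate_leak_is_negligible(self, params, mesh_coarse):
        """Setting the nm/s bicarbonate permeabilities to exactly zero
        changes assimilation by far less than 0.1%."""
        c_p = c.pepc_for_capacity_ratio(params, mesh_coarse.geometry, 1.0)
        leaky = c.solve_steady_state(params.replace(c_P=c_p), SolverOptions(), mesh=mesh_coarse)
        tight = c.solve_steady_state(
            params.replace(c_P=c_p, sigma_pB=0.0, sigma_vB=0.0),
            SolverOptions(), mesh=mesh_coarse)
        a1 = c.net_assimilation(leaky.currents)
        a2 = c.net_assimilation(tight.currents)
        assert abs(a1 - a2) / abs(a1) < 1e-3

    def test_cytosolic_bicarbonate_stays_near_equilibrium(self, c3_state, params):
        """Pure C3: HCO3- shifts from local equilibrium stay below 0.2 mol/m3."""
        from c4cell.biochem import ca_rates
        from c4cell.geometry import CYTOSOL

        cb, bc = ca_rates(params.pH_cyt, params.eta_CA_cyt, params)
        cyt = c3_state.mesh.region == CYTOSOL
        eq = c3_state.fields[0][cyt] * cb / bc
        assert np.abs(c3_state.fields[2][cyt] - eq).max() < 0.2

    def test_warm_start_reaches_same_fixed_point(self, params, mesh_coarse, c3_state_coarse):
        st2 = c.solve_steady_state(params, SolverOptions(), mesh=mesh_coarse, initial=c3_state_coarse)
        assert st2.currents.J_Calvin == pytest.approx(c3_state_coarse.currents.J_Calvin, rel=1e-6)
        assert st2.iterations <= c3_state_coarse.iterations

    def test_zero_co2_supply_is_below_compensation(self, params, mesh_coarse):
        st = c.solve_steady_state(params.replace(p_CO2=0.0), SolverOptions(), mesh=mesh_coarse)
        assert st.currents.J_Calvin - 0.5 * st.currents.J_phresp < 0
        assert np.isnan(c.photon_cost(st.currents, params))


class TestErrors:
    def test_nonconvergence_raises_with_history(self, params, mesh_coarse):
        with pytest.raises(SolverError) as exc:
            c.solve_steady_state(
                params, SolverOptions(max_outer=2), mesh=mesh_coarse)
        assert len(exc.value.history) == 2
        assert exc.value.history[-1]["dJ"] > SolverOptions().outer_tol

    def test_options_validation(self):
        with pytest.raises(ValueError):
            SolverOptions(damping=0.0)
        with pytest.raises(ValueError):
            SolverOptions(outer_tol=-1.0)

    def test_oracle_rejects_large_meshes(self, params, mesh_default):
        with pytest.raises(SolverError, match="coarse"):
            c.oracle_solve(params, mesh=mesh_default)
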
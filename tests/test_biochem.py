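"""Interconversion kinetics, enzyme rate laws, sources and current integrals."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import c4cell as c
from c4cell.biochem import ReactionCurrents, region_chemistry
from c4cell.geometry import STROMA


class TestCaRates:
    def test_cytosolic_calibration_points(self, params):
        v_cb, _ = c.ca_rates(7.5, 1e6, params)
        assert v_cb == pytest.approx(3.9245e4, rel=1e-3)
        v_cb4, _ = c.ca_rates(7.5, 1e4, params)
        assert v_cb4 == pytest.approx(392.45, rel=1e-3)

    def test_base_rates_at_stromal_ph(self, params):
        v_cb, v_bc = c.ca_rates(8.0, 1.0, params)
        assert v_cb == pytest.approx(0.0441, rel=1e-3)
        assert v_bc == pytest.approx(9.40e-4, rel=1e-3)

    @given(pH=st.floats(4.0, 10.0), eta=st.floats(1.0, 1e8))
    def test_detailed_balance_equilibrium_independent_of_activity(self, params, pH, eta):
        """CA accelerates both directions equally: the equilibrium ratio is pH-only."""
        cb1, bc1 = c.ca_rates(pH, 1.0, params)
        cb2, bc2 = c.ca_rates(pH, eta, params)
        assert cb2 / bc2 == pytest.approx(cb1 / bc1, rel=1e-12)
        assert cb2 == pytest.approx(eta * cb1, rel=1e-12)


class TestRateLaws:
    def test_rubisco_saturation_and_half_saturation(self, params):
        carb, _ = c.rubisco_rates(1e6, 0.0, params.c_R, params)
        assert carb == pytest.approx(params.v_C * params.c_R, rel=1e-4)  # 15.2
        carb_half, _ = c.rubisco_rates(params.K_C, 0.0, params.c_R, params)
        assert carb_half == pytest.approx(params.v_C * params.c_R / 2, rel=1e-12)

    def test_rubisco_at_airspace_equilibrium(self, params):
        n_C = params.H_C * params.p_CO2
        n_O = params.H_O * params.p_O2
        carb, oxy = c.rubisco_rates(n_C, n_O, params.c_R, params)
        assert carb == pytest.approx(4.77, rel=5e-3)
        assert oxy == pytest.approx(1.23, rel=5e-3)

    def test_degenerate_origin(self, params):
        carb, oxy = c.rubisco_rates(0.0, 0.0, params.c_R, params)
        assert carb == 0.0 and oxy == 0.0

    @given(
        n_C=st.floats(1e-9, 10.0), n_O=st.floats(1e-9, 10.0),
        m=st.floats(1.01, 100.0),
    )
    def test_rubisco_selectivity_and_monotonicity(self, params, n_C, n_O, m):
        carb, oxy = c.rubisco_rates(n_C, n_O, params.c_R, params)
        # carboxylation/oxygenation ratio is the specificity times n_C/n_O
        spec = (params.v_C / params.K_C) / (params.v_O / params.K_O)
        assert carb / oxy == pytest.approx(spec * n_C / n_O, rel=1e-9)
        carb_up, _ = c.rubisco_rates(m * n_C, n_O, params.c_R, params)
        _, oxy_up = c.rubisco_rates(m * n_C, n_O, params.c_R, params)
        assert carb_up >= carb
        assert oxy_up <= oxy

    def test_pepc_examples(self, params):
        assert c.pepc_rate(params.K_B, 0.1, params) == pytest.approx(150 * 0.1 / 2)
        assert c.pepc_rate(0.2, 0.1, params) == pytest.approx(10.0, rel=1e-12)
        assert c.pepc_rate(0.5, 0.0, params) == 0.0


class TestMeshTerms:
    def test_reaction_terms_vanish_at_equilibrium_without_enzymes(self, params, mesh_coarse):
        chem = region_chemistry(mesh_coarse, params, enzyme_scale=0.0)
        n_C = np.full(mesh_coarse.n_cells, 9.625e-3)
        n_B = n_C * chem.v_cb / np.maximum(chem.v_bc, 1e-300)
        n_O = np.full(mesh_coarse.n_cells, 0.2856)
        r_C, r_O, r_B = c.reaction_terms((n_C, n_O, n_B), mesh_coarse, chem)
        assert np.allclose(r_C, 0.0, atol=1e-12)
        assert np.allclose(r_O, 0.0)
        assert np.allclose(r_B, 0.0, atol=1e-12)

    def test_interconversion_conserves_inorganic_carbon(self, params, mesh_coarse):
        chem = region_chemistry(mesh_coarse, params, enzyme_scale=0.0)
        rng_fields = (
            np.linspace(0.001, 0.02, mesh_coarse.n_cells),
            np.full(mesh_coarse.n_cells, 0.2856),
            np.linspace(0.3, 0.05, mesh_coarse.n_cells),
        )
        r_C, _, r_B = c.reaction_terms(rng_fields, mesh_coarse, chem)
        assert np.allclose(r_C + r_B, 0.0, atol=1e-12)

    def test_source_normalisation(self, mesh_coarse):
        J = ReactionCurrents(J_Calvin=3.0, J_phresp=1.0, J_C4=2.0)
        s_C, s_O = c.source_terms(J, mesh_coarse)
        V = mesh_coarse.volume
        assert float(s_C @ V) == pytest.approx(J.J_C4 + 0.5 * J.J_phresp, rel=1e-12)
        assert float(s_O @ V) == pytest.approx(J.J_Calvin + J.J_phresp, rel=1e-12)
        zero = c.source_terms(ReactionCurrents(), mesh_coarse)
        assert np.all(zero[0] == 0.0) and np.all(zero[1] == 0.0)

    def test_saturating_stroma_current_equals_rate_times_volume(self, params, mesh_coarse):
        chem = region_chemistry(mesh_coarse, params)
        fields = (
            np.full(mesh_coarse.n_cells, 1e6),
            np.zeros(mesh_coarse.n_cells),
            np.zeros(mesh_coarse.n_cells),
        )
        J = c.currents_from_fields(fields, mesh_coarse, chem)
        V_plas = float(mesh_coarse.w[:, STROMA] @ mesh_coarse.volume)
        assert J.J_Calvin == pytest.approx(params.v_C * params.c_R * V_plas, rel=1e-4)
        assert J.J_phresp == 0.0
        zeroJ = c.currents_from_fields(
            tuple(np.zeros(mesh_coarse.n_cells) for _ in range(3)), mesh_coarse, chem)
        assert (zeroJ.J_Calvin, zeroJ.J_phresp, zeroJ.J_C4) == (0.0, 0.0, 0.0)

    def test_current_integral_against_fine_quadrature(self, params, geometry, mesh_coarse):
        """Mesh-weighted current integral vs midpoint quadrature of a smooth field."""
        a, b = 0.004, 0.002

        def n_C_of(r, z):
            return a + b * np.sin(z) * np.cos(r)

        chem = region_chemistry(mesh_coarse, params)
        fields = (
            n_C_of(mesh_coarse.cr, mesh_coarse.cz),
            np.zeros(mesh_coarse.n_cells),
            np.zeros(mesh_coarse.n_cells),
        )
        J = c.currents_from_fields(fields, mesh_coarse, chem)

        nrq, nzq = 900, 1600
        r = (np.arange(nrq) + 0.5) * geometry.R_cyl / nrq
        z = (np.arange(nzq) + 0.5) * geometry.z_bot / nzq
        lab = geometry.classify(r[:, None], z[None, :])
        dens = params.v_C * params.c_R * n_C_of(r[:, None], z[None, :])
        dens = dens / (n_C_of(r[:, None], z[None, :]) + params.K_C)
        w = 2 * np.pi * r[:, None] * (geometry.R_cyl / nrq) * (geometry.z_bot / nzq)
        expected = float(((lab == STROMA) * dens * w).sum())
        assert J.J_Calvin == pytest.approx(expected, rel=1e-2)
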
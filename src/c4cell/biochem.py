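"""Reaction, source and current terms of the cell model.

Three processes act on the dissolved species:

* reversible CO2 <-> HCO3- interconversion in every aqueous region, at
  pH-dependent base rates multiplied by the carbonic-anhydrase activity
  factor of the region (stroma and cytosol carry CA, the vacuole runs at
  base rates).  Because both directions scale with the same factor the
  equilibrium ratio n_B/n_C is set by pH alone (detailed balance);
* competitive RubisCO carboxylation/oxygenation of CO2 and O2 in the
  stroma, Michaelis-Menten with mutual competitive inhibition;
* PEPC carboxylation of HCO3- in the cytosol, plain Michaelis-Menten.

The three reaction currents are volume integrals of those densities; the
steady-state source terms redistribute them: the C4 current is released as
CO2 uniformly over the stroma, half an oxygenation current returns as
photorespired CO2 uniformly over the cytosol (mitochondria are spatially
averaged there), and photosystem-II O2 production, set by NADPH demand,
is released uniformly over the stroma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CYTOSOL, STROMA, VACUOLE, Mesh
from .params import ModelParams

__all__ = [
    "RegionChemistry",
    "ReactionCurrents",
    "ca_rates",
    "rubisco_rates",
    "pepc_rate",
    "region_chemistry",
    "reaction_terms",
    "source_terms",
    "currents_from_fields",
]


@dataclass(frozen=True)
class ReactionCurrents:
    """Reaction currents over the simulated cylinder, in 1e-18 mol/s."""

    J_Calvin: float = 0.0
    J_phresp: float = 0.0
    J_C4: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.J_Calvin, self.J_phresp, self.J_C4])

    @classmethod
    def from_array(cls, a) -> "ReactionCurrents":
        return cls(float(a[0]), float(a[1]), float(a[2]))


def ca_rates(pH: float, eta_CA: float, params: ModelParams) -> tuple[float, float]:
    """First-order interconversion rates (v_C->B, v_B->C) in 1/s.

    Base hydration combines the direct reaction with the hydroxide pathway,
    whose composite constant (in M/s) is divided by the proton concentration
    10^-pH M; base dehydration combines the proton pathway with spontaneous
    decomposition.  Both are multiplied by the CA activity factor.
    """
    h_conc = 10.0 ** (-pH)  # mol/L
    v_cb = eta_CA * (params.k_CO2 + params.k_OHKw / h_conc)
    v_bc = eta_CA * (params.k_d * h_conc + params.k_HCO3)
    return float(v_cb), float(v_bc)


@dataclass(frozen=True)
class RegionChemistry:
    """Per-cell chemistry coefficients on a mesh.

    ``v_cb``/``v_bc`` are the interconversion rates of each cell's region
    (by cell-centre membership), scaled by the cell's live volume fraction;
    keeping a single region's rate per cell preserves the exact uniform
    CO2/HCO3- equilibrium within each region for the enzyme-free limit.
    ``c_R_eff``/``c_P_eff`` are the substrate-primed enzyme concentrations
    after any light-cap scaling.
    """

    v_cb: np.ndarray
    v_bc: np.ndarray
    c_R_eff: float
    c_P_eff: float
    params: ModelParams


def region_chemistry(mesh: Mesh, params: ModelParams, enzyme_scale: float = 1.0) -> RegionChemistry:
    """Precompute per-cell interconversion rates and primed-enzyme levels."""
    rates = {reg: ca_rates(params.pH(name), params.eta_CA(name), params)
             for reg, name in ((STROMA, "stroma"), (CYTOSOL, "cytosol"), (VACUOLE, "vacuole"))}
    live_frac = mesh.w.sum(axis=1)
    v_cb = np.array([rates[r][0] for r in mesh.region]) * live_frac
    v_bc = np.array([rates[r][1] for r in mesh.region]) * live_frac
    return RegionChemistry(
        v_cb=v_cb, v_bc=v_bc,
        c_R_eff=enzyme_scale * params.c_R,
        c_P_eff=enzyme_scale * params.c_P,
        params=params,
    )


def rubisco_rates(n_C, n_O, c_R_eff: float, params: ModelParams):
    """Competitive RubisCO carboxylation and oxygenation densities.

    Returns (carboxylation, oxygenation) in mol m^-3 s^-1; the degenerate
    point n_C = n_O = 0 evaluates to (0, 0).
    """
    n_C = np.asarray(n_C, dtype=float)
    n_O = np.asarray(n_O, dtype=float)
    den_c = n_C + n_O * params.K_C / params.K_O + params.K_C
    den_o = n_O + n_C * params.K_O / params.K_C + params.K_O
    carb = params.v_C * c_R_eff * n_C / den_c
    oxy = params.v_O * c_R_eff * n_O / den_o
    return carb, oxy


def pepc_rate(n_B, c_P_eff: float, params: ModelParams):
    """PEPC carboxylation density v_B c_P n_B / (n_B + K_B), mol m^-3 s^-1."""
    n_B = np.asarray(n_B, dtype=float)
    return params.v_B * c_P_eff * n_B / (n_B + params.K_B)


def reaction_terms(fields, mesh: Mesh, chem: RegionChemistry):
    """Pointwise reaction densities (r_C, r_O, r_B) in mol m^-3 s^-1.

    Sign convention: positive = consumption of the species.  Enzymatic
    sinks are weighted by the stroma (RubisCO) or cytosol (PEPC) volume
    fraction of each cell; interconversion uses the region-blended rates
    and cancels exactly between r_C and r_B (total inorganic carbon is
    conserved by conversion).
    """
    n_C, n_O, n_B = fields
    p = chem.params
    carb, oxy = rubisco_rates(n_C, n_O, chem.c_R_eff, p)
    w_p = mesh.w[:, STROMA]
    w_c = mesh.w[:, CYTOSOL]
    conv = chem.v_cb * n_C - chem.v_bc * n_B
    r_C = w_p * carb + conv
    r_O = w_p * oxy
    r_B = w_c * pepc_rate(n_B, chem.c_P_eff, p) - conv
    return r_C, r_O, r_B


def source_terms(currents: ReactionCurrents, mesh: Mesh):
    """Per-cell source densities (s_C, s_O) in mol m^-3 s^-1.

    C4-released CO2 is uniform over the stroma at J_C4/V_p, photorespired
    CO2 uniform over the cytosol at (J_phresp/2)/V_c, and O2 production
    uniform over the stroma at (J_Calvin + J_phresp)/V_p.  HCO3- has no
    source.  Integrated against the cell volumes these recover the currents
    exactly.
    """
    w_p = mesh.w[:, STROMA]
    w_c = mesh.w[:, CYTOSOL]
    V_p = float(w_p @ mesh.volume)
    V_c = float(w_c @ mesh.volume)
    s_C = w_p * (currents.J_C4 / V_p) + w_c * (0.5 * currents.J_phresp / V_c)
    s_O = w_p * ((currents.J_Calvin + currents.J_phresp) / V_p)
    return s_C, s_O


def currents_from_fields(fields, mesh: Mesh, chem: RegionChemistry) -> ReactionCurrents:
    """Volume integrals of the three enzymatic densities (1e-18 mol/s)."""
    n_C, n_O, n_B = fields
    carb, oxy = rubisco_rates(n_C, n_O, chem.c_R_eff, chem.params)
    pep = pepc_rate(n_B, chem.c_P_eff, chem.params)
    w_pV = mesh.w[:, STROMA] * mesh.volume
    w_cV = mesh.w[:, CYTOSOL] * mesh.volume
    return ReactionCurrents(
        J_Calvin=float(w_pV @ carb),
        J_phresp=float(w_pV @ oxy),
        J_C4=float(w_cV @ pep),
    )
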
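"""Photon, ATP and NADPH accounting, efficiency measures, and the light cap.

Stoichiometry (per reaction event): fixing one CO2 costs 3 ATP + 2 NADPH,
resolving one RuBP oxygenation 3.5 ATP + 2 NADPH, and moving one carbon
through the C4 cycle 2 ATP and no reductant.  Linear electron transfer
yields one NADPH and 6 lumenal protons per 4 photons; with ``h`` protons
per ATP (default 4, i.e. the 12:3 synthase ratio) that is ``6/h`` ATP per
NADPH.  ATP demand beyond that margin is met by cyclic electron transfer
around PS-I at 2 protons (``2/h`` ATP) per photon.  At the default
stoichiometry the photon bill collapses to the familiar 8 photons per
carboxylation, 9 per oxygenation and 4 per C4 transfer.

Net assimilation is ``J_Calvin - J_phresp/2`` (half a CO2 is re-released in
the cytosol per oxygenation), which at steady state equals the CO2 influx
from the airspace.  Light use is expressed per stromal volume, the natural
proxy for thylakoid activity; a finite light-harvesting capacity is
enforced by scaling both primed-enzyme pools down by a common factor until
photon consumption matches the capacity exactly (the two cycles draw on
ATP without coordination, so their capacity ratio is held fixed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .biochem import ReactionCurrents
from .geometry import CellGeometry, Mesh
from .params import UNLIMITED, ModelParams
from .solver import SolverOptions, SteadyState, solve_steady_state

__all__ = [
    "EnergyBudget",
    "SolutionSummary",
    "energy_budget",
    "photon_cost",
    "net_assimilation",
    "assimilation_per_area",
    "light_use_density",
    "apply_light_cap",
    "summarize",
]


@dataclass(frozen=True)
class EnergyBudget:
    """Energy demand of a current triple (rates in 1e-18 mol/s)."""

    nadph: float
    atp: float
    linear_photons: float
    cyclic_photons: float
    total_photons: float
    cyclic_psi_fraction: float   # share of PS-I electron current that is cyclic
    atp_per_photon: float


@dataclass(frozen=True)
class SolutionSummary:
    """Headline measures of one converged scenario."""

    assimilation: float          # umol m^-2 s^-1 per cell surface area
    photon_cost: float           # photons per net assimilated carbon (nan below compensation)
    photon_cost_defined: bool
    light_use: float             # mol m^-3 s^-1 per stromal volume
    cap_scale: float             # light-cap enzyme scaling factor f in (0, 1]
    cyclic_psi_fraction: float
    atp_per_carbon: float
    capacity_ratio: float


def energy_budget(currents: ReactionCurrents, params: ModelParams) -> EnergyBudget:
    """ATP/NADPH/photon demand of a reaction-current triple."""
    J_cal, J_ph, J_c4 = currents.J_Calvin, currents.J_phresp, currents.J_C4
    if min(J_cal, J_ph, J_c4) < -1e-12 * max(abs(J_cal), abs(J_ph), abs(J_c4), 1.0):
        raise ValueError("reaction currents must be non-negative")
    nadph = 2.0 * (J_cal + J_ph)
    atp = 3.0 * J_cal + 3.5 * J_ph + 2.0 * J_c4
    h = params.atp_h_ratio
    linear_photons = 4.0 * nadph
    surplus_atp = atp - (6.0 / h) * nadph
    if surplus_atp < -1e-9 * max(atp, 1.0):
        raise ValueError("negative cyclic-ATP residual; inconsistent stoichiometry")
    cyclic_photons = max(surplus_atp, 0.0) * (h / 2.0)
    total = linear_photons + cyclic_photons
    # PS-I electrons: 2 per NADPH through the linear chain, 1 per cyclic photon
    psi_linear = 2.0 * nadph
    psi_total = psi_linear + cyclic_photons
    return EnergyBudget(
        nadph=nadph, atp=atp, linear_photons=linear_photons,
        cyclic_photons=cyclic_photons, total_photons=total,
        cyclic_psi_fraction=cyclic_photons / psi_total if psi_total > 0 else 0.0,
        atp_per_photon=atp / total if total > 0 else 0.0,
    )


def net_assimilation(currents: ReactionCurrents) -> float:
    """Net carbon uptake J_Calvin - J_phresp/2, in 1e-18 mol/s."""
    return currents.J_Calvin - 0.5 * currents.J_phresp


def photon_cost(currents: ReactionCurrents, params: ModelParams) -> float:
    """Photons per net assimilated carbon; NaN below the compensation point."""
    budget = energy_budget(currents, params)
    net = net_assimilation(currents)
    if net <= 0.0:
        return math.nan
    return budget.total_photons / net


def assimilation_per_area(currents: ReactionCurrents, geometry: CellGeometry) -> float:
    """Net assimilation per cell surface area, umol m^-2 s^-1."""
    return net_assimilation(currents) / geometry.A_cell


def light_use_density(currents: ReactionCurrents, geometry: CellGeometry,
                      params: ModelParams) -> float:
    """Photon consumption per stromal volume, mol m^-3 s^-1."""
    return energy_budget(currents, params).total_photons / geometry.V_plas


def summarize(state: SteadyState, cap_scale: float = 1.0) -> SolutionSummary:
    """Collect the headline measures of a converged state."""
    from .params import capacity_ratio  # local import avoids a cycle at import time

    g = state.mesh.geometry
    budget = energy_budget(state.currents, state.params)
    net = net_assimilation(state.currents)
    cost = photon_cost(state.currents, state.params)
    return SolutionSummary(
        assimilation=net / g.A_cell,
        photon_cost=cost,
        photon_cost_defined=math.isfinite(cost),
        light_use=budget.total_photons / g.V_plas,
        cap_scale=cap_scale,
        cyclic_psi_fraction=budget.cyclic_psi_fraction,
        atp_per_carbon=budget.atp / net if net > 0 else math.nan,
        capacity_ratio=capacity_ratio(state.params, g),
    )


def apply_light_cap(
    params: ModelParams,
    options: SolverOptions | None = None,
    mesh: Mesh | None = None,
    cap_tol: float = 1e-4,
) -> tuple[SteadyState, SolutionSummary]:
    """Solve with the light-harvesting capacity enforced.

    If the unconstrained solution uses less light than the capacity the
    scale is 1 and the solution is returned unchanged.  Otherwise both
    primed-enzyme pools are scaled by a common factor ``f`` found by root
    bracketing so that light use per stromal volume matches the capacity to
    ``cap_tol`` relative.
    """
    options = options or SolverOptions()
    state = solve_steady_state(params, options, mesh=mesh)
    mesh = state.mesh
    if not params.lhc_limited:
        return state, summarize(state, cap_scale=1.0)
    lhc = float(params.LHC)
    use = light_use_density(state.currents, mesh.geometry, params)
    if use <= lhc * (1.0 + cap_tol):
        return state, summarize(state, cap_scale=1.0)

    warm = {"state": state}

    def excess(f: float) -> float:
        warm["state"] = solve_steady_state(
            params, options, mesh=mesh, enzyme_scale=f, initial=warm["state"]
        )
        return light_use_density(warm["state"].currents, mesh.geometry, params) - lhc

    # light use vanishes with the enzymes and is roughly proportional to
    # them, so bracket around the proportional guess and expand if needed
    f0 = lhc / use
    lo, hi = max(0.4 * f0, 1e-9), min(1.0, 2.5 * f0)
    e_lo, e_hi = excess(lo), excess(hi)
    while e_lo > 0 and lo > 1e-9:
        lo *= 0.3
        e_lo = excess(lo)
    while e_hi < 0 and hi < 1.0:
        hi = min(1.0, hi * 2.5)
        e_hi = excess(hi)
    if not e_lo <= 0 <= e_hi:
        raise RuntimeError(
            f"light use is not monotone across the enzyme-scale bracket "
            f"({lo:.3g}, {hi:.3g}); excess = ({e_lo:.3g}, {e_hi:.3g})"
        )
    # light use is near-proportional to f, so a relative tolerance a bit
    # tighter than cap_tol on f suffices for cap_tol on the light use
    f = brentq(excess, lo, hi, rtol=0.2 * cap_tol)
    state = warm["state"]
    use = light_use_density(state.currents, mesh.geometry, params)
    if abs(use - lhc) / lhc > cap_tol:
        state = solve_steady_state(params, options, mesh=mesh, enzyme_scale=f, initial=state)
        use = light_use_density(state.currents, mesh.geometry, params)
        if abs(use - lhc) / lhc > cap_tol:
            raise RuntimeError(
                f"light-cap iteration failed: light use {use:.6g} vs capacity {lhc:.6g}"
            )
    return state, summarize(state, cap_scale=f)
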
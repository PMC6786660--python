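"""Steady-state solver for the coupled reaction-diffusion system.

The three species obey ``D_i lap(n_i) - r_i(n) + s_i = 0`` on the meshed
cell with permeability jump conditions on membranes and a permeable wall
(sigma_c) against Henry-equilibrium airspace concentrations at z = 0.

The production path is a damped Picard iteration: the Michaelis-Menten
denominators and the globally coupled source currents are frozen, the
resulting *linear* diffusion-reaction systems are solved exactly (CO2 and
HCO3- together, since the interconversion coupling between them is stiff;
O2 separately), the reaction currents are recomputed from the new fields
and damped, and the cycle repeats until the current triple is stationary.
All linear solves are direct sparse LU factorisations; no randomness is
involved anywhere.

A deliberately independent verification path (:func:`oracle_solve`) solves
the same discrete problem by a dense finite-difference Newton iteration on
the full nonlinear residual -- no Picard splitting, no frozen denominators
-- and is used to cross-check the production path on coarse meshes.  A 1D
three-layer slab with a closed-form series-resistance flux provides an
analytic regression fixture for the conductance assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import biochem
from .biochem import ReactionCurrents, RegionChemistry
from .geometry import CYTOSOL, STROMA, Mesh, build_geometry, build_mesh
from .params import ModelParams, diffusion_coefficient

__all__ = [
    "SolverOptions",
    "SteadyState",
    "SolverError",
    "solve_steady_state",
    "boundary_flux",
    "conservation_residuals",
    "oracle_solve",
    "slab_flux_analytic",
    "solve_slab",
]

SPECIES = ("CO2", "O2", "HCO3")


class SolverError(RuntimeError):
    """Raised on non-convergence or a non-physical solution.

    Carries the outer-iteration history (list of per-iteration current
    triples and relative changes) in ``history`` when available.
    """

    def __init__(self, msg: str, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the steady-state solve.

    ``outer_tol`` is the relative stationarity tolerance on the current
    triple (and on the fields); ``damping`` multiplies the current update.
    ``linear_tol`` is kept for an iterative linear fallback; the default
    path factorises directly and solves to machine precision.
    """

    outer_tol: float = 1e-8
    linear_tol: float = 1e-12
    damping: float = 0.5
    max_outer: int = 400
    resolution: float = 8.0

    def __post_init__(self):
        if not (self.outer_tol > 0 and self.linear_tol > 0):
            raise ValueError("tolerances must be positive")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")


@dataclass
class SteadyState:
    """Converged fields, currents and diagnostics of one solve."""

    mesh: Mesh
    params: ModelParams
    fields: np.ndarray            # (3, n_cells): n_C, n_O, n_B in mol m^-3
    currents: ReactionCurrents
    chem: RegionChemistry
    boundary_fluxes: dict         # per species, 1e-18 mol/s, positive inward
    converged: bool
    iterations: int
    residuals: dict               # relative nonlinear residual per species
    history: list = field(default_factory=list)
    enzyme_scale: float = 1.0


# ---------------------------------------------------------------------------
# Transport operator assembly


def _sigma_for(params: ModelParams, species: str):
    """(envelope, tonoplast, wall) permeabilities for one species, um/s."""
    if species == "HCO3":
        return params.sigma_pB, params.sigma_vB, 0.0
    return params.sigma_p, params.sigma_tonoplast, params.sigma_c


def transport_system(mesh: Mesh, params: ModelParams):
    """Assemble per-species diffusion operators.

    Returns a dict species -> (L, b, g_b) where L is the positive
    semi-definite conductance operator (including the exterior-face
    conductance on its diagonal), b the exterior-concentration load vector
    and g_b the per-boundary-face conductances.  Conductance units are
    um^3/s, so that L @ n is a current in 1e-18 mol/s.
    """
    n = mesh.n_cells
    out = {}
    D_cell = np.empty(n)
    for species in SPECIES:
        D_by_region = np.array([
            diffusion_coefficient(species, "stroma", params),
            diffusion_coefficient(species, "cytosol", params),
            diffusion_coefficient(species, "vacuole", params),
        ])
        D_cell[:] = D_by_region[mesh.region]
        s_env, s_ton, s_wall = _sigma_for(params, species)

        A = mesh.conn_A
        R = mesh.conn_di / (A * D_cell[mesh.conn_i]) + mesh.conn_dj / (A * D_cell[mesh.conn_j])
        if s_env > 0:
            R = R + mesh.conn_env / (A * mesh.f_env * s_env)
        else:
            R = np.where(mesh.conn_env, np.inf, R)
        if s_ton > 0:
            R = R + mesh.conn_ton / (A * mesh.f_ton * s_ton)
        else:
            R = np.where(mesh.conn_ton, np.inf, R)
        g = np.where(np.isfinite(R), 1.0 / R, 0.0)

        i, j = mesh.conn_i, mesh.conn_j
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([i, j, j, i])
        data = np.concatenate([g, g, -g, -g])
        # exterior faces: series of the half-cell path and the wall membrane
        if s_wall > 0:
            Rb = mesh.bnd_d / (mesh.bnd_A * D_cell[mesh.bnd_cell]) + 1.0 / (mesh.bnd_A * s_wall)
            g_b = 1.0 / Rb
        else:
            g_b = np.zeros(mesh.bnd_cell.size)
        rows = np.concatenate([rows, mesh.bnd_cell])
        cols = np.concatenate([cols, mesh.bnd_cell])
        data = np.concatenate([data, g_b])
        L = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        n_ext = {
            "CO2": params.H_C * params.p_CO2,
            "O2": params.H_O * params.p_O2,
            "HCO3": 0.0,
        }[species]
        b = np.zeros(n)
        np.add.at(b, mesh.bnd_cell, g_b * n_ext)
        out[species] = (L, b, g_b)
    return out


def _initial_fields(mesh: Mesh, params: ModelParams, chem: RegionChemistry) -> np.ndarray:
    n_C0 = params.H_C * params.p_CO2
    n_O0 = params.H_O * params.p_O2
    live = np.maximum(mesh.w.sum(axis=1), 1e-300)
    n_B0 = n_C0 * chem.v_cb / np.maximum(chem.v_bc, 1e-300)
    # blended rates are scaled by the live fraction identically, so the
    # ratio is already the local equilibrium ratio; guard empty cells
    n_B0 = np.where(live > 0, n_B0, 0.0)
    return np.vstack([np.full(mesh.n_cells, n_C0), np.full(mesh.n_cells, n_O0), n_B0])


# ---------------------------------------------------------------------------
# Production path: damped Picard


def solve_steady_state(
    params: ModelParams,
    options: SolverOptions | None = None,
    mesh: Mesh | None = None,
    enzyme_scale: float = 1.0,
    initial: SteadyState | None = None,
) -> SteadyState:
    """Solve the coupled steady state on ``mesh`` (built if not given).

    ``enzyme_scale`` multiplies both primed-enzyme concentrations (the
    light-cap mechanism); ``initial`` warm-starts the outer iteration from
    a previous solution on the same mesh.
    """
    options = options or SolverOptions()
    if mesh is None:
        mesh = build_mesh(build_geometry(params), options.resolution)
    chem = biochem.region_chemistry(mesh, params, enzyme_scale)
    systems = transport_system(mesh, params)
    L_C, b_C, gb_C = systems["CO2"]
    L_O, b_O, gb_O = systems["O2"]
    L_B, b_B, gb_B = systems["HCO3"]
    V = mesh.volume
    w_p = mesh.w[:, STROMA]
    w_c = mesh.w[:, CYTOSOL]
    p = params

    if initial is not None and initial.fields.shape[1] == mesh.n_cells:
        fields = initial.fields.copy()
        J = initial.currents.as_array()
    else:
        fields = _initial_fields(mesh, p, chem)
        J = np.zeros(3)

    # stationarity is measured against the larger of the currents themselves
    # and the diffusive supply scale of the cell
    J_floor = max(gb_C.sum() * p.H_C * p.p_CO2, gb_O.sum() * p.H_O * p.p_O2, 1e-300)
    vcbV = chem.v_cb * V
    vbcV = chem.v_bc * V
    diag_conv_C = sp.diags(vcbV)
    diag_conv_B = sp.diags(vbcV)

    history = []
    converged = False
    it = 0
    # the configured damping is the safe floor; while the iteration
    # contracts monotonically the step is cautiously lengthened, and any
    # growth of the update resets it, which keeps the fixed-point robust
    # for stiff pump regimes without paying ~100 iterations everywhere
    beta = options.damping
    prev_dJ = np.inf
    streak = 0
    for it in range(1, options.max_outer + 1):
        n_C, n_O, n_B = fields
        den_C = n_C + n_O * p.K_C / p.K_O + p.K_C
        den_O = n_O + n_C * p.K_O / p.K_C + p.K_O
        den_B = n_B + p.K_B
        a_C = w_p * p.v_C * chem.c_R_eff / den_C * V
        a_O = w_p * p.v_O * chem.c_R_eff / den_O * V
        a_B = w_c * p.v_B * chem.c_P_eff / den_B * V
        s_C, s_O = biochem.source_terms(ReactionCurrents.from_array(J), mesh)

        M_O = (L_O + sp.diags(a_O)).tocsc()
        new_O = spla.spsolve(M_O, b_O + V * s_O)

        M = sp.bmat(
            [
                [L_C + sp.diags(a_C) + diag_conv_C, -diag_conv_B],
                [-diag_conv_C, L_B + sp.diags(a_B) + diag_conv_B],
            ],
            format="csc",
        )
        rhs = np.concatenate([b_C + V * s_C, b_B])
        sol = spla.spsolve(M, rhs)
        new_C, new_B = sol[: mesh.n_cells], sol[mesh.n_cells:]

        f_scale = np.maximum(np.abs(fields).max(axis=1), 1e-300)
        d_fields = max(
            np.abs(new_C - n_C).max() / f_scale[0],
            np.abs(new_O - n_O).max() / f_scale[1],
            np.abs(new_B - n_B).max() / f_scale[2],
        )
        fields = np.vstack([new_C, new_O, new_B])
        J_star = biochem.currents_from_fields(fields, mesh, chem).as_array()
        d_J = np.abs(J_star - J).max() / max(np.abs(J).max(), J_floor)
        if d_J < prev_dJ:
            streak += 1
            if streak >= 4:
                beta = min(1.0, beta * 1.4)
        else:
            beta = options.damping
            streak = 0
        prev_dJ = d_J
        J = J + beta * (J_star - J)
        history.append({"iter": it, "J": J.tolist(), "dJ": float(d_J),
                        "dfields": float(d_fields), "beta": float(beta)})
        if d_J < options.outer_tol and d_fields < options.outer_tol:
            converged = True
            break

    if not converged:
        raise SolverError(
            f"Picard iteration did not converge in {options.max_outer} outer iterations "
            f"(last dJ = {history[-1]['dJ']:.3e})",
            history=history,
        )
    fmin = fields.min()
    if fmin < -1e-12 * max(fields.max(), 1.0):
        raise SolverError(
            f"negative concentration {fmin:.3e} beyond round-off; the discretisation "
            "is too coarse for these parameters",
            history=history,
        )

    currents = biochem.currents_from_fields(fields, mesh, chem)
    bflux = {
        "CO2": float(gb_C @ (p.H_C * p.p_CO2 - fields[0][mesh.bnd_cell])),
        "O2": float(gb_O @ (p.H_O * p.p_O2 - fields[1][mesh.bnd_cell])),
        "HCO3": 0.0,
    }
    residuals = _nonlinear_residuals(fields, mesh, chem, systems, currents)
    return SteadyState(
        mesh=mesh, params=params, fields=fields, currents=currents, chem=chem,
        boundary_fluxes=bflux, converged=converged, iterations=it,
        residuals=residuals, history=history, enzyme_scale=enzyme_scale,
    )


def _nonlinear_residuals(fields, mesh, chem, systems, currents):
    """Relative residual of the full discrete nonlinear system per species."""
    r_C, r_O, r_B = biochem.reaction_terms(fields, mesh, chem)
    s_C, s_O = biochem.source_terms(currents, mesh)
    V = mesh.volume
    out = {}
    for species, r, s in (("CO2", r_C, s_C), ("O2", r_O, s_O), ("HCO3", r_B, 0.0)):
        L, b, _ = systems[species]
        res = L @ fields[SPECIES.index(species)] - b + V * r - V * (s if np.ndim(s) else 0.0)
        scale = max(np.abs(b).sum(), np.abs(V * r).sum(), 1e-300)
        out[species] = float(np.abs(res).sum() / scale)
    return out


def boundary_flux(state: SteadyState, species: str) -> float:
    """Signed net influx (positive into the cell) at the IAS face, 1e-18 mol/s."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    return state.boundary_fluxes[species]


def conservation_residuals(state: SteadyState) -> dict:
    """Steady-state closure checks.

    carbon:      IAS CO2 influx vs net assimilation J_Calvin - J_phresp/2
    oxygen:      IAS O2 efflux vs J_Calvin
    bicarbonate: net cytosolic CO2->HCO3- conversion vs J_C4
    Each is |a - b| / max(|a|, |b|), reported as 0 for the all-zero case.
    """
    J = state.currents
    p = state.params
    net_assim = J.J_Calvin - 0.5 * J.J_phresp
    influx_C = state.boundary_fluxes["CO2"]
    efflux_O = -state.boundary_fluxes["O2"]
    cyt = state.mesh.region == CYTOSOL
    V = state.mesh.volume
    net_conv = float(
        (V * (state.chem.v_cb * state.fields[0] - state.chem.v_bc * state.fields[2]))[cyt].sum()
    )

    current_scale = max(J.J_Calvin, J.J_phresp, J.J_C4, abs(influx_C))

    def rel(a, b):
        # floor the denominator at 1% of the dominant current so that
        # closures between two near-zero quantities report as satisfied;
        # discrepancies below solver noise relative to the diffusive
        # supply scale count as exactly closed
        scale = max(abs(a), abs(b), 0.01 * current_scale)
        return abs(a - b) / scale if scale > 1e-8 * _supply_scale(state) else 0.0

    return {
        "carbon": rel(influx_C, net_assim),
        "oxygen": rel(efflux_O, J.J_Calvin),
        "bicarbonate": rel(net_conv, J.J_C4),
    }


def _supply_scale(state: SteadyState) -> float:
    p = state.params
    A = state.mesh.geometry.A_cell
    return max(p.sigma_c * A * p.H_C * p.p_CO2, p.sigma_c * A * p.H_O * p.p_O2, 1e-300)


# ---------------------------------------------------------------------------
# Verification path: dense finite-difference Newton on the full residual


def oracle_solve(
    params: ModelParams,
    mesh: Mesh | None = None,
    resolution: float = 4.0,
    enzyme_scale: float = 1.0,
    tol: float = 1e-10,
    max_newton: int = 60,
) -> SteadyState:
    """Solve the same discrete problem without any Picard splitting.

    The full nonlinear residual (Michaelis-Menten terms, interconversion
    and the field-dependent source currents all evaluated at the iterate)
    is driven to zero by a Newton iteration with a dense forward-difference
    Jacobian, refreshed only when progress stalls.  Restricted to coarse
    meshes; raises on larger ones.
    """
    if mesh is None:
        mesh = build_mesh(build_geometry(params), resolution)
    n = mesh.n_cells
    if 3 * n > 6000:
        raise SolverError(f"oracle path is limited to coarse meshes (3N = {3 * n} > 6000)")
    chem = biochem.region_chemistry(mesh, params, enzyme_scale)
    systems = transport_system(mesh, params)
    V = mesh.volume
    mats = [systems[s][0] for s in SPECIES]
    loads = [systems[s][1] for s in SPECIES]

    def residual(x: np.ndarray) -> np.ndarray:
        f = x.reshape(3, n)
        r = biochem.reaction_terms(f, mesh, chem)
        J = biochem.currents_from_fields(f, mesh, chem)
        s_C, s_O = biochem.source_terms(J, mesh)
        srcs = (s_C, s_O, np.zeros(n))
        out = np.empty((3, n))
        for k in range(3):
            out[k] = mats[k] @ f[k] - loads[k] + V * r[k] - V * srcs[k]
        return out.ravel()

    x = _initial_fields(mesh, params, chem).ravel()
    scale = max(np.abs(loads[0]).sum(), np.abs(loads[1]).sum(), 1e-300)
    F = residual(x)
    lu = None
    last_norm = np.inf
    for _ in range(max_newton):
        norm = np.abs(F).sum() / scale
        if norm < tol:
            break
        if lu is None or norm > 0.5 * last_norm:
            jac = _fd_jacobian(residual, x, F)
            lu = _dense_lu(jac)
        last_norm = norm
        step = lu(F)
        t = 1.0
        x_new, F_new = x - step, None
        while t > 1e-4:
            x_new = x - t * step
            F_new = residual(x_new)
            if np.abs(F_new).sum() < np.abs(F).sum():
                break
            t *= 0.5
        x, F = x_new, F_new
    else:
        raise SolverError("oracle Newton iteration failed to converge")
    if np.abs(F).sum() / scale >= tol:
        raise SolverError("oracle Newton iteration failed to converge")

    fields = x.reshape(3, n)
    currents = biochem.currents_from_fields(fields, mesh, chem)
    p = params
    gb_C, gb_O = systems["CO2"][2], systems["O2"][2]
    bflux = {
        "CO2": float(gb_C @ (p.H_C * p.p_CO2 - fields[0][mesh.bnd_cell])),
        "O2": float(gb_O @ (p.H_O * p.p_O2 - fields[1][mesh.bnd_cell])),
        "HCO3": 0.0,
    }
    residuals = _nonlinear_residuals(fields, mesh, chem, systems, currents)
    return SteadyState(
        mesh=mesh, params=params, fields=fields, currents=currents, chem=chem,
        boundary_fluxes=bflux, converged=True, iterations=max_newton,
        residuals=residuals, history=[], enzyme_scale=enzyme_scale,
    )


def _fd_jacobian(fun, x, f0):
    m = x.size
    jac = np.empty((m, m))
    eps = np.sqrt(np.finfo(float).eps)
    for k in range(m):
        h = eps * max(abs(x[k]), 1e-6)
        xp = x.copy()
        xp[k] += h
        jac[:, k] = (fun(xp) - f0) / h
    return jac


def _dense_lu(jac):
    from scipy.linalg import lu_factor, lu_solve

    fac = lu_factor(jac)
    return lambda rhs: lu_solve(fac, rhs)


# ---------------------------------------------------------------------------
# Analytic 1D slab fixture


def slab_flux_analytic(n_left, n_right, layers, sigmas, sigma_left=None, sigma_right=None):
    """Closed-form steady flux through a stack of diffusive layers.

    ``layers`` is a sequence of (thickness um, diffusivity um^2/s);
    ``sigmas`` the permeabilities (um/s) of the membranes *between*
    consecutive layers; ``sigma_left``/``sigma_right`` optional end
    membranes toward the fixed exterior concentrations.  Returns the flux
    per unit area (positive left -> right) in mol m^-3 um / s.
    """
    if len(sigmas) != max(len(layers) - 1, 0):
        raise ValueError("need exactly one membrane permeability between consecutive layers")
    R = sum(L / D for L, D in layers) + sum(1.0 / s for s in sigmas)
    if sigma_left is not None:
        R += 1.0 / sigma_left
    if sigma_right is not None:
        R += 1.0 / sigma_right
    return (n_left - n_right) / R


def solve_slab(n_left, n_right, layers, sigmas, sigma_left=None, sigma_right=None,
               cells_per_layer: int = 20):
    """Finite-volume solve of the same slab; returns (flux, z, n).

    Uses the identical two-point series-resistance flux construction as the
    cell solver (half-cell diffusive paths plus a membrane permeability on
    interface faces) on a 1D chain, with Dirichlet exterior values.
    """
    zs, Ds = [], []
    z0 = 0.0
    for L, D in layers:
        dz = L / cells_per_layer
        for k in range(cells_per_layer):
            zs.append(z0 + (k + 0.5) * dz)
            Ds.append(D)
        z0 += L
    zs = np.array(zs)
    Ds = np.array(Ds)
    n = zs.size
    half = np.empty(n)
    for idx in range(n):
        layer = idx // cells_per_layer
        half[idx] = layers[layer][0] / (2 * cells_per_layer)

    g = np.empty(n - 1)
    for idx in range(n - 1):
        R = half[idx] / Ds[idx] + half[idx + 1] / Ds[idx + 1]
        if (idx + 1) % cells_per_layer == 0:
            R += 1.0 / sigmas[(idx + 1) // cells_per_layer - 1]
        g[idx] = 1.0 / R
    R_l = half[0] / Ds[0] + (1.0 / sigma_left if sigma_left is not None else 0.0)
    R_r = half[-1] / Ds[-1] + (1.0 / sigma_right if sigma_right is not None else 0.0)
    g_l, g_r = 1.0 / R_l, 1.0 / R_r

    main = np.zeros(n)
    main[:-1] += g
    main[1:] += g
    main[0] += g_l
    main[-1] += g_r
    A = sp.diags([-g, main, -g], offsets=(-1, 0, 1), format="csc")
    rhs = np.zeros(n)
    rhs[0] = g_l * n_left
    rhs[-1] = g_r * n_right
    sol = spla.spsolve(A, rhs)
    flux = g_l * (n_left - sol[0])
    return flux, zs, sol
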
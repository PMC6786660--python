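# Methods

## Model summary and assumptions

The package solves the coupled steady state of three dissolved species —
CO2, O2 and HCO3⁻ — in the axisymmetric "personal space" of one peripheral
chloroplast of a C3 mesophyll cell. The governing equations are
`D_i ∇²n_i − r_i(n) + s_i = 0` per species, with compartment-dependent
diffusivities (aqueous values divided by relative viscosities of 10, 2 and
1 in stroma, cytosol and vacuole), Fick jump conditions `j = σ(n₁ − n₂)`
across membranes, and a permeable wall against fixed Henry-equilibrium
airspace concentrations.

Key assumptions inherited from the biology:

* **Optimal downstream machinery.** Calvin–Benson, photorespiration and the
  C4 shuttle run at whatever rate their carboxylases set; intermediates
  (RuBP, PEP, C4 acids) are never limiting except through the light cap.
  Predictions are therefore best-case.
* **Spatially averaged mitochondria.** Photorespired CO2 (half a molecule
  per oxygenation) returns uniformly over the peripheral cytosol.
* **Fixed pH per compartment** (8.0 stroma, 7.5 cytosol, 5.5 vacuole):
  buffering capacity far exceeds the sub-0.2 mM bicarbonate shifts the
  solutions exhibit, which the solver verifies.
* **Energy accounting, not photosystem kinetics.** Photon demand is a
  stoichiometric ledger (3 ATP + 2 NADPH per carboxylation, 3.5 + 2 per
  oxygenation, 2 ATP per C4 transfer; 4 photons and 6 lumenal protons per
  NADPH through linear flow; 2 protons per cyclic photon; 4 protons per
  ATP). Cyclic and linear flow are assumed perfectly coordinated to demand.

## Geometry

The cylinder radius follows from the chloroplast surface-coverage fraction,
`R_cyl = r_P/√φ_cov`. The chloroplast is a hemisphere of radius `r_P` with
its flat face toward the plasmalemma, offset by a cytosol gap `d_sep` plus
the excluded membrane thickness `θ_mem`. The tonoplast follows the envelope
at offset `d_sep + θ_mem` over the cap that protrudes into the vacuole and
is planar elsewhere; the protrusion depth is `d_V = r_P/2`, which yields a
~0.8 µm peripheral cytosol layer and a volume-adjusted wall supply rate
`A σ_c / V_cyt ≈ 460 s⁻¹`, consistent with the regime the model is meant to
capture. The simulated vacuole extends `1.5 r_P` below the tonoplast cap;
lateral and bottom boundaries are symmetry planes. Membranes are zero-volume
interface conditions with their `θ_mem` shells geometrically excluded —
resolving them as low-diffusivity layers would change nothing but the
excluded volume while destroying the conditioning of the linear systems.

Feasibility bounds are enforced: the chloroplast plus its membrane offsets
must fit inside the cylinder (this caps the usable coverage near 89% at
default sizes) and `0 < d_V < r_P`.

## Discretisation

A tensor-product (r, z) finite-volume grid is graded from a coarse spacing
`1/resolution` down to `0.12/resolution` (0.015 µm at the default
resolution of 8 cells/µm) in bands around every membrane, so halving or
doubling the resolution refines the mesh uniformly for convergence studies.
Cells are classified by cell-centre membership (stroma / cytosol / vacuole /
excluded membrane shell); cells cut by an interface carry 4×4-subsampled
region volume fractions, which weight the enzymatic sinks, source
distributions, current integrals and region measures. Each region's weights
are renormalised so its mesh volume matches the geometric volume exactly —
this removes the O(h) staircase bias that otherwise leaks cut-cell volume
into membrane shells.

Interface connections are built by scanning grid lines: two live cells
flanking a run of membrane cells (or directly adjacent across a region
change) are linked through a series resistance of their half-cell diffusive
paths plus one `1/(Aσ)` term per membrane type crossed. Runs longer than
`1.6(2θ_mem + d_sep)` are tangent-ray artefacts and are skipped; transport
there is carried by the perpendicular rays. Because a staircase overstates
the area of oblique surfaces (by ~19% for this geometry), the permeability
terms are rescaled by the analytic-to-staircase area ratio per membrane;
without the correction the envelope conductance would be biased high by a
few percent. Interconversion rates are assigned per cell from the
cell-centre region (scaled by the live volume fraction) rather than blended
across regions — blending would create spurious within-region bicarbonate
gradients and break the exact uniform equilibrium of the enzyme-free limit.

The assembled diffusion operator has exactly zero interior row sums
(discrete conservation), and all cross-region faces carry a membrane, so
regions cannot leak into each other.

## Solver

The production path is a damped Picard iteration. Per outer iteration the
Michaelis–Menten denominators and the globally coupled source currents are
frozen; the resulting linear systems are solved exactly by sparse LU. CO2
and HCO3⁻ are solved as one coupled 2N×2N system because the
CA-boosted interconversion (up to ~4×10⁴ s⁻¹) couples them far too stiffly
for lagging one species; O2 couples only through the frozen denominators
and solves separately. The three currents are then recomputed from the new
fields and under-relaxed. The configured damping factor (default 0.5) is a
floor: while the update norm shrinks monotonically the step is lengthened
by 1.4× per 4 consecutive contractions up to 1.0, and any growth resets it.
This keeps the stiff saturating-pump regimes robust (~50 iterations)
without paying ~100 iterations everywhere.

Numerical controls: outer tolerance 10⁻⁸ (relative, on both the current
triple and the fields), direct linear solves to machine precision,
Henry-equilibrium initial fields with zero currents (fully deterministic —
there is no randomness anywhere), optional warm starts for parameter
sweeps. Negative concentrations are never clipped; anything beyond 10⁻¹²
of scale aborts with an error, as it indicates an under-resolved mesh. The
photon cost is reported as NaN below the compensation point rather than a
signed number.

Verification is two-pronged:

* an **independent oracle** solves the identical discrete problem with no
  Picard splitting — a dense forward-difference Newton iteration on the
  full nonlinear residual (frozen-Jacobian reuse between steps, refreshed
  on stall), restricted to coarse meshes. Production and oracle currents
  agree to ~10⁻⁹ relative;
* an **analytic 1D slab** family (layers + membranes + fixed ends) whose
  series-resistance flux the finite-volume chain reproduces to round-off,
  regression-testing the conductance assembly.

Steady-state closures hold to well under 1%: airspace CO2 influx equals
net assimilation `J_Calvin − J_phresp/2`, O2 efflux equals `J_Calvin`, and
net cytosolic CO2→HCO3⁻ conversion equals `J_C4` (the nm/s bicarbonate
membrane permeabilities shift assimilation by <0.1%, and may be set to
exactly zero). Grid convergence of the assimilation rate is second order in
practice; the default resolution sits within 0.3% of the Richardson limit.

## Light-harvesting cap

A finite light-harvesting capacity (mol photons per m³ stroma per s) is
enforced by scaling both primed-enzyme pools by a common factor f — the two
cycles draw on the shared ATP/NADPH pool without coordination, so their
capacity ratio stays fixed. f is found by root bracketing around the
proportional guess `LHC/use` and polished until the volumetric light use
matches the capacity to 10⁻⁴ relative; each trial solve warm-starts from
the previous one. "Unlimited" capacity is an explicit sentinel, not a large
number, so no cap iteration ever runs in the unconstrained case.

## Drivers and problem sizes

The efficacy threshold (the envelope permeability where C4 and C3 photon
costs cross) is bracketed at saturating pump activity — operationalised as
a PEPC-to-RubisCO carboxylation capacity ratio of 10, where both efficacy
measures have plateaued — and bisected to 1%. The light-utilisation
operating points bisect log c_P to the same tolerance; the capped-optimum
search uses bounded scalar minimisation over log c_P. Threshold searches
were cross-checked against dense grid scans on coarse meshes.

Default problem sizes were chosen so the package runs at desk scale: the
production mesh has ~6000 control volumes (a single steady solve takes a
few seconds on one CPU; the threshold bisection ~30 solves), the oracle and
most unit tests run on a ~2000-cell mesh, and the figure-reproduction
commands use reduced sweep grids (4–5 points per axis) that capture the
trends rather than the full published rasters.

## Design choices where the design was open

* The tonoplast contour over the protruding cap is an offset surface of the
  envelope; its exact shape is a convention with demonstrably small
  sensitivity (the vacuole acts mainly as a low-viscosity transport shunt).
* The cytosol volume in the photorespiratory source denominator is the full
  peripheral-cytosol volume of the cylinder, consistent with spatially
  averaged mitochondria.
* Light use is normalised per stromal volume throughout, making results
  transferable across coverage and chloroplast-size scans.
* The C3 reference for "gain" is the same parameter set with c_P = 0 and a
  non-binding cap; comparisons are only made where the cap does not
  constrain C3 photosynthesis.
* The 12:3 ATP-synthase stoichiometry is the default; 14:3 is a
  configuration option (`atp_h_ratio = 14/3`) and leaves relative efficacy
  measures within a few percent while raising the absolute photon bill.

## What the built-in scenarios do and do not show

All quantitative outputs are computed on the idealised geometry above with
literature point-values for kinetics and permeabilities. Passing tests
demonstrate internal consistency (conservation, oracle equivalence, grid
convergence) and reproduction of the model's published operating points —
not that a real mesophyll cell would realise these gains: actual envelope
permeability spans orders of magnitude in the literature, chloroplasts are
not perfect hemispheres, mitochondrial positioning is not uniform, and
photosystem regulation is not instantaneous or lossless.

## Known limitations

* No transient dynamics; steady state only.
* No explicit C4-intermediate (malate/PEP) transport or RuBP pool dynamics.
* No temperature dependence (all constants at 20 °C).
* The staircase discretisation, even area-corrected, carries a small
  geometric bias at membrane corners; PDE-derived quantities should be read
  with a few-percent discretisation allowance.
* Leaf-level radiative transfer and canopy effects are out of scope; the
  incident-flux conversion applies to the cell surface, not the leaf.
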
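"""Model parameters, unit conventions and closed-form unit conversions.

The internal unit system is micrometre-second-(mol m^-3): lengths in um,
times in s, concentrations in mol m^-3 (numerically equal to mM), pressures
in bar.  In these units diffusion coefficients are um^2/s, membrane
permeabilities um/s, reaction currents come out in 1e-18 mol/s (amol/s), a
current divided by an area in um^2 is directly in umol m^-2 s^-1, and a
photon current divided by a volume in um^3 is directly in mol m^-3 s^-1.
No scale factors appear anywhere in the transport or biochemistry code.

The composite hydroxide-pathway constant ``k_OHKw`` is stored in M s^-1 and
is divided by the proton concentration 10^-pH M at the point of use; it is
never decomposed into a rate constant and an ion product.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Union

__all__ = [
    "UNLIMITED",
    "ModelParams",
    "ParamError",
    "load_params",
    "diffusion_coefficient",
    "henry_concentration",
    "permeability_to_conductance",
    "lhc_to_incident_flux",
    "capacity_ratio",
]

#: Sentinel for an uncapped light-harvesting capacity.  An explicit sentinel
#: is used instead of a large number so that the light-cap iteration is
#: skipped entirely rather than spuriously triggered.
UNLIMITED = "unlimited"

SPECIES = ("CO2", "O2", "HCO3")
REGIONS = ("stroma", "cytosol", "vacuole")


class ParamError(ValueError):
    """Raised for malformed configuration input or invariant violations."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the cell model.

    Defaults are the wheat-derived reference values; geometry-linked
    quantities (``d_V``, ``h_V``, ``sigma_v``) default to ``None`` and are
    resolved against ``r_P`` / ``sigma_p`` (vacuole drop r_P/2, simulated
    vacuole height 1.5 r_P, tonoplast permeability twice the envelope's).
    """

    # --- geometry (um / fractions) -------------------------------------
    r_P: float = 1.5              # chloroplast (hemisphere) radius, um
    phi_cov: float = 0.5          # chloroplast cell-surface coverage fraction
    d_sep: float = 0.03           # envelope-plasmalemma / envelope-tonoplast gap, um
    theta_mem: float = 0.03       # envelope & tonoplast membrane thickness, um
    d_V: float | None = None      # vacuole drop (default r_P/2), um
    h_V: float | None = None      # simulated vacuole height (default 1.5 r_P), um
    # --- enzymes (mol m^-3, 1/s) ---------------------------------------
    c_R: float = 4.0              # RuBP-primed RubisCO active sites, mol m^-3
    c_P: float = 0.0              # PEP-primed PEPC active sites, mol m^-3
    v_C: float = 3.8              # RubisCO carboxylation rate, 1/s
    v_O: float = 0.83             # RubisCO oxygenation rate, 1/s
    v_B: float = 150.0            # PEPC carboxylation rate, 1/s
    K_C: float = 9.7e-3           # RubisCO K_M for CO2, mol m^-3
    K_O: float = 0.244            # RubisCO K_M for O2, mol m^-3
    K_B: float = 0.1              # PEPC K_M for HCO3-, mol m^-3
    # --- gas reservoir (bar, mol m^-3 bar^-1) --------------------------
    p_CO2: float = 250e-6         # IAS CO2 partial pressure, bar
    p_O2: float = 0.21            # IAS O2 partial pressure, bar
    H_C: float = 38.5             # Henry constant for CO2 at 20 C, mol m^-3 bar^-1
    H_O: float = 1.36             # Henry constant for O2 at 20 C, mol m^-3 bar^-1
    # --- CO2 <-> HCO3- interconversion ---------------------------------
    pH_stroma: float = 8.0
    pH_cyt: float = 7.5
    pH_vac: float = 5.5
    eta_CA_stroma: float = 1e6    # CA activity factor in the stroma
    eta_CA_cyt: float = 1e6       # CA activity factor in the cytosol
    k_CO2: float = 0.037          # CO2 + H2O -> HCO3- + H+, 1/s
    k_OHKw: float = 7.1e-11       # composite CO2 + OH- pathway constant, M/s
    k_d: float = 7.6e4            # HCO3- + H+ -> CO2 + H2O, 1/(M s)
    k_HCO3: float = 1.8e-4        # HCO3- -> CO2 + OH-, 1/s
    # --- membrane permeabilities (um/s) --------------------------------
    sigma_c: float = 200.0        # cell wall + plasmalemma, gases
    sigma_p: float = 600.0        # chloroplast envelope, gases
    sigma_v: float | None = None  # tonoplast, gases (default 2 sigma_p)
    sigma_pB: float = 1e-3        # envelope, HCO3-
    sigma_vB: float = 2e-3        # tonoplast, HCO3-
    # --- aqueous diffusion (um^2/s) and relative viscosities -----------
    D_C_aq: float = 1800.0
    D_O_aq: float = 1800.0
    D_B_aq: float = 1100.0
    eta_visc_cyt: float = 2.0
    eta_visc_str: float = 10.0
    eta_visc_vac: float = 1.0
    # --- energetics ----------------------------------------------------
    LHC: Union[float, str] = UNLIMITED  # light-harvesting capacity, mol m^-3 s^-1
    phi_Calvin: float = 8.0       # photons per CO2 fixed
    phi_phresp: float = 9.0       # photons per RuBP oxygenation
    phi_C4: float = 4.0           # photons per C transferred by the C4 cycle
    atp_h_ratio: float = 4.0      # protons per ATP (12:3 default; 14/3 option)

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        object.__setattr__(self, "_validated", False)
        self.validate()

    # resolved geometry-linked defaults
    @property
    def vacuole_drop(self) -> float:
        return self.r_P / 2.0 if self.d_V is None else self.d_V

    @property
    def vacuole_height(self) -> float:
        return 1.5 * self.r_P if self.h_V is None else self.h_V

    @property
    def sigma_tonoplast(self) -> float:
        return 2.0 * self.sigma_p if self.sigma_v is None else self.sigma_v

    @property
    def lhc_limited(self) -> bool:
        return self.LHC != UNLIMITED

    def validate(self) -> None:
        pos = [
            "r_P", "d_sep", "theta_mem", "c_R", "v_C", "v_O", "v_B",
            "K_C", "K_O", "K_B", "H_C", "H_O", "k_CO2", "k_OHKw", "k_d",
            "k_HCO3", "sigma_c", "sigma_p",
            "D_C_aq", "D_O_aq", "D_B_aq", "eta_visc_cyt", "eta_visc_str",
            "eta_visc_vac", "phi_Calvin", "phi_phresp", "phi_C4",
            "atp_h_ratio",
        ]
        for name in pos:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParamError(f"parameter {name!r} must be strictly positive, got {v!r}")
        # bicarbonate permeabilities are near-zero physically and may be
        # set to exactly zero (impermeable membranes)
        for name in ("c_P", "p_CO2", "p_O2", "sigma_pB", "sigma_vB"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise ParamError(f"parameter {name!r} must be non-negative, got {v!r}")
        if not 0.0 < self.phi_cov < 1.0:
            raise ParamError(f"phi_cov must lie in (0, 1), got {self.phi_cov!r}")
        for name in ("pH_stroma", "pH_cyt", "pH_vac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 14.0:
                raise ParamError(f"{name} must lie in [0, 14], got {v!r}")
        for name in ("eta_CA_stroma", "eta_CA_cyt"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 1.0):
                raise ParamError(f"{name} must be >= 1, got {v!r}")
        for name, floor in (("d_V", 0.0), ("h_V", 0.0), ("sigma_v", 0.0)):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > floor):
                raise ParamError(f"{name} must be strictly positive, got {v!r}")
        if self.LHC != UNLIMITED:
            if not (isinstance(self.LHC, (int, float)) and math.isfinite(self.LHC) and self.LHC > 0):
                raise ParamError(f"LHC must be positive or {UNLIMITED!r}, got {self.LHC!r}")

    # ------------------------------------------------------------------
    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParamError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    # region helpers ----------------------------------------------------
    def pH(self, region: str) -> float:
        return {"stroma": self.pH_stroma, "cytosol": self.pH_cyt, "vacuole": self.pH_vac}[region]

    def eta_CA(self, region: str) -> float:
        return {"stroma": self.eta_CA_stroma, "cytosol": self.eta_CA_cyt, "vacuole": 1.0}[region]


# ---------------------------------------------------------------------------
# Configuration parsing


def _parse_value(key: str, text: str):
    text = text.strip().strip('"').strip("'")
    if key == "LHC" and text.lower() == UNLIMITED:
        return UNLIMITED
    if text.lower() in ("none", "default"):
        return None
    # allow simple fractions such as 14/3 for atp_h_ratio
    if "/" in text:
        try:
            num, den = text.split("/")
            return float(num) / float(den)
        except ValueError:
            pass
    try:
        return float(text)
    except ValueError as exc:
        raise ParamError(f"cannot parse value for key {key!r}: {text!r}") from exc


def load_params(config_text: str = "", overrides: dict | None = None) -> ModelParams:
    """Build a :class:`ModelParams` from a flat ``key = value`` document.

    Blank lines and ``#`` comments are ignored; unknown keys are rejected;
    keys not present take their defaults.  ``overrides`` (e.g. from CLI
    ``--set key=value`` flags) are applied on top of the document.
    """
    values: dict = {}
    field_names = {f.name for f in dataclasses.fields(ModelParams)}
    for lineno, raw in enumerate(config_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParamError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in field_names:
            raise ParamError(f"line {lineno}: unknown parameter key {key!r}")
        values[key] = _parse_value(key, val)
    if overrides:
        for key, val in overrides.items():
            if key not in field_names:
                raise ParamError(f"unknown parameter key {key!r}")
            values[key] = _parse_value(key, val) if isinstance(val, str) else val
    return ModelParams(**values)


# ---------------------------------------------------------------------------
# Closed-form conversions


def diffusion_coefficient(species: str, region: str, params: ModelParams) -> float:
    """Effective diffusion coefficient ``D_aq / eta_region`` in um^2/s."""
    if species not in SPECIES:
        raise ParamError(f"unknown species {species!r}; expected one of {SPECIES}")
    if region not in REGIONS:
        raise ParamError(f"unknown region {region!r}; expected one of {REGIONS}")
    d_aq = {"CO2": params.D_C_aq, "O2": params.D_O_aq, "HCO3": params.D_B_aq}[species]
    eta = {
        "stroma": params.eta_visc_str,
        "cytosol": params.eta_visc_cyt,
        "vacuole": params.eta_visc_vac,
    }[region]
    return d_aq / eta


def henry_concentration(pressure: float, H: float) -> float:
    """Dissolved gas concentration ``n = H p`` (mol m^-3) at equilibrium."""
    if pressure < 0:
        raise ParamError(f"pressure must be non-negative, got {pressure!r}")
    return H * pressure


def permeability_to_conductance(sigma: float, H: float, phi_surface_ratio: float) -> float:
    """Leaf-level conductance ``g = phi H sigma`` in mol bar^-1 m^-2 s^-1.

    ``sigma`` is a membrane permeability in um/s, ``H`` a Henry constant in
    mol m^-3 bar^-1 and ``phi_surface_ratio`` the barrier-to-leaf surface
    area ratio.  The 1e-6 factor converts um/s to m/s.
    """
    if sigma <= 0 or H <= 0 or phi_surface_ratio <= 0:
        raise ParamError("sigma, H and phi_surface_ratio must all be positive")
    return phi_surface_ratio * H * sigma * 1e-6


def lhc_to_incident_flux(LHC: float, r_P: float, phi_cov: float) -> float:
    """Incident photon flux (umol m^-2 s^-1) equivalent to a volumetric use.

    A volumetric photon consumption ``LHC`` (mol m^-3 s^-1) over the stromal
    volume of one hemispherical chloroplast, (2/3) pi r_P^3, referred to the
    cell cross-section served by that chloroplast, pi r_P^2 / phi_cov, gives
    ``LHC * (2/3) r_P * phi_cov`` -- directly in umol m^-2 s^-1 in the
    internal unit system.
    """
    if LHC < 0 or r_P <= 0:
        raise ParamError("LHC must be >= 0 and r_P > 0")
    if not 0.0 < phi_cov < 1.0:
        raise ParamError(f"phi_cov must lie in (0, 1), got {phi_cov!r}")
    return LHC * (2.0 / 3.0) * r_P * phi_cov


def capacity_ratio(params: ModelParams, geometry) -> float:
    """PEPC-to-RubisCO carboxylation capacity ratio.

    ``(v_B c_P V_cyt) / (v_C c_R V_plas)`` with the region volumes taken
    from a built :class:`~c4cell.geometry.CellGeometry`.
    """
    if geometry.V_plas <= 0:
        raise ParamError("chloroplast volume must be positive")
    return (params.v_B * params.c_P * geometry.V_cyt) / (params.v_C * params.c_R * geometry.V_plas)


def pepc_for_capacity_ratio(params: ModelParams, geometry, ratio: float) -> float:
    """Inverse of :func:`capacity_ratio`: the c_P giving a target ratio."""
    if ratio < 0:
        raise ParamError("capacity ratio must be non-negative")
    return ratio * params.v_C * params.c_R * geometry.V_plas / (params.v_B * geometry.V_cyt)
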
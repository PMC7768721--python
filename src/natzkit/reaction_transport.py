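"""One-dimensional steady-state reaction-transport model of sediment porewater.

The model resolves five solutes (O2, NO3-, NH4+, Mn2+, DIC, all in uM) and
two solids (TOC in wt% dry sediment, MnO2 in umol g-1 dry sediment) on a
uniform finite-volume grid, coupled through a six-reaction kinetic network:

    R1  aerobic organic-matter degradation
    R2  heterotrophic denitrification
    R3  organoclastic MnO2 reduction
    R4  nitrification
    R5  Mn(II) oxidation with O2
    R6  anaerobic ammonium oxidation (anammox)

Solutes are transported by molecular diffusion (tortuosity-corrected) and
porewater advection; solids by burial advection and bioturbation (diffusive
mixing restricted to the upper mixed layer).  All species are assumed to be
at steady state; the coupled nonlinear system is solved by damped Newton
iteration on a banded numerical Jacobian, with pseudo-transient continuation
as a fallback for poor initial guesses.

Units follow common diagenetic practice: depth in cm below the sediment-water
interface (positive downward), time in years, fluxes in umol cm-2 yr-1
(positive downward), volumetric reaction rates in umol per cm3 of bulk
sediment per year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

__all__ = [
    "SOLUTES",
    "SOLIDS",
    "SPECIES",
    "REACTIONS",
    "SedimentGrid",
    "SpeciesSpec",
    "ReactionNetwork",
    "BoundaryCondition",
    "SteadyStateSolution",
    "ConfigurationError",
    "ConvergenceError",
    "build_grid",
    "tortuosity_corrected_diffusivity",
    "reaction_rates",
    "anammox_stoichiometry",
    "solve_steady_state",
    "mass_balance_report",
    "rmse_model_vs_data",
    "default_species",
]

logger = logging.getLogger(__name__)

SOLUTES = ("O2", "NO3", "NH4", "Mn2", "DIC")
SOLIDS = ("TOC", "MnO2")
SPECIES = SOLUTES + SOLIDS
REACTIONS = ("R1", "R2", "R3", "R4", "R5", "R6")

#: g per mol of carbon, for wt% <-> umol conversions
_M_CARBON = 12.011
#: umol C per g dry sediment for 1 wt% TOC
_WTPCT_TO_UMOL_G = 1e4 / _M_CARBON


class ConfigurationError(ValueError):
    """Physically inconsistent grid, network or boundary configuration."""


class ConvergenceError(RuntimeError):
    """Steady-state solver failed; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SedimentGrid:
    """Uniform finite-volume grid with compaction and bioturbation closures.

    ``depths`` are cell centers (cm below seafloor, increasing downward);
    faces sit at ``i * cell_thickness`` for ``i = 0..n``.  Porosity and the
    bioturbation coefficient are stored both at centers and faces so the
    solver never re-evaluates the closures.
    """

    depths: np.ndarray
    cell_thickness: float
    porosity: np.ndarray
    porosity_faces: np.ndarray
    temperature: float
    pressure: float
    salinity: float
    burial_velocity: float
    bioturbation_coeff: np.ndarray
    bioturbation_faces: np.ndarray
    bioturbation_depth: float

    def __post_init__(self):
        if np.any(np.diff(self.depths) <= 0):
            raise ConfigurationError("grid depths must strictly increase")
        if self.cell_thickness <= 0:
            raise ConfigurationError("cell_thickness must be positive")
        for phi in (self.porosity, self.porosity_faces):
            if np.any((phi <= 0) | (phi >= 1)):
                raise ConfigurationError("porosity must lie strictly in (0, 1)")
        if np.any(self.bioturbation_coeff < 0):
            raise ConfigurationError("bioturbation coefficient must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.depths.size

    @property
    def domain_length(self) -> float:
        return self.n_cells * self.cell_thickness

    @property
    def faces(self) -> np.ndarray:
        return np.arange(self.n_cells + 1) * self.cell_thickness


def build_grid(
    domain_length: float,
    n_cells: int = 200,
    porosity_surface: float = 0.85,
    porosity_deep: float = 0.75,
    attenuation: float = 50.0,
    T: float = 0.5,
    P: float = 250.0,
    salinity: float = 35.0,
    w: float = 2e-3,
    Db0: float = 0.1,
    zbio: float = 10.0,
) -> SedimentGrid:
    """Build a uniform sediment grid.

    Porosity follows an exponential compaction profile
    ``phi(z) = phi_deep + (phi_surface - phi_deep) * exp(-z / attenuation)``
    and bioturbation is a constant ``Db0`` down to ``zbio`` (cm), zero below
    — a step closure for the surface mixed layer, which in pelagic sediment
    is generally shallower than ~10 cm.

    Parameters use field-standard units: lengths cm, ``T`` degC, ``P`` bar,
    ``w`` (burial velocity) cm yr-1, ``Db0`` cm2 yr-1.
    """
    if domain_length <= 0 or attenuation <= 0:
        raise ConfigurationError("domain_length and attenuation must be positive")
    if n_cells < 10:
        raise ConfigurationError("n_cells must be >= 10")
    if not (0 < porosity_deep <= porosity_surface < 1):
        raise ConfigurationError(
            "require 0 < porosity_deep <= porosity_surface < 1, got "
            f"{porosity_deep}, {porosity_surface}"
        )
    if w < 0 or Db0 < 0 or zbio < 0:
        raise ConfigurationError("w, Db0 and zbio must be non-negative")

    dz = domain_length / n_cells
    centers = (np.arange(n_cells) + 0.5) * dz
    faces = np.arange(n_cells + 1) * dz

    def phi_of(z):
        return porosity_deep + (porosity_surface - porosity_deep) * np.exp(
            -np.asarray(z, dtype=float) / attenuation
        )

    db_centers = np.where(centers <= zbio, Db0, 0.0)
    # the face at the mixed-layer base carries no mixing flux: continuum flux
    # continuity makes transport across the base purely advective
    db_faces = np.where(faces < zbio, Db0, 0.0)
    return SedimentGrid(
        depths=centers,
        cell_thickness=dz,
        porosity=phi_of(centers),
        porosity_faces=phi_of(faces),
        temperature=T,
        pressure=P,
        salinity=salinity,
        burial_velocity=w,
        bioturbation_coeff=db_centers,
        bioturbation_faces=db_faces,
        bioturbation_depth=zbio,
    )


def tortuosity_corrected_diffusivity(D0, porosity):
    """Sediment diffusivity ``Ds = D0 / (1 - 2 ln phi)`` (Boudreau relation).

    ``D0`` is the free-solution diffusivity at in-situ temperature
    (cm2 yr-1); the correction accounts for the tortuous porewater path in
    muds and reduces to ``D0`` at unit porosity.
    """
    D0 = np.asarray(D0, dtype=float)
    phi = np.asarray(porosity, dtype=float)
    if np.any(D0 <= 0):
        raise ConfigurationError("free-solution diffusivity must be positive")
    if np.any((phi <= 0) | (phi >= 1)):
        raise ConfigurationError("porosity must lie strictly in (0, 1)")
    out = D0 / (1.0 - 2.0 * np.log(phi))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# species & kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesSpec:
    """One modeled chemical species and its transport properties."""

    name: str
    phase: str  # "solute" | "solid"
    free_solution_diffusivity: float | None = None  # cm2 yr-1, solutes only
    unit: str = "uM"

    def __post_init__(self):
        if self.name not in SPECIES:
            raise ConfigurationError(f"unknown species {self.name!r}")
        if self.phase not in ("solute", "solid"):
            raise ConfigurationError(f"phase must be solute or solid, got {self.phase!r}")
        expected = "solute" if self.name in SOLUTES else "solid"
        if self.phase != expected:
            raise ConfigurationError(f"{self.name} must be a {expected}")
        if self.phase == "solute":
            if self.free_solution_diffusivity is None or self.free_solution_diffusivity <= 0:
                raise ConfigurationError(f"{self.name}: solutes need D0 > 0")
        elif self.free_solution_diffusivity is not None:
            raise ConfigurationError(f"{self.name}: solids carry no diffusivity")


#: free-solution diffusivities (cm2 yr-1) near 0-2 degC, seawater
DEFAULT_D0 = {"O2": 365.0, "NO3": 318.0, "NH4": 330.0, "Mn2": 106.0, "DIC": 186.0}
_DEFAULT_D0 = DEFAULT_D0
_UNITS = {"TOC": "wt%", "MnO2": "umol/g"}


def default_species(D0: dict[str, float] | None = None) -> dict[str, SpeciesSpec]:
    """The canonical seven-species set with overridable solute diffusivities."""
    d0 = dict(_DEFAULT_D0)
    if D0:
        d0.update(D0)
    specs = {}
    for name in SOLUTES:
        specs[name] = SpeciesSpec(name, "solute", d0[name], "uM")
    for name in SOLIDS:
        specs[name] = SpeciesSpec(name, "solid", None, _UNITS[name])
    return specs


def anammox_stoichiometry(mode: str = "nitrate_coupled") -> dict[str, float]:
    """Stoichiometric coefficients for the anammox reaction.

    ``nitrite_canonical`` is the textbook catabolic reaction
    NH4+ + NO2- -> N2 + 2 H2O, used for thermodynamic calculations.
    ``nitrate_coupled`` is the electron-balanced overall reaction
    5 NH4+ + 3 NO3- -> 4 N2 + 9 H2O + 2 H+ used by the transport model,
    appropriate when nitrite is an undetectable transient supplied by
    nitrate reducers; coefficients are normalized per mol NH4+.
    """
    if mode == "nitrite_canonical":
        return {"NH4+": -1.0, "NO2-": -1.0, "N2": 1.0, "H2O": 2.0}
    if mode == "nitrate_coupled":
        return {"NH4+": -1.0, "NO3-": -0.6, "N2": 0.8, "H2O": 1.8, "H+": 0.4}
    raise ConfigurationError(f"unknown anammox mode {mode!r}")


@dataclass(frozen=True)
class ReactionNetwork:
    """Kinetic parameters and stoichiometry of the six-reaction network.

    Organic matter is degraded at first order (``k_TOC``, yr-1) through a
    Monod/inhibition cascade over the terminal oxidants O2 > NO3- > MnO2;
    nitrification and Mn(II) oxidation are bimolecular in their substrates
    and anammox is bimolecular in NH4+ and NO3- with hyperbolic O2
    inhibition.  ``r_NC`` is the N:C ratio of degrading organic matter, so
    every mole of C oxidized releases ``r_NC`` moles of NH4+.

    Half-saturation and inhibition constants are in uM for solutes and
    umol g-1 for MnO2; bimolecular constants in uM-1 yr-1; ``rho_dry``
    (g cm-3) couples solid and porewater inventories.
    """

    k_TOC: float = 1.2e-4
    K_O2: float = 20.0
    K_NO3: float = 10.0
    K_MnO2: float = 40.0
    Kin_O2: float = 10.0
    Kin_NO3: float = 10.0
    k_nit: float = 0.5
    k_mnox: float = 0.5
    k_amx: float = 0.01
    r_NC: float = 16.0 / 106.0
    rho_dry: float = 2.5
    anammox_mode: str = "nitrate_coupled"
    stoich: pd.DataFrame = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        positive = (
            "k_TOC K_O2 K_NO3 K_MnO2 Kin_O2 Kin_NO3 k_nit k_mnox k_amx rho_dry".split()
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.r_NC < 1):
            raise ConfigurationError("r_NC must lie in (0, 1)")
        if self.anammox_mode != "nitrate_coupled":
            raise ConfigurationError(
                "the transport model uses the nitrate-coupled anammox reaction; "
                "the nitrite form is available for thermodynamics only"
            )
        object.__setattr__(self, "stoich", self._build_stoich())
        self._check_conservation()

    def _build_stoich(self) -> pd.DataFrame:
        """nu(species, reaction); rows N2 and OrgN are implicit bookkeeping
        pools used only for atom-conservation checks."""
        rows = list(SPECIES) + ["N2", "OrgN"]
        S = pd.DataFrame(0.0, index=rows, columns=list(REACTIONS))
        r = self.r_NC
        # primary OM degradation, per mol organic C
        S.loc[["TOC", "O2", "DIC", "NH4"], "R1"] = [-1.0, -1.0, 1.0, r]
        S.loc[["TOC", "NO3", "DIC", "NH4", "N2"], "R2"] = [-1.0, -0.8, 1.0, r, 0.4]
        S.loc[["TOC", "MnO2", "Mn2", "DIC", "NH4"], "R3"] = [-1.0, -2.0, 2.0, 1.0, r]
        # secondary redox reactions
        S.loc[["NH4", "O2", "NO3"], "R4"] = [-1.0, -2.0, 1.0]
        S.loc[["Mn2", "O2", "MnO2"], "R5"] = [-1.0, -0.5, 1.0]
        amx = anammox_stoichiometry(self.anammox_mode)
        S.loc[["NH4", "NO3", "N2"], "R6"] = [amx["NH4+"], amx["NO3-"], amx["N2"]]
        # organic N shadows organic C at the N:C ratio
        S.loc["OrgN"] = r * S.loc["TOC"]
        return S

    def _check_conservation(self):
        S = self.stoich
        n_balance = S.loc["NO3"] + S.loc["NH4"] + 2.0 * S.loc["N2"] + S.loc["OrgN"]
        mn_balance = S.loc["Mn2"] + S.loc["MnO2"]
        if not np.allclose(n_balance, 0.0, atol=1e-12):
            raise ConfigurationError(f"stoichiometry does not conserve N: {dict(n_balance)}")
        if not np.allclose(mn_balance, 0.0, atol=1e-12):
            raise ConfigurationError(f"stoichiometry does not conserve Mn: {dict(mn_balance)}")


def _state_to_bulk(conc: dict[str, np.ndarray], net: ReactionNetwork, porosity):
    """Convert native-unit solid concentrations to bulk umol cm-3."""
    phi = np.asarray(porosity, dtype=float)
    dry = net.rho_dry * (1.0 - phi)  # g dry per cm3 bulk
    toc = np.asarray(conc["TOC"], dtype=float) * _WTPCT_TO_UMOL_G * dry
    mno2 = np.asarray(conc["MnO2"], dtype=float) * dry
    return toc, mno2


def reaction_rates(
    conc: dict[str, float | np.ndarray],
    net: ReactionNetwork,
    porosity: float | np.ndarray,
    clip_negative: bool = False,
) -> dict[str, np.ndarray]:
    """Volumetric rates of R1..R6 in umol cm-3 (bulk sediment) yr-1.

    ``conc`` holds native units (solutes uM, TOC wt%, MnO2 umol g-1).  The
    returned basis is mol organic C for R1-R3, mol NH4+ for R4 and R6 and
    mol Mn2+ for R5; multiply by the stoichiometry matrix to get per-species
    source terms.  Negative concentrations raise unless ``clip_negative``
    (used by the solver, which logs the clip) is set.
    """
    c = {k: np.asarray(v, dtype=float) for k, v in conc.items()}
    if any(np.any(v < 0) for v in c.values()):
        if not clip_negative:
            raise ValueError("negative concentrations passed to reaction_rates")
        c = {k: np.clip(v, 0.0, None) for k, v in c.items()}
    phi = np.asarray(porosity, dtype=float)
    toc_bulk, mno2_bulk = _state_to_bulk(c, net, phi)

    f_o2 = c["O2"] / (net.K_O2 + c["O2"])
    f_no3 = c["NO3"] / (net.K_NO3 + c["NO3"])
    f_mno2 = np.divide(
        mno2_bulk,
        net.K_MnO2 * net.rho_dry * (1.0 - phi) + mno2_bulk,
        out=np.zeros_like(mno2_bulk),
        where=mno2_bulk > 0,
    )
    inh_o2 = net.Kin_O2 / (net.Kin_O2 + c["O2"])
    inh_no3 = net.Kin_NO3 / (net.Kin_NO3 + c["NO3"])

    # R1-R3 directly on the bulk organic-carbon pool
    r1 = net.k_TOC * toc_bulk * f_o2
    r2 = net.k_TOC * toc_bulk * f_no3 * inh_o2
    r3 = net.k_TOC * toc_bulk * f_mno2 * inh_o2 * inh_no3
    # bimolecular porewater reactions: uM yr-1 -> umol cm-3 bulk yr-1
    pw_to_bulk = 1e-3 * phi
    r4 = net.k_nit * c["O2"] * c["NH4"] * pw_to_bulk
    r5 = net.k_mnox * c["O2"] * c["Mn2"] * pw_to_bulk
    r6 = net.k_amx * c["NH4"] * c["NO3"] * inh_o2 * pw_to_bulk
    return {"R1": r1, "R2": r2, "R3": r3, "R4": r4, "R5": r5, "R6": r6}


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryCondition:
    """One boundary condition: fixed concentration (native units), fixed
    flux (umol cm-2 yr-1, positive downward) or zero gradient."""

    species: str
    edge: str  # "top" | "bottom"
    kind: str  # "fixed_concentration" | "fixed_flux" | "zero_gradient"
    value: float = 0.0

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ConfigurationError(f"unknown species {self.species!r}")
        if self.edge not in ("top", "bottom"):
            raise ConfigurationError("edge must be 'top' or 'bottom'")
        if self.kind not in ("fixed_concentration", "fixed_flux", "zero_gradient"):
            raise ConfigurationError(f"unknown boundary kind {self.kind!r}")
        if self.kind == "fixed_flux" and self.species in SOLIDS and self.edge != "top":
            raise ConfigurationError("solids accept flux conditions only at the top")


def _index_bcs(bcs, species_names):
    table = {}
    for bc in bcs:
        key = (bc.species, bc.edge)
        if key in table:
            raise ConfigurationError(f"duplicate boundary condition for {key}")
        table[key] = bc
    for name in species_names:
        for edge in ("top", "bottom"):
            if (name, edge) not in table:
                raise ConfigurationError(f"missing {edge} boundary condition for {name}")
    return table


# ---------------------------------------------------------------------------
# steady-state solution container
# ---------------------------------------------------------------------------


@dataclass
class SteadyStateSolution:
    """Converged concentration and rate profiles with flux diagnostics."""

    grid: SedimentGrid
    species: dict[str, SpeciesSpec]
    network: ReactionNetwork
    concentrations: dict[str, np.ndarray]  # native units
    reaction_rates: dict[str, np.ndarray]  # umol cm-3 bulk yr-1
    boundary_fluxes: dict[str, tuple[float, float]]  # (top, bottom), + down
    residual_norm: float
    converged: bool
    iterations: int
    residual_history: list[float] = field(default_factory=list)
    extra_sources: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-depth table of concentrations and reaction rates."""
        cols = {"depth_cm": self.grid.depths}
        rename = {
            "O2": "O2_uM", "NO3": "NO3_uM", "NH4": "NH4_uM", "Mn2": "Mn2_uM",
            "DIC": "DIC_uM", "TOC": "TOC_wtpct", "MnO2": "MnO2_umol_g",
        }
        for name in SPECIES:
            cols[rename[name]] = self.concentrations[name]
        for rx in REACTIONS:
            cols[f"{rx}_umol_cm3_yr"] = self.reaction_rates[rx]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# solver internals
# ---------------------------------------------------------------------------


class _Discretization:
    """Finite-volume residual of the coupled steady-state system.

    The state is a (n_species, n_cells) array in native units.  Residuals are
    per-cell flux imbalances in umol cm-2 yr-1:

        res[i] = F(face i) - F(face i+1) + sum_r nu * R_r * dz

    with fluxes positive downward.  Solute fluxes are
    ``phi * (-Ds dC/dz + u C)`` on the umol cm-3 scale; solid fluxes
    ``(1-phi) rho * (-Db dS/dz + w S)`` on the umol g-1 scale (TOC converted
    from wt% to umol C g-1).  Dirichlet edges use half-cell gradients to the
    boundary value, zero-gradient edges drop the diffusive term, and flux
    edges substitute the prescribed value directly.
    """

    def __init__(self, grid, species, net, bcs, extra_sources=None):
        self.grid = grid
        self.net = net
        self.extra_sources = extra_sources or {}
        self.names = list(SPECIES)
        self.species = species
        self.bcs = _index_bcs(bcs, self.names)
        n = grid.n_cells
        dz = grid.cell_thickness
        self.n, self.dz = n, dz

        # state -> umol per cm3 porewater (solutes) / umol per g dry (solids)
        self.conv = np.array(
            [1e-3 if s in SOLUTES else (_WTPCT_TO_UMOL_G if s == "TOC" else 1.0)
             for s in self.names]
        )
        phi_f = grid.porosity_faces
        self.phi_f = phi_f
        # per-species face transport coefficients (n_species, n_faces)
        self.diff_f = np.zeros((len(self.names), n + 1))
        self.adv_f = np.zeros((len(self.names), n + 1))
        for k, s in enumerate(self.names):
            if s in SOLUTES:
                ds = tortuosity_corrected_diffusivity(
                    species[s].free_solution_diffusivity, phi_f
                )
                self.diff_f[k] = phi_f * ds
                self.adv_f[k] = phi_f * grid.burial_velocity
            else:
                solid_frac = (1.0 - phi_f) * net.rho_dry
                self.diff_f[k] = solid_frac * grid.bioturbation_faces
                self.adv_f[k] = solid_frac * grid.burial_velocity
        # at faces where the mixing coefficient jumps (the mixed-layer base)
        # the solution is kinked; the upstream cell value is the accurate
        # face value there, the centered mean elsewhere
        db = grid.bioturbation_coeff
        kink = db[:-1] != db[1:]
        self.upwind_face = np.zeros((len(self.names), n - 1), dtype=bool)
        for k, s in enumerate(self.names):
            if s in SOLIDS:
                self.upwind_face[k] = kink

    # -- fluxes -----------------------------------------------------------

    def face_fluxes(self, state: np.ndarray) -> np.ndarray:
        """(n_species, n_faces) fluxes in umol cm-2 yr-1, positive downward."""
        n, dz = self.n, self.dz
        c = state * self.conv[:, None]
        F = np.empty((len(self.names), n + 1))
        # interior faces: central differences for diffusion and advection
        # (burial/advection cell Peclet and decay numbers are << 1 here, so
        # the second-order central face value is stable)
        grad = (c[:, 1:] - c[:, :-1]) / dz
        mid = np.where(self.upwind_face, c[:, :-1], 0.5 * (c[:, 1:] + c[:, :-1]))
        F[:, 1:n] = -self.diff_f[:, 1:n] * grad + self.adv_f[:, 1:n] * mid
        for k, s in enumerate(self.names):
            conv = self.conv[k]
            top = self.bcs[(s, "top")]
            if top.kind == "fixed_concentration":
                # quadratic one-sided gradient through the boundary value and
                # the two nearest cell centers (second-order boundary flux)
                cb = top.value * conv
                grad0 = (-8.0 * cb / 3.0 + 3.0 * c[k, 0] - c[k, 1] / 3.0) / dz
                F[k, 0] = -self.diff_f[k, 0] * grad0 + self.adv_f[k, 0] * cb
            elif top.kind == "zero_gradient":
                F[k, 0] = self.adv_f[k, 0] * c[k, 0]
            else:
                F[k, 0] = top.value
            bot = self.bcs[(s, "bottom")]
            if bot.kind == "fixed_concentration":
                cb = bot.value * conv
                gradn = (8.0 * cb / 3.0 - 3.0 * c[k, n - 1] + c[k, n - 2] / 3.0) / dz
                F[k, n] = -self.diff_f[k, n] * gradn + self.adv_f[k, n] * cb
            elif bot.kind == "zero_gradient":
                F[k, n] = self.adv_f[k, n] * c[k, n - 1]
            else:
                F[k, n] = bot.value
        return F

    def volumetric_rates(self, state: np.ndarray) -> dict[str, np.ndarray]:
        conc = {s: state[k] for k, s in enumerate(self.names)}
        return reaction_rates(conc, self.net, self.grid.porosity, clip_negative=True)

    def residual(self, state: np.ndarray) -> np.ndarray:
        F = self.face_fluxes(state)
        rates = self.volumetric_rates(state)
        src = np.zeros((len(self.names), self.n))
        S = self.net.stoich
        for j, rx in enumerate(REACTIONS):
            nu = S[rx].to_numpy()[: len(self.names)]
            src += nu[:, None] * rates[rx][None, :]
        for s, extra in self.extra_sources.items():
            src[self.names.index(s)] += extra
        return F[:, :-1] - F[:, 1:] + src * self.dz

    def scales(self, state: np.ndarray) -> np.ndarray:
        """Per-species residual scale: dominant flux magnitude with a floor."""
        F = self.face_fluxes(state)
        mag = np.max(np.abs(F), axis=1)
        diff_scale = np.max(self.diff_f, axis=1) * np.max(
            np.abs(state * self.conv[:, None]), axis=1
        ) / max(self.grid.domain_length, 1.0)
        return np.maximum.reduce([mag, diff_scale, np.full_like(mag, 1e-10)])


def _scaled_norm(res, scales):
    return float(np.max(np.abs(res) / scales[:, None]))


def _banded_jacobian(disc, state, res0, half_bandwidth):
    """Numerical Jacobian in solve_banded layout via column coloring.

    The state is flattened species-major within each cell (interleaved), so
    transport couples indices +/- n_species and kinetics couple within a
    cell; the band half-width is n_species.
    """
    ns, n = state.shape
    m = ns * n
    bw = half_bandwidth
    ncolors = 2 * bw + 1
    ab = np.zeros((ncolors, m))
    flat = state.T.ravel()  # cell-major -> species interleaved
    eps = np.sqrt(np.finfo(float).eps)
    for color in range(ncolors):
        cols = np.arange(color, m, ncolors)
        h = eps * np.maximum(np.abs(flat[cols]), 1.0)
        pert = flat.copy()
        pert[cols] += h
        res_p = disc.residual(pert.reshape(n, ns).T)
        dr = (res_p - res0).T.ravel()
        for j, hj in zip(cols, h):
            lo, hi = max(0, j - bw), min(m, j + bw + 1)
            rows = np.arange(lo, hi)
            ab[bw + rows - j, j] = dr[rows] / hj
    # a species with no transport and no kinetics leaves a zero row/column
    # (any value is a steady state); pin it so the factorization stays regular
    dead = np.max(np.abs(ab), axis=0) == 0.0
    ab[bw, dead] = 1.0
    return ab


def _initial_state(disc):
    """Linear interpolation between boundary values; steady-burial solids."""
    n = disc.n
    z = disc.grid.depths
    L = disc.grid.domain_length
    state = np.zeros((len(disc.names), n))
    for k, s in enumerate(disc.names):
        top = disc.bcs[(s, "top")]
        bot = disc.bcs[(s, "bottom")]
        c_top = top.value if top.kind == "fixed_concentration" else None
        c_bot = bot.value if bot.kind == "fixed_concentration" else None
        if top.kind == "fixed_flux":
            adv = max(disc.adv_f[k, 0], 1e-30)
            c_top = max(top.value, 0.0) / adv / disc.conv[k]
        if c_top is None and c_bot is None:
            state[k] = 0.0
        elif c_bot is None:
            state[k] = c_top
        elif c_top is None:
            state[k] = c_bot
        else:
            state[k] = c_top + (c_bot - c_top) * z / L
    return state


def solve_steady_state(
    grid: SedimentGrid,
    species: dict[str, SpeciesSpec],
    net: ReactionNetwork,
    bcs: list[BoundaryCondition],
    tol: float = 1e-10,
    max_iter: int = 60,
    initial_state: dict[str, np.ndarray] | None = None,
    clip_tolerance: float = 1e-6,
    extra_sources: dict[str, np.ndarray] | None = None,
) -> SteadyStateSolution:
    """Solve the coupled nonlinear steady-state system.

    Damped Newton iteration on a banded numerical Jacobian; when a Newton
    step cannot reduce the residual the solver falls back to pseudo-transient
    continuation (a diagonally lagged implicit Euler march with geometric
    time-step growth) until Newton becomes contractive again.  Negative
    concentrations are clipped to zero between iterations; a clip larger than
    ``clip_tolerance`` (native units) at convergence is treated as failure.
    """
    missing = [s for s in SPECIES if s not in species]
    if missing:
        raise ConfigurationError(f"missing species specs: {missing}")
    disc = _Discretization(grid, species, net, bcs, extra_sources)
    ns, n = len(disc.names), disc.n
    bw = ns

    if initial_state is not None:
        state = np.vstack([np.asarray(initial_state[s], float) for s in disc.names])
    else:
        state = _initial_state(disc)

    history: list[float] = []
    dt = None  # pseudo-transient step, None = plain Newton
    res = disc.residual(state)
    scales = disc.scales(state)
    norm = _scaled_norm(res, scales)
    history.append(norm)
    total_clip = 0.0

    it = 0
    for it in range(1, max_iter + 1):
        if norm < tol:
            break
        ab = _banded_jacobian(disc, state, res, bw)
        if dt is not None:
            # add the pseudo-time mass term on the diagonal
            mass = np.tile(disc.conv, n) / dt * disc.dz
            ab[bw, :] -= mass
        try:
            step = solve_banded((bw, bw), ab, -res.T.ravel())
        except np.linalg.LinAlgError:
            dt = 1.0 if dt is None else dt
            continue
        step = step.reshape(n, ns).T

        lam, accepted = 1.0, False
        for _ in range(12):
            trial = state + lam * step
            clip = float(np.abs(np.minimum(trial, 0.0)).max())
            trial = np.clip(trial, 0.0, None)
            r_t = disc.residual(trial)
            n_t = _scaled_norm(r_t, scales)
            if n_t < norm * (1.0 - 1e-4 * lam) or n_t < tol:
                state, res, norm = trial, r_t, n_t
                total_clip = clip
                accepted = True
                break
            lam *= 0.5
        if accepted:
            scales = disc.scales(state)
            norm = _scaled_norm(res, scales)
            if dt is not None:
                dt *= 3.0  # geometric growth back toward plain Newton
                if dt > 1e12:
                    dt = None
        else:
            # Newton stagnated: start or tighten pseudo-transient continuation
            dt = 10.0 if dt is None else dt / 4.0
            if dt < 1e-8:
                raise ConvergenceError(
                    "pseudo-transient continuation collapsed "
                    f"(residual {norm:.3e} after {it} iterations)",
                    history,
                )
        history.append(norm)
    if norm >= tol:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations (residual {norm:.3e})",
            history,
        )

    if total_clip > clip_tolerance:
        raise ConvergenceError(
            f"negative-concentration clip {total_clip:.3e} exceeds tolerance "
            f"{clip_tolerance:.1e} at convergence",
            history,
        )
    if total_clip > 0:
        logger.warning("clipped negative concentrations by up to %.3e at convergence",
                       total_clip)

    F = disc.face_fluxes(state)
    rates = disc.volumetric_rates(state)
    return SteadyStateSolution(
        grid=grid,
        species=species,
        network=net,
        concentrations={s: state[k].copy() for k, s in enumerate(disc.names)},
        reaction_rates=rates,
        boundary_fluxes={s: (float(F[k, 0]), float(F[k, -1])) for k, s in enumerate(disc.names)},
        residual_norm=norm,
        converged=True,
        iterations=it,
        residual_history=history,
        extra_sources={k: np.asarray(v, float) for k, v in (extra_sources or {}).items()},
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def mass_balance_report(sol: SteadyStateSolution) -> pd.DataFrame:
    """Per-species steady-state closure: (top flux - bottom flux) must equal
    the depth-integrated net reaction sink, and total N must balance.

    Returns a table with columns flux_difference, integrated_reaction and
    relative_closure (|difference| normalized by the dominant term, floored).
    """
    if not sol.converged:
        raise ValueError("mass balance requires a converged solution")
    dz = sol.grid.cell_thickness
    S = sol.network.stoich
    rows = {}
    for k, s in enumerate(SPECIES):
        net_rx = sum(
            float(S.loc[s, rx]) * sol.reaction_rates[rx].sum() * dz for rx in REACTIONS
        )
        if s in sol.extra_sources:
            net_rx += float(np.sum(sol.extra_sources[s])) * dz
        top, bot = sol.boundary_fluxes[s]
        diff = top - bot
        denom = max(abs(diff), abs(net_rx), 1e-8)
        rows[s] = {
            "flux_difference": diff,
            "integrated_reaction": net_rx,
            "relative_closure": abs(diff + net_rx) / denom,
        }
    report = pd.DataFrame(rows).T
    # whole-column N budget: boundary N in + organic N release = N2 out
    n2_prod = 2.0 * sum(
        float(S.loc["N2", rx]) * sol.reaction_rates[rx].sum() * dz for rx in REACTIONS
    )
    orgn = -sum(
        float(S.loc["OrgN", rx]) * sol.reaction_rates[rx].sum() * dz for rx in REACTIONS
    )
    n_in = sum(sol.boundary_fluxes[s][0] - sol.boundary_fluxes[s][1] for s in ("NO3", "NH4"))
    report.attrs["nitrogen_budget"] = {
        "boundary_N_influx": n_in,
        "organic_N_release": orgn,
        "N2_production": n2_prod,
    }
    return report


def rmse_model_vs_data(sol: SteadyStateSolution, profile, species: str) -> float:
    """RMSE (uM) between the modeled profile, linearly interpolated to the
    measured depths, and the measurements."""
    depths = np.asarray(profile.depths, dtype=float)
    measured = np.asarray(profile.concentrations[species], dtype=float)
    ok = np.isfinite(measured)
    depths, measured = depths[ok], measured[ok]
    if depths.size == 0:
        raise ValueError("empty measured profile")
    model = np.interp(depths, sol.grid.depths, sol.concentrations[species])
    return float(np.sqrt(np.mean((model - measured) ** 2)))
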
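"""In-situ Gibbs energy, catabolic power supply and cell-specific energetics.

The thermodynamic drive of anammox at depth z is

    dGr(z) = dG0r(T) + R T ln Q(z),        Q = prod a_i^nu_i

with activities from porewater concentrations (unit coefficients or the
Davies equation at seawater ionic strength).  The catabolic power supplied
per unit sediment volume is the product of the reaction rate and |dGr|; the
per-cell quantities divide by local cell abundance and convert to proton
fluxes through the proton-translocation stoichiometry of the anammox
electron transport chain.

Standard-state constants (dG_f, dH_f at 25 degC / 1 bar) ship as a packaged
table; temperature is handled by the integrated van 't Hoff relation with
constant reaction enthalpy, and an optional user-supplied molar volume term
covers pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ThermoState",
    "PowerProfile",
    "CellEnergetics",
    "load_thermo_table",
    "standard_gibbs",
    "in_situ_gibbs",
    "power_supply",
    "cell_specific_rate",
    "proton_pumping_rate",
]

#: kJ mol-1 K-1
GAS_CONSTANT = 8.314e-3
T_REF = 298.15
#: seconds per year, for J yr-1 -> W
SECONDS_PER_YEAR = 3.154e7
AVOGADRO = 6.022e23
#: Debye-Hueckel A coefficient (kg^1/2 mol^-1/2), ~25 degC value
_DAVIES_A = 0.509


def load_thermo_table() -> pd.DataFrame:
    """Packaged formation constants (kJ mol-1, 25 degC / 1 bar), indexed by
    species label; N2 is the dissolved gas."""
    with resources.files("natzkit.data").joinpath("thermo_constants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="species")


@dataclass
class ThermoState:
    """In-situ thermodynamic conditions and the constants table."""

    T: float = 273.65  # kelvin
    P: float = 250.0  # bar
    ionic_strength: float = 0.7  # mol kg-1, seawater
    activity_model: str = "davies"  # "unit" | "davies"
    formation_energies: pd.DataFrame = field(default_factory=load_thermo_table)

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive kelvin")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.activity_model not in ("unit", "davies"):
            raise ValueError(f"unknown activity model {self.activity_model!r}")

    def activity_coefficient(self, species: str) -> float:
        """Single-ion activity coefficient; Davies reduces to 1 at I = 0."""
        if self.activity_model == "unit":
            return 1.0
        charge = float(self.formation_energies.loc[species, "charge"])
        I = self.ionic_strength
        if I == 0 or charge == 0:
            return 1.0
        sqrt_i = math.sqrt(I)
        log10_gamma = -_DAVIES_A * charge**2 * (sqrt_i / (1 + sqrt_i) - 0.3 * I)
        return 10.0**log10_gamma


def _check_species(reaction: dict[str, float], table: pd.DataFrame):
    missing = [s for s in reaction if s not in table.index]
    if missing:
        raise KeyError(f"no formation constants for species: {missing}")


def standard_gibbs(
    reaction: dict[str, float],
    thermo: ThermoState,
    delta_V: float = 0.0,
) -> float:
    """Standard Gibbs energy of reaction (kJ per mol reaction) at in-situ T, P.

    At 25 degC / 1 bar this is the plain stoichiometric sum of formation
    energies.  Temperature correction uses the integrated van 't Hoff
    relation with T-independent reaction enthalpy,

        dG0(T) = dG0(Tref) * T/Tref + dH0 * (1 - T/Tref),

    and pressure adds ``delta_V * (P - 1)`` for a user-supplied molar volume
    change (cm3 mol-1, converted to kJ; default 0).
    """
    table = thermo.formation_energies
    _check_species(reaction, table)
    dg0 = sum(nu * table.loc[s, "dG_f_kJ_mol"] for s, nu in reaction.items())
    dh0 = sum(nu * table.loc[s, "dH_f_kJ_mol"] for s, nu in reaction.items())
    T = thermo.T
    dg_T = dg0 * T / T_REF + dh0 * (1.0 - T / T_REF)
    # 1 cm3 bar = 0.1 J
    dg_P = delta_V * (thermo.P - 1.0) * 0.1 * 1e-3
    return float(dg_T + dg_P)


def in_situ_gibbs(
    reaction: dict[str, float],
    thermo: ThermoState,
    concentrations: dict[str, float | np.ndarray],
    concentration_floor: float = 1e-3,
    delta_V: float = 0.0,
) -> float | np.ndarray:
    """In-situ Gibbs energy dGr = dG0r + RT ln Q, normalized per mol NH4+.

    ``concentrations`` are uM (converted to mol/kg assuming dilute seawater);
    H2O and H+ activities: water is taken at unit activity, H+ at seawater
    pH 7.7 unless supplied.  Zero or negative concentrations are replaced by
    ``concentration_floor`` (uM); pass ``None`` to raise instead.
    """
    table = thermo.formation_energies
    _check_species(reaction, table)
    dg0 = standard_gibbs(reaction, thermo, delta_V=delta_V)

    ln_q = 0.0
    for s, nu in reaction.items():
        if s == "H2O":
            continue
        if s == "H+":
            activity = 10.0**-7.7 if s not in concentrations else (
                np.asarray(concentrations[s], float) * 1e-6
            )
        else:
            if s not in concentrations:
                raise KeyError(f"concentration required for {s}")
            c = np.asarray(concentrations[s], dtype=float)
            if np.any(c <= 0):
                if concentration_floor is None:
                    raise ValueError(f"non-positive concentration for {s}")
                c = np.where(c <= 0, concentration_floor, c)
            activity = c * 1e-6 * thermo.activity_coefficient(s)
        ln_q = ln_q + nu * np.log(activity)

    dgr = dg0 + GAS_CONSTANT * thermo.T * ln_q
    n_nh4 = abs(reaction.get("NH4+", 0.0))
    if n_nh4 > 0:
        dgr = dgr / n_nh4
    return float(dgr) if np.ndim(dgr) == 0 else dgr


@dataclass
class PowerProfile:
    """Catabolic power supply per unit bulk sediment volume."""

    depth: np.ndarray  # cm
    gibbs_energy: np.ndarray  # kJ per mol NH4+
    rate: np.ndarray  # umol NH4+ cm-3 yr-1
    power: np.ndarray  # J cm-3 yr-1
    source: str = "modeled"

    @property
    def power_W_cm3(self) -> np.ndarray:
        return self.power / SECONDS_PER_YEAR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_cm": self.depth,
                "gibbs_kJ_mol_NH4": self.gibbs_energy,
                "rate_umol_cm3_yr": self.rate,
                "power_J_cm3_yr": self.power,
                "power_W_cm3": self.power_W_cm3,
                "source": self.source,
            }
        )


def power_supply(
    rate_profile: np.ndarray,
    gibbs_profile: np.ndarray,
    depth: np.ndarray,
    source: str = "modeled",
) -> PowerProfile:
    """Power(z) = rate(z) * |dGr(z)|: umol cm-3 yr-1 times kJ mol-1 gives
    1e-3 J cm-3 yr-1.  Exergonic (negative) dGr yields positive power; any
    endergonic depths contribute zero."""
    depth = np.asarray(depth, dtype=float)
    rate = np.asarray(rate_profile, dtype=float)
    gibbs = np.asarray(gibbs_profile, dtype=float)
    if not (depth.shape == rate.shape == gibbs.shape):
        raise ValueError("rate, Gibbs-energy and depth grids must match")
    exergonic = np.clip(-gibbs, 0.0, None)
    power = rate * exergonic * 1e-3
    return PowerProfile(depth=depth, gibbs_energy=gibbs, rate=rate, power=power,
                        source=source)


@dataclass
class CellEnergetics:
    """Per-cell metabolic and proton-pumping rates."""

    cell_rate: float | np.ndarray  # fmol NH4+ cell-1 d-1
    proton_rate: float | np.ndarray  # protons cell-1 s-1
    protons_per_NH4: float = 4.0
    cell_power: float | np.ndarray | None = None  # W cell-1


def cell_specific_rate(
    rate,
    abundance,
    rho_dry: float = 2.5,
    porosity: float = 0.8,
    abundance_per: str = "g",
):
    """Cell-specific metabolic rate in fmol NH4+ cell-1 d-1.

    ``rate`` is a bulk volumetric anammox rate (umol NH4+ cm-3 yr-1);
    ``abundance`` is in cells per g dry sediment (``abundance_per='g'``,
    converted to cells per cm3 bulk via ``rho_dry * (1 - porosity)``) or
    already per cm3 bulk (``abundance_per='cm3'``).
    """
    rate = np.asarray(rate, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if np.any(abundance <= 0):
        raise ValueError("cell abundance must be positive")
    if abundance_per == "g":
        cells_cm3 = abundance * rho_dry * (1.0 - porosity)
    elif abundance_per == "cm3":
        cells_cm3 = abundance
    else:
        raise ValueError("abundance_per must be 'g' or 'cm3'")
    per_cell = rate / cells_cm3  # umol cell-1 yr-1
    out = per_cell * 1e9 / 365.25  # fmol cell-1 d-1
    return float(out) if out.ndim == 0 else out


def proton_pumping_rate(cell_rate, n_H: float = 4.0):
    """Protons pumped per cell per second for a given cell-specific rate
    (fmol NH4+ cell-1 d-1), assuming ``n_H`` translocated protons per NH4+
    turned over."""
    cell_rate = np.asarray(cell_rate, dtype=float)
    if np.any(cell_rate < 0):
        raise ValueError("cell rate must be >= 0")
    if n_H <= 0:
        raise ValueError("n_H must be positive")
    out = cell_rate * 1e-15 * AVOGADRO * n_H / 86400.0
    return float(out) if out.ndim == 0 else out
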
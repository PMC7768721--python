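"""Quality control, NATZ detection and diffusive-flux analysis of porewater
nitrate/ammonium profiles.

The nitrate-ammonium transition zone (NATZ) is bracketed by the depth where
downward-diffusing NO3- falls below a detection-scale threshold and the
shallowest depth where upward-diffusing NH4+ is still detectable; both
crossings are located by linear interpolation between bracketing samples.
Diffusive fluxes into the zone follow Fick's first law with
tortuosity-corrected diffusivity, with the concentration gradient estimated
by least squares over the samples nearest the zone boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reaction_transport import tortuosity_corrected_diffusivity

logger = logging.getLogger(__name__)

__all__ = [
    "PorewaterProfile",
    "NatzInterval",
    "QCResult",
    "SiteCompilation",
    "NoNatzError",
    "qc_filter",
    "detect_natz",
    "diffusive_flux",
    "classify_efflux",
    "summarize_sites",
    "sediment_age",
]

DEFAULT_THRESHOLD_UM = 2.0
DEFAULT_POROSITY = 0.8


class NoNatzError(ValueError):
    """The profile passed QC but shows no detectable NH4+ anywhere."""


@dataclass
class PorewaterProfile:
    """A measured porewater depth-series for one site.

    ``concentrations`` maps species name (NO3, NH4, optionally O2/Mn2/DIC)
    to a series in uM aligned with ``depths`` (cm below seafloor); missing
    values are NaN, never zero.
    """

    site_id: str
    depths: np.ndarray
    concentrations: dict[str, np.ndarray]
    water_depth: float = np.nan  # m
    porosity: float | np.ndarray = DEFAULT_POROSITY
    temperature: float = np.nan  # degC
    detection_limit: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.size and np.any(np.diff(self.depths) <= 0):
            order = np.argsort(self.depths, kind="stable")
            if np.unique(self.depths).size != self.depths.size:
                raise ValueError(f"{self.site_id}: duplicate depths")
            logger.info("%s: depth rows were unsorted; sorting by depth", self.site_id)
            self.depths = self.depths[order]
            self.concentrations = {
                k: np.asarray(v, dtype=float)[order] for k, v in self.concentrations.items()
            }
        else:
            self.concentrations = {
                k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
            }
        for name, series in self.concentrations.items():
            if series.shape != self.depths.shape:
                raise ValueError(f"{self.site_id}: {name} series length mismatch")
            if np.any(series[np.isfinite(series)] < 0):
                raise ValueError(f"{self.site_id}: negative {name} concentrations")

    def series(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Depths and values with NaNs dropped."""
        v = self.concentrations[species]
        ok = np.isfinite(v)
        return self.depths[ok], v[ok]


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class NatzInterval:
    """Detected transition-zone interval and its boundary fluxes
    (umol cm-2 yr-1, positive downward)."""

    top: float
    bottom: float
    no3_flux_in: float = np.nan
    nh4_flux_in: float = np.nan
    nh4_efflux_above: bool | None = None
    method_notes: str = ""

    @property
    def thickness(self) -> float:
        return self.bottom - self.top

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top + self.bottom)


def qc_filter(
    profile: PorewaterProfile,
    min_points: int = 6,
    depletion_threshold: float = DEFAULT_THRESHOLD_UM,
) -> QCResult:
    """Gate a profile: enough data points and a reached nitrate-depletion
    depth; profiles failing either gate carry reason codes."""
    if "NO3" not in profile.concentrations:
        raise ValueError(f"{profile.site_id}: profile has no NO3 series")
    _, no3 = profile.series("NO3")
    reasons = []
    if no3.size < min_points:
        reasons.append("too_few_points")
    if no3.size == 0 or no3.min() >= depletion_threshold:
        reasons.append("no_depletion")
    return QCResult(passed=not reasons, reasons=reasons)


def _first_downward_crossing(z, v, threshold):
    """Shallowest depth where v drops below threshold, by linear
    interpolation between the bracketing samples."""
    below = v < threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(z[0])
    z0, z1, v0, v1 = z[i - 1], z[i], v[i - 1], v[i]
    if v0 == v1:
        return float(z1)
    return float(z0 + (v0 - threshold) * (z1 - z0) / (v0 - v1))


def detect_natz(
    profile: PorewaterProfile,
    threshold: float = DEFAULT_THRESHOLD_UM,
    threshold_nh4: float | None = None,
) -> NatzInterval:
    """Locate the NATZ from the NO3- depletion depth and the shallowest
    detectable NH4+.

    The NO3- crossing is the first downward crossing below ``threshold``;
    the NH4+ boundary is the first crossing below ``threshold_nh4`` scanning
    upward from the bottom of the profile (i.e. the shallowest extent of
    detectable ammonium).  The interval is the ordered pair of the two
    depths; a zero-thickness interval is legitimate.
    """
    if "NH4" not in profile.concentrations:
        raise ValueError(f"{profile.site_id}: profile has no NH4 series")
    thr_nh4 = threshold if threshold_nh4 is None else threshold_nh4
    z_no3s, no3 = profile.series("NO3")
    z_nh4s, nh4 = profile.series("NH4")
    z_no3 = _first_downward_crossing(z_no3s, no3, threshold)
    if z_no3 is None:
        raise NoNatzError(f"{profile.site_id}: NO3 never falls below {threshold} uM")
    if not (nh4 >= thr_nh4).any():
        raise NoNatzError(f"{profile.site_id}: NH4 never reaches {thr_nh4} uM")
    # scan upward from depth: mirror the series and find the crossing
    z_nh4 = _first_downward_crossing(z_nh4s[::-1], nh4[::-1], thr_nh4)
    if z_nh4 is None:  # NH4 detectable everywhere, zone reaches the surface
        z_nh4 = float(z_nh4s[0])
    top, bottom = sorted((z_no3, z_nh4))
    return NatzInterval(
        top=top,
        bottom=bottom,
        method_notes=f"threshold_no3={threshold}uM threshold_nh4={thr_nh4}uM",
    )


def diffusive_flux(
    profile: PorewaterProfile,
    species: str,
    interval: NatzInterval,
    boundary: str,
    D0: float,
    porosity: float | None = None,
    n_fit_points: int = 3,
) -> float:
    """Fickian diffusive flux J = -phi * Ds * dC/dz toward the NATZ boundary
    (umol cm-2 yr-1, positive downward).

    The gradient is a least-squares slope over the ``n_fit_points`` samples
    nearest the interval edge on the stated side (``above_natz`` uses the
    samples at or above ``interval.top``; ``below_natz`` at or below
    ``interval.bottom``); uM converts to umol cm-3 via 1e-3.
    """
    if boundary not in ("above_natz", "below_natz"):
        raise ValueError("boundary must be 'above_natz' or 'below_natz'")
    z, v = profile.series(species)
    if boundary == "above_natz":
        mask = z <= interval.top
        zs, vs = z[mask][-n_fit_points:], v[mask][-n_fit_points:]
    else:
        mask = z >= interval.bottom
        zs, vs = z[mask][:n_fit_points], v[mask][:n_fit_points]
    if zs.size < n_fit_points:
        raise ValueError(
            f"{profile.site_id}: only {zs.size} points {boundary.replace('_', ' ')} "
            f"(need {n_fit_points})"
        )
    slope = np.polyfit(zs, vs, 1)[0]  # uM per cm
    phi = profile.porosity if porosity is None else porosity
    phi = float(np.mean(phi))
    ds = tortuosity_corrected_diffusivity(D0, phi)
    return float(-phi * ds * slope * 1e-3)


def classify_efflux(
    profile: PorewaterProfile,
    interval: NatzInterval,
    threshold: float = DEFAULT_THRESHOLD_UM,
) -> bool | None:
    """True if ammonium escapes above the NATZ (any detection at or above
    ``interval.top`` — a zone whose detectable ammonium reaches the
    seafloor counts), False if not, None when no measurements exist at or
    above the zone top (indeterminate)."""
    z, nh4 = profile.series("NH4")
    above = z <= interval.top
    if not above.any():
        return None
    return bool((nh4[above] > threshold).any())


@dataclass
class SiteCompilation:
    """Processed multi-site collection: (profile, interval-or-None, QC)."""

    sites: list[tuple[PorewaterProfile, NatzInterval | None, QCResult]]

    @property
    def n_pass(self) -> int:
        return sum(1 for _, itv, qc in self.sites if qc.passed and itv is not None)

    @property
    def n_no_efflux(self) -> int:
        return sum(
            1
            for _, itv, qc in self.sites
            if qc.passed and itv is not None and itv.nh4_efflux_above is False
        )


def summarize_sites(compilation: SiteCompilation) -> dict:
    """Counts, the no-efflux percentage, and per-site tables of NATZ depth
    and boundary fluxes against water depth."""
    n_pass = compilation.n_pass
    n_no_efflux = compilation.n_no_efflux
    if n_pass == 0:
        percent = np.nan
    else:
        percent = round(100.0 * n_no_efflux / n_pass)
    rows = []
    for prof, itv, qc in compilation.sites:
        if not qc.passed or itv is None:
            continue
        rows.append(
            {
                "site_id": prof.site_id,
                "water_depth_m": prof.water_depth,
                "natz_top_cm": itv.top,
                "natz_bottom_cm": itv.bottom,
                "natz_mid_cm": itv.midpoint,
                "no3_flux_in": itv.no3_flux_in,
                "nh4_flux_in": itv.nh4_flux_in,
                "nh4_efflux_above": itv.nh4_efflux_above,
            }
        )
    return {
        "n_sites": len(compilation.sites),
        "n_pass": n_pass,
        "n_no_efflux": n_no_efflux,
        "percent_no_efflux": percent,
        "site_table": pd.DataFrame(rows),
    }


def sediment_age(depth: float, sedimentation_rate: float) -> float:
    """Age (years) of sediment at ``depth`` cm for a constant sedimentation
    rate in cm per kiloyear."""
    if sedimentation_rate <= 0:
        raise ValueError("sedimentation rate must be positive")
    return depth / sedimentation_rate * 1000.0
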
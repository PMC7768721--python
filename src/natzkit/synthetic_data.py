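"""Synthetic-data generators with emitted ground truth.

Every input the analysis pipeline consumes can be generated here: a forward-
modeled sediment core with measurement noise, anammox cell-abundance
profiles, multi-site nitrate/ammonium profile collections with a controlled
no-efflux fraction, and genome-coverage tracks with a controlled
origin:terminus ratio.  Each generator returns the synthetic observations
together with a truth object holding everything a recovery test needs; all
randomness flows through one seeded generator per call.

The default core emulates a pelagic ridge-flank setting: a 3 m core with an
oxic zone whose O2 is depleted within the upper ~0.4-1.2 m, nitrate depleted
shortly below, a deep ammonium source diffusing upward, and Mn(II) building
up beneath the oxygen-depletion depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import reaction_transport as rt
from .profile_analysis import NatzInterval, PorewaterProfile, detect_natz
from .replication_index import CoverageTrack

__all__ = [
    "SyntheticCoreSpec",
    "SyntheticTruth",
    "reference_boundary_conditions",
    "make_core",
    "make_abundance_profile",
    "make_site_collection",
    "make_coverage",
    "fit_k_amx",
]

#: default sampling scheme: 5-cm spacing over the upper half meter,
#: 25-cm spacing below, to the base of a 3-m core
DEFAULT_SAMPLE_DEPTHS = tuple(np.arange(5.0, 51.0, 5.0)) + tuple(
    np.arange(75.0, 301.0, 25.0)
)

DEFAULT_BOUNDARY_VALUES = {
    "O2_top_uM": 300.0,
    "NO3_top_uM": 15.0,
    "NH4_top_uM": 0.0,
    "NH4_bottom_uM": 80.0,
    "Mn2_top_uM": 0.0,
    "DIC_top_uM": 2200.0,
    "TOC_flux": 2.8,  # umol C cm-2 yr-1 deposition
    "MnO2_flux": 0.03,  # umol cm-2 yr-1 deposition
}


def reference_boundary_conditions(values: dict[str, float] | None = None):
    """Boundary-condition set for the reference core: fixed bottom-water
    concentrations at the sediment-water interface, deposition fluxes for
    the solids, a fixed deep ammonium source, and zero-gradient elsewhere."""
    v = dict(DEFAULT_BOUNDARY_VALUES)
    if values:
        unknown = set(values) - set(v)
        if unknown:
            raise rt.ConfigurationError(f"unknown boundary values: {sorted(unknown)}")
        v.update(values)
    B = rt.BoundaryCondition
    return [
        B("O2", "top", "fixed_concentration", v["O2_top_uM"]),
        B("O2", "bottom", "zero_gradient"),
        B("NO3", "top", "fixed_concentration", v["NO3_top_uM"]),
        B("NO3", "bottom", "zero_gradient"),
        B("NH4", "top", "fixed_concentration", v["NH4_top_uM"]),
        B("NH4", "bottom", "fixed_concentration", v["NH4_bottom_uM"]),
        B("Mn2", "top", "fixed_concentration", v["Mn2_top_uM"]),
        B("Mn2", "bottom", "zero_gradient"),
        B("DIC", "top", "fixed_concentration", v["DIC_top_uM"]),
        B("DIC", "bottom", "zero_gradient"),
        B("TOC", "top", "fixed_flux", v["TOC_flux"]),
        B("TOC", "bottom", "zero_gradient"),
        B("MnO2", "top", "fixed_flux", v["MnO2_flux"]),
        B("MnO2", "bottom", "zero_gradient"),
    ]


@dataclass
class SyntheticCoreSpec:
    """Everything needed to forward-model and sample one synthetic core."""

    domain_length: float = 300.0
    n_cells: int = 300  # 1-cm cells align grid faces with the 10-cm mixed-layer base
    porosity_surface: float = 0.85
    porosity_deep: float = 0.75
    attenuation: float = 50.0
    temperature: float = 0.5  # degC
    pressure: float = 250.0  # bar
    burial_velocity: float = 2e-3  # cm yr-1 (2 cm per ky)
    Db0: float = 0.1
    zbio: float = 10.0
    network: rt.ReactionNetwork = field(default_factory=rt.ReactionNetwork)
    boundary_values: dict[str, float] = field(default_factory=dict)
    noise_sd: float | dict[str, float] = 1.0  # uM, per solute
    sample_depths: tuple[float, ...] = DEFAULT_SAMPLE_DEPTHS
    seed: int = 0
    site_id: str = "synthetic-core"

    def build_grid(self) -> rt.SedimentGrid:
        return rt.build_grid(
            self.domain_length,
            self.n_cells,
            self.porosity_surface,
            self.porosity_deep,
            self.attenuation,
            T=self.temperature,
            P=self.pressure,
            w=self.burial_velocity,
            Db0=self.Db0,
            zbio=self.zbio,
        )

    def noise_for(self, species: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(species, 0.0))
        return float(self.noise_sd)


@dataclass
class SyntheticTruth:
    """Generator ground truth accompanying every synthetic dataset."""

    params: dict[str, Any]
    solution: rt.SteadyStateSolution | None = None
    true_profiles: dict[str, np.ndarray] | None = None
    true_r6: np.ndarray | None = None
    true_natz: NatzInterval | None = None
    true_fluxes: dict[str, float] | None = None
    true_abundance: np.ndarray | None = None
    labels: list[dict[str, Any]] | None = None


def make_core(spec: SyntheticCoreSpec) -> tuple[PorewaterProfile, SyntheticTruth]:
    """Forward-model a core, sample it, and add independent Gaussian noise
    (clipped at zero).  The truth carries the full solution, the noiseless
    sampled profiles, the anammox rate profile, the NATZ detected on the
    noiseless model grid, and the model boundary fluxes."""
    grid = spec.build_grid()
    depths = np.asarray(spec.sample_depths, dtype=float)
    if np.any((depths < 0) | (depths > spec.domain_length)):
        raise rt.ConfigurationError("sample depths outside the model domain")
    species = rt.default_species()
    bcs = reference_boundary_conditions(spec.boundary_values)
    sol = rt.solve_steady_state(grid, species, spec.network, bcs)

    rng = np.random.default_rng(spec.seed)
    true_profiles = {}
    observed = {}
    for name in rt.SOLUTES:
        model = np.interp(depths, grid.depths, sol.concentrations[name])
        true_profiles[name] = model
        sd = spec.noise_for(name)
        noisy = model + rng.normal(0.0, sd, size=model.shape) if sd > 0 else model.copy()
        observed[name] = np.clip(noisy, 0.0, None)

    model_profile = PorewaterProfile(
        site_id=spec.site_id + "-truth",
        depths=grid.depths.copy(),
        concentrations={n: sol.concentrations[n].copy() for n in rt.SOLUTES},
        porosity=float(np.mean(grid.porosity)),
        temperature=spec.temperature,
    )
    true_natz = detect_natz(model_profile)
    profile = PorewaterProfile(
        site_id=spec.site_id,
        depths=depths,
        concentrations=observed,
        porosity=float(np.mean(grid.porosity)),
        temperature=spec.temperature,
    )
    truth = SyntheticTruth(
        params={"spec": spec},
        solution=sol,
        true_profiles=true_profiles,
        true_r6=sol.reaction_rates["R6"].copy(),
        true_natz=true_natz,
        true_fluxes={s: sol.boundary_fluxes[s][0] for s in rt.SOLUTES},
    )
    return profile, truth


def make_abundance_profile(
    natz: NatzInterval,
    sample_depths,
    background: float = 1e2,  # cells per g dry sediment (detection floor)
    peak: float = 1e6,
    width: float = 30.0,  # cm
    noise_sd_log10: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Anammox-abundance profile: a log-scale Gaussian bump centered in the
    NATZ over a constant background, with multiplicative lognormal noise.
    Defaults span four orders of magnitude, the increase consistently seen
    for anammox bacteria entering their niche."""
    if not peak >= background > 0:
        raise ValueError("require peak >= background > 0")
    if width <= 0:
        raise ValueError("width must be positive")
    depths = np.asarray(sample_depths, dtype=float)
    rng = np.random.default_rng(seed)
    log_bg, log_peak = np.log10(background), np.log10(peak)
    bump = np.exp(-0.5 * ((depths - natz.midpoint) / width) ** 2)
    log_true = log_bg + (log_peak - log_bg) * bump
    true = 10.0**log_true
    noisy = 10.0 ** (log_true + rng.normal(0.0, noise_sd_log10, size=depths.shape))
    truth = SyntheticTruth(
        params={
            "background": background,
            "peak": peak,
            "width": width,
            "noise_sd_log10": noise_sd_log10,
            "seed": seed,
            "center": natz.midpoint,
        },
        true_abundance=true,
    )
    return noisy, truth


def _site_template(rng, no_efflux: bool, n_points: int, threshold: float = 2.0):
    """Piecewise-linear NO3/NH4 shape with a randomized depletion depth in
    the observed global range (~1.3-460 cm)."""
    z_dep = float(np.exp(rng.uniform(np.log(1.3), np.log(460.0))))
    no3_top = rng.uniform(10.0, 40.0)
    gap = z_dep * rng.uniform(0.05, 0.3)
    nh4_deep = rng.uniform(20.0, 100.0)
    z_max = z_dep + gap + z_dep * rng.uniform(0.8, 1.5)
    depths = np.linspace(0.0, z_max, n_points)
    no3 = np.clip(no3_top * (1.0 - depths / z_dep), 0.0, None)
    z_nh4_onset = z_dep + gap
    nh4 = np.clip(
        nh4_deep * (depths - z_nh4_onset) / max(z_max - z_nh4_onset, 1e-6), 0.0, None
    )
    if not no_efflux:
        # ammonium escaping the zone: a detectable tail above the NATZ
        tail = rng.uniform(2.0 * threshold, 8.0 * threshold)
        nh4 = nh4 + tail * np.exp(-depths / max(z_dep, 1.0))
    noise = rng.normal(0.0, 0.5, size=(2, n_points))
    no3 = np.clip(no3 + noise[0], 0.0, None)
    nh4_noise = np.clip(nh4 + noise[1], 0.0, None)
    if no_efflux:
        # keep the no-efflux label exact: noise must not fake a detection
        above = depths < z_dep
        nh4_noise[above] = np.minimum(nh4_noise[above], 0.8 * threshold)
    return depths, no3, nh4_noise, z_dep


def make_site_collection(
    n_sites: int = 67,
    no_efflux_fraction: float = 0.84,
    sparsity: int = 12,
    sparse_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[PorewaterProfile], SyntheticTruth]:
    """A multi-site profile compilation with known efflux labels.

    Each site is drawn no-efflux with probability ``no_efflux_fraction``;
    a ``sparse_fraction`` of sites get only 5 data points so they fail the
    six-point quality gate downstream.  Labels are emitted in the truth.
    """
    if not 0.0 <= no_efflux_fraction <= 1.0:
        raise ValueError("no_efflux_fraction must lie in [0, 1]")
    if sparsity < 2:
        raise ValueError("sparsity must be >= 2")
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for i in range(n_sites):
        no_efflux = bool(rng.random() < no_efflux_fraction)
        sparse = bool(rng.random() < sparse_fraction)
        n_points = 5 if sparse else sparsity
        depths, no3, nh4, z_dep = _site_template(rng, no_efflux, n_points)
        profiles.append(
            PorewaterProfile(
                site_id=f"site-{i:03d}",
                depths=depths,
                concentrations={"NO3": no3, "NH4": nh4},
                water_depth=float(rng.uniform(900.0, 5200.0)),
            )
        )
        labels.append(
            {"site_id": f"site-{i:03d}", "no_efflux": no_efflux, "sparse": sparse,
             "z_depletion": z_dep}
        )
    truth = SyntheticTruth(
        params={
            "n_sites": n_sites,
            "no_efflux_fraction": no_efflux_fraction,
            "sparsity": sparsity,
            "sparse_fraction": sparse_fraction,
            "seed": seed,
        },
        labels=labels,
    )
    return profiles, truth


def make_coverage(
    genome_length: int = 3_000_000,
    ori_ter_ratio: float = 1.32,
    n_scaffolds: int = 71,
    noise_model: str = "none",
    mean_depth: float = 20.0,
    window_size: int = 5000,
    step: int = 100,
    seed: int = 0,
) -> tuple[CoverageTrack, SyntheticTruth]:
    """Genome-coverage track for a population replicating bidirectionally
    from a single origin.

    Expected per-base depth is log-linear from the origin (position 0,
    maximum) to the terminus (mid-genome, minimum) with max/min equal to
    ``ori_ter_ratio``, scaled to the requested mean depth.  The genome is
    cut into ``n_scaffolds`` contiguous scaffolds and summarized in sliding
    windows; ``noise_model='poisson'`` draws the per-base depth from a
    Poisson law around its expectation (the counting noise of independent
    read sampling), which overlapping windows then average.
    """
    if ori_ter_ratio < 1.0:
        raise ValueError("ori_ter_ratio must be >= 1")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if noise_model not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    pos = np.arange(genome_length)
    # circular distance to the origin, 0 at ori, 1 at terminus
    d = np.minimum(pos, genome_length - pos) / (genome_length / 2.0)
    log2_depth = (1.0 - d) * np.log2(ori_ter_ratio)
    depth = 2.0**log2_depth
    depth *= mean_depth / depth.mean()
    if noise_model == "poisson":
        depth = rng.poisson(depth).astype(float)

    # contiguous scaffolds of near-equal length
    edges = np.linspace(0, genome_length, n_scaffolds + 1).astype(int)
    frames, covs = [], []
    csum = np.concatenate([[0.0], np.cumsum(depth)])
    for k in range(n_scaffolds):
        lo, hi = edges[k], edges[k + 1]
        if hi - lo < window_size:
            continue
        starts = np.arange(lo, hi - window_size + 1, step)
        means = (csum[starts + window_size] - csum[starts]) / window_size
        frames.append(
            pd.DataFrame(
                {"scaffold": f"scaffold_{k:03d}", "start": starts - lo,
                 "end": starts - lo + window_size}
            )
        )
        covs.append(means)
    coverage = np.concatenate(covs)
    track = CoverageTrack(
        windows=pd.concat(frames, ignore_index=True),
        coverage=coverage,
        window_size=window_size,
        step=step,
    )
    truth = SyntheticTruth(
        params={
            "genome_length": genome_length,
            "ori_ter_ratio": ori_ter_ratio,
            "n_scaffolds": n_scaffolds,
            "noise_model": noise_model,
            "mean_depth": mean_depth,
            "seed": seed,
        }
    )
    return track, truth


def fit_k_amx(
    profile: PorewaterProfile,
    spec: SyntheticCoreSpec,
    bounds: tuple[float, float] = (1e-3, 10.0),
) -> float:
    """Recover the anammox rate constant from an observed core by 1D least
    squares: minimize the summed squared NO3+NH4 misfit over log10(k_amx),
    re-solving the forward model at each trial value."""
    grid = spec.build_grid()
    species = rt.default_species()
    bcs = reference_boundary_conditions(spec.boundary_values)
    z_no3, no3 = profile.series("NO3")
    z_nh4, nh4 = profile.series("NH4")
    warm: dict[str, np.ndarray] = {}

    def objective(log10_k: float) -> float:
        net = rt.ReactionNetwork(
            **{
                f: getattr(spec.network, f)
                for f in (
                    "k_TOC K_O2 K_NO3 K_MnO2 Kin_O2 Kin_NO3 k_nit k_mnox "
                    "r_NC rho_dry".split()
                )
            },
            k_amx=10.0**log10_k,
        )
        sol = rt.solve_steady_state(
            grid, species, net, bcs, initial_state=warm or None
        )
        warm.update(sol.concentrations)
        m_no3 = np.interp(z_no3, grid.depths, sol.concentrations["NO3"])
        m_nh4 = np.interp(z_nh4, grid.depths, sol.concentrations["NH4"])
        return float(np.sum((m_no3 - no3) ** 2) + np.sum((m_nh4 - nh4) ** 2))

    res = minimize_scalar(
        objective,
        bounds=(np.log10(bounds[0]), np.log10(bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0**res.x)
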
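"""Readers and writers for the package's tabular formats.

Porewater profiles travel as wide- or long-format CSV; model solutions as a
per-depth CSV with a JSON sidecar of fluxes and convergence metadata;
genome coverage as bedGraph-like TSV (scaffold, start, end, depth; 0-based
half-open) or per-base depth TSV with a (name, length) scaffold table.
All writers emit full double precision so a read-back reproduces the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .profile_analysis import PorewaterProfile
from .reaction_transport import SOLUTES, SteadyStateSolution
from .replication_index import CoverageTrack, windows_from_depth

__all__ = [
    "read_profile_table",
    "write_profile_table",
    "write_solution",
    "read_coverage",
    "write_coverage",
    "write_manifest",
    "InputError",
]

_WIDE_CONC_COLS = {f"{s}_uM": s for s in SOLUTES}
_META_COLS = ("water_depth_m", "temperature_C", "porosity")


class InputError(ValueError):
    """Malformed or inconsistent input table."""


def _profile_from_group(site_id: str, sub: pd.DataFrame, dialect: str) -> PorewaterProfile:
    if dialect == "wide":
        conc = {
            s: pd.to_numeric(sub[col], errors="coerce").to_numpy(dtype=float)
            for col, s in _WIDE_CONC_COLS.items()
            if col in sub.columns
        }
    else:
        pivot = sub.pivot_table(
            index="depth_cm", columns="species", values="concentration_uM", aggfunc="first"
        ).reindex(sub["depth_cm"].unique())
        conc = {s: pivot[s].to_numpy(dtype=float) for s in pivot.columns}
        sub = sub.drop_duplicates("depth_cm")
    if not conc:
        raise InputError(f"{site_id}: no concentration columns found")
    depths = pd.to_numeric(sub["depth_cm"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(depths)):
        bad = list(np.nonzero(~np.isfinite(depths))[0] + 1)
        raise InputError(f"{site_id}: non-numeric depth in rows {bad}")
    meta = {}
    for col in _META_COLS:
        if col in sub.columns and sub[col].notna().any():
            meta[col] = float(sub[col].dropna().iloc[0])
    try:
        return PorewaterProfile(
            site_id=str(site_id),
            depths=depths,
            concentrations=conc,
            water_depth=meta.get("water_depth_m", np.nan),
            temperature=meta.get("temperature_C", np.nan),
            porosity=meta.get("porosity", 0.8),
        )
    except ValueError as exc:
        raise InputError(str(exc)) from exc


def read_profile_table(path, dialect: str = "wide") -> dict[str, PorewaterProfile]:
    """Read porewater profiles grouped by ``site_id``.

    Wide dialect: columns ``site_id`` (optional for single-site files),
    ``depth_cm`` and ``<species>_uM``; long dialect: ``site_id``,
    ``depth_cm``, ``species``, ``concentration_uM``.  Rows are sorted by
    depth per site; duplicate depths are an error; missing values stay
    missing.  Site metadata travels in optional constant columns
    (water_depth_m, temperature_C, porosity).
    """
    if dialect not in ("wide", "long"):
        raise InputError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    table = pd.read_csv(path)
    required = {"depth_cm"} | ({"species", "concentration_uM"} if dialect == "long" else set())
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"{path.name}: missing columns {sorted(missing)}")
    if "site_id" not in table.columns:
        table["site_id"] = path.stem
    return {
        str(site): _profile_from_group(str(site), sub, dialect)
        for site, sub in table.groupby("site_id", sort=False)
    }


def write_profile_table(profiles, path, dialect: str = "wide") -> None:
    """Inverse of :func:`read_profile_table`; accepts a profile, a list or a
    mapping."""
    if isinstance(profiles, PorewaterProfile):
        profiles = [profiles]
    elif isinstance(profiles, dict):
        profiles = list(profiles.values())
    rows = []
    for prof in profiles:
        for i, depth in enumerate(prof.depths):
            base = {"site_id": prof.site_id, "depth_cm": depth}
            if np.isfinite(prof.water_depth):
                base["water_depth_m"] = prof.water_depth
            if np.isfinite(prof.temperature):
                base["temperature_C"] = prof.temperature
            base["porosity"] = float(np.mean(prof.porosity))
            if dialect == "wide":
                for s, series in prof.concentrations.items():
                    base[f"{s}_uM"] = series[i]
                rows.append(base)
            else:
                for s, series in prof.concentrations.items():
                    rows.append({**base, "species": s, "concentration_uM": series[i]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_solution(sol: SteadyStateSolution, outdir) -> tuple[Path, Path]:
    """Write the per-depth solution CSV and its JSON sidecar (boundary
    fluxes, residual, convergence metadata)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "solution.csv"
    sol.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "boundary_fluxes_umol_cm2_yr": {
            s: {"top": top, "bottom": bot} for s, (top, bot) in sol.boundary_fluxes.items()
        },
        "residual_norm": sol.residual_norm,
        "converged": sol.converged,
        "iterations": sol.iterations,
        "n_cells": sol.grid.n_cells,
        "domain_length_cm": sol.grid.domain_length,
    }
    json_path = outdir / "solution.json"
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def read_coverage(
    path,
    lengths_path=None,
    window_size: int = 5000,
    step: int = 100,
) -> CoverageTrack:
    """Read a coverage track.

    A four-column TSV (scaffold, start, end, depth) is taken as
    ready-made windows; a three-column TSV (scaffold, pos, depth) is
    per-base depth and requires ``lengths_path``, a (name, length) TSV, to
    build sliding windows.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    table = pd.read_csv(path, sep="\t")
    cols = set(table.columns)
    if {"scaffold", "start", "end", "depth"}.issubset(cols):
        windows = table[["scaffold", "start", "end"]].reset_index(drop=True)
        sizes = (windows["end"] - windows["start"]).to_numpy()
        return CoverageTrack(
            windows=windows,
            coverage=table["depth"].to_numpy(dtype=float),
            window_size=int(sizes.max()) if sizes.size else window_size,
            step=step,
        )
    if {"scaffold", "pos", "depth"}.issubset(cols):
        if lengths_path is None:
            raise InputError("per-base depth input needs a scaffold-lengths table")
        lengths = pd.read_csv(lengths_path, sep="\t")
        if not {"name", "length"}.issubset(lengths.columns):
            raise InputError("scaffold-lengths table needs columns (name, length)")
        length_map = dict(zip(lengths["name"].astype(str), lengths["length"].astype(int)))
        return windows_from_depth(table, length_map, window_size=window_size, step=step)
    raise InputError(
        f"{path.name}: expected columns (scaffold,start,end,depth) or (scaffold,pos,depth)"
    )


def write_coverage(track: CoverageTrack, path) -> None:
    out = track.windows.copy()
    out["depth"] = track.coverage
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_manifest(outdir, config: dict, seed: int | None = None) -> Path:
    """Run manifest: package version, the fully resolved configuration, its
    hash and the seed — enough to reproduce the run bit for bit."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "natzkit_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(json.dumps(config, default=str)),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
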
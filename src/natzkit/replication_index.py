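"""Index of replication (iRep) from per-window genome coverage.

Bidirectional replication of a circular prokaryotic chromosome makes
coverage highest at the origin and lowest at the terminus in a growing
population.  Sorting per-window coverage, discarding the extremes, and
fitting log2 coverage against rank fraction recovers the origin:terminus
coverage ratio as 2^|slope|; under the assumption that each replicating
cell holds two genome copies, iRep - 1 approximates the fraction of cells
replicating at sampling time.

Input is a coverage table (bedGraph-like windows or per-base depth), not
read alignments: mapping is upstream of this package.  No GC correction is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "GenomeQual",
    "genome_qc",
    "irep_estimate",
    "replicating_fraction",
    "windows_from_depth",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5000
DEFAULT_STEP = 100
MIN_SCAFFOLD_LENGTH = 5000
MIN_WINDOWS = 100


@dataclass
class CoverageTrack:
    """Ordered per-window mean read depth.

    ``windows`` is a DataFrame with columns (scaffold, start, end) in
    0-based half-open coordinates; ``coverage`` aligns with its rows.
    """

    windows: pd.DataFrame
    coverage: np.ndarray
    window_size: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP

    def __post_init__(self):
        self.coverage = np.asarray(self.coverage, dtype=float)
        if len(self.windows) != self.coverage.size:
            raise ValueError("windows and coverage lengths differ")
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be >= 0")
        if self.window_size < self.step:
            raise ValueError("window_size must be >= step")


@dataclass
class GenomeQual:
    """Genome-quality summary gating the iRep calculation."""

    completeness: float  # percent
    mean_coverage: float
    n_scaffolds: int
    genome_length: int  # bp
    min_scaffold_length: int = MIN_SCAFFOLD_LENGTH
    scaffolds_per_mbp: float = field(init=False)

    def __post_init__(self):
        if min(self.completeness, self.mean_coverage, self.genome_length) < 0:
            raise ValueError("genome-quality fields must be non-negative")
        self.scaffolds_per_mbp = self.n_scaffolds / (self.genome_length / 1e6)


def genome_qc(
    qual: GenomeQual,
    scaffold_lengths: dict[str, int] | None = None,
    scaffold_coverage: dict[str, float] | None = None,
) -> tuple[bool, list[str]]:
    """Apply the iRep genome-quality gates.

    When per-scaffold lengths are given, scaffolds shorter than
    ``qual.min_scaffold_length`` are dropped and the statistics recomputed
    (length-weighted coverage if per-scaffold coverages are available)
    before gating.  Gates (all strict where printed as strict): completeness
    > 75%, mean coverage > 5x, <= 175 scaffolds per Mbp.
    """
    q = qual
    if scaffold_lengths:
        kept = {n: ln for n, ln in scaffold_lengths.items() if ln >= q.min_scaffold_length}
        dropped = len(scaffold_lengths) - len(kept)
        if dropped:
            logger.info("genome_qc: dropped %d scaffolds < %d bp", dropped,
                        q.min_scaffold_length)
        length = sum(kept.values())
        cov = q.mean_coverage
        if scaffold_coverage and length > 0:
            cov = sum(scaffold_coverage[n] * ln for n, ln in kept.items()) / length
        q = GenomeQual(
            completeness=q.completeness,
            mean_coverage=cov,
            n_scaffolds=len(kept),
            genome_length=length,
            min_scaffold_length=q.min_scaffold_length,
        )
    reasons = []
    if not q.completeness > 75.0:
        reasons.append("low_completeness")
    if not q.mean_coverage > 5.0:
        reasons.append("low_coverage")
    if not q.scaffolds_per_mbp <= 175.0:
        reasons.append("too_fragmented")
    return (not reasons, reasons)


def irep_estimate(track: CoverageTrack, trim_fraction: float = 0.05) -> float:
    """Estimate iRep (the origin:terminus coverage ratio) from a track.

    Window coverages are log2-transformed, sorted in descending order, the
    top and bottom ``trim_fraction`` discarded, and log2 coverage regressed
    against rank fraction x in [0, 1]; iRep = 2^|slope|.  Zero-coverage
    windows cannot be log-transformed and are excluded (with a logged
    count) before sorting.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    cov = track.coverage
    nz = cov > 0
    n_zero = int((~nz).sum())
    if n_zero:
        logger.info("irep_estimate: excluding %d zero-coverage windows", n_zero)
    cov = cov[nz]
    log2cov = np.sort(np.log2(cov))[::-1]
    n = log2cov.size
    k = int(np.floor(trim_fraction * n))
    trimmed = log2cov[k : n - k] if k else log2cov
    if trimmed.size < MIN_WINDOWS:
        raise ValueError(
            f"only {trimmed.size} windows after trimming (need >= {MIN_WINDOWS})"
        )
    # rank fraction stays relative to the full sorted set so trimming the
    # extremes does not compress the fitted slope
    x = np.arange(k, n - k) / (n - 1)
    slope = np.polyfit(x, trimmed, 1)[0]
    return float(2.0 ** abs(slope))


def replicating_fraction(irep: float) -> float:
    """Percent of cells replicating, under the two-genome-copy assumption:
    100 * (iRep - 1).  Values below 1 (no resolvable replication) report 0
    with a warning."""
    if irep < 1.0:
        logger.warning("iRep %.3f < 1; reporting a replicating fraction of 0", irep)
        return 0.0
    return 100.0 * (irep - 1.0)


def windows_from_depth(
    depth_table: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_scaffold_length: int = MIN_SCAFFOLD_LENGTH,
) -> CoverageTrack:
    """Build sliding-window mean coverage from per-base depth.

    ``depth_table`` has columns (scaffold, pos, depth) with 0-based
    positions; positions absent from the table count as zero depth.
    Windows are fully contained in their scaffold; scaffolds shorter than
    ``min_scaffold_length`` (or than one window) are skipped.
    """
    required = {"scaffold", "pos", "depth"}
    if not required.issubset(depth_table.columns):
        raise ValueError(f"depth table needs columns {sorted(required)}")
    frames = []
    covs = []
    for name, length in scaffold_lengths.items():
        if length < max(min_scaffold_length, window_size):
            continue
        sub = depth_table[depth_table["scaffold"] == name]
        depth = np.zeros(length)
        pos = sub["pos"].to_numpy(dtype=int)
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            raise ValueError(f"{name}: positions outside [0, {length})")
        depth[pos] = sub["depth"].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(depth)])
        starts = np.arange(0, length - window_size + 1, step)
        means = (csum[starts + window_size] - csum[starts]) / window_size
        frames.append(
            pd.DataFrame(
                {"scaffold": name, "start": starts, "end": starts + window_size}
            )
        )
        covs.append(means)
    if not frames:
        raise ValueError("no scaffold long enough for a single window")
    return CoverageTrack(
        windows=pd.concat(frames, ignore_index=True),
        coverage=np.concatenate(covs),
        window_size=window_size,
        step=step,
    )
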
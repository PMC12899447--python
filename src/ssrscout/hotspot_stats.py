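"""Locus-centered SSR density profiling and permutation hotspot calling.

For each target locus the ± flank analysis region is tiled with 1 kb
windows at two offsets (0 and 500 bp, i.e. half-overlapping grids pooled
together). Per-window SSR counts x_w are standardized with the locus-level
mean µ and sample standard deviation σ, z_w = (x_w − µ)/σ. Significance is
assessed against a locus-specific max-Z null: the observed total SSR count
is redistributed uniformly over the region B times, each permutation's
maximum window z (standardized with the *observed* µ, σ) is recorded, and
the empirical 95th/99th percentiles of those maxima become the thresholds.
Windows whose observed z strictly exceeds a threshold are merged (when
overlapping or bookended) into hotspot regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import AnalysisRegion
from .ssr_mining import SSRRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_OFFSETS = (0, 500)
DEFAULT_B = 1000
LEVELS = (95, 99)


@dataclass(frozen=True)
class Window:
    index: int
    offset: int
    start: int
    end: int


@dataclass
class WindowGrid:
    region: AnalysisRegion
    window_size: int
    offsets: tuple[int, ...]
    windows: list[Window]

    def starts(self) -> np.ndarray:
        return np.array([w.start for w in self.windows])

    def ends(self) -> np.ndarray:
        return np.array([w.end for w in self.windows])


@dataclass
class DensityProfile:
    locus_id: str
    grid: WindowGrid
    counts: np.ndarray
    mu: float
    sigma: float
    z: np.ndarray | None  # None when sigma == 0 (z undefined)


@dataclass
class PermutationNull:
    locus_id: str
    B: int
    max_z: np.ndarray
    thresholds: dict[int, float]
    seed: int | None = None


@dataclass
class HotspotRegion:
    locus_id: str
    contig_id: str
    start: int
    end: int
    n_windows: int
    max_z: float
    level: int


def build_grid(
    region: AnalysisRegion,
    window_size: int = DEFAULT_WINDOW,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> WindowGrid:
    """Pool sliding windows from all offsets over the analysis region.

    Trailing partial windows are kept, trimmed to the region end; every
    window has width >= 1.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if region.length < 1:
        raise ValueError(f"region {region.locus_id} shorter than 1 bp")
    windows: list[Window] = []
    idx = 0
    for off in offsets:
        start = region.start + off
        while start <= region.end:
            end = min(start + window_size - 1, region.end)
            windows.append(Window(idx, off, start, end))
            idx += 1
            start += window_size
    return WindowGrid(region, window_size, tuple(offsets), windows)


def _counts_from_starts(starts: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Per-window counts of SSR start coordinates (inclusive membership;
    a start on a boundary shared by windows of both offsets counts in each)."""
    starts = np.sort(np.asarray(starts))
    ws = grid.starts()
    we = grid.ends()
    return (
        np.searchsorted(starts, we, side="right")
        - np.searchsorted(starts, ws, side="left")
    ).astype(np.int64)


def count_windows(ssrs: Iterable[SSRRecord], grid: WindowGrid) -> DensityProfile:
    """Build the per-window SSR density profile of a locus.

    Membership is by SSR start coordinate; zero-count windows are retained
    so that µ and σ are computed over the complete pooled grid. σ is the
    sample standard deviation (n−1 denominator); z is undefined when σ = 0.
    """
    starts = np.array([s.start for s in ssrs], dtype=np.int64)
    counts = _counts_from_starts(starts, grid)
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    z = (counts - mu) / sigma if sigma > 0 else None
    return DensityProfile(grid.region.locus_id, grid, counts, mu, sigma, z)


def permutation_null(
    n_ssrs: int,
    region: AnalysisRegion,
    grid: WindowGrid,
    mu: float,
    sigma: float,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
) -> PermutationNull | None:
    """Permutation max-Z null for one locus.

    Each permutation redistributes the observed SSR count uniformly (with
    replacement) over region base positions, projects starts onto the
    pooled window grid, and records the maximum of (x_w − µ)/σ using the
    observed µ and σ. Returns None (an exclusion signal, logged) when the
    locus has no SSRs or σ <= 0.
    """
    if n_ssrs < 1 or sigma <= 0 or not math.isfinite(sigma):
        logger.info(
            "locus %s excluded from permutation analysis (n_ssrs=%d, sigma=%s)",
            region.locus_id,
            n_ssrs,
            sigma,
        )
        return None
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    positions = rng.integers(region.start, region.end + 1, size=(B, n_ssrs))
    positions.sort(axis=1)
    ws = grid.starts()
    we = grid.ends()
    # per-permutation window counts via row-wise searchsorted
    lo = np.apply_along_axis(np.searchsorted, 1, positions, ws, side="left")
    hi = np.apply_along_axis(np.searchsorted, 1, positions, we, side="right")
    max_counts = (hi - lo).max(axis=1)
    max_z = (max_counts - mu) / sigma
    thresholds = {
        level: _empirical_percentile(max_z, level / 100.0) for level in LEVELS
    }
    return PermutationNull(
        locus_id=region.locus_id,
        B=B,
        max_z=max_z,
        thresholds=thresholds,
        seed=seed if isinstance(seed, int) else None,
    )


def _empirical_percentile(values: np.ndarray, p: float) -> float:
    """Order statistic at rank ceil(p·B) of the sorted sample (1-indexed)."""
    v = np.sort(values)
    rank = min(len(v), max(1, math.ceil(p * len(v))))
    return float(v[rank - 1])


def call_hotspots(
    profile: DensityProfile, null: PermutationNull, level: int
) -> list[HotspotRegion]:
    """Merge windows whose observed z strictly exceeds the level threshold.

    Significant windows from both offset grids are pooled; genomic
    intervals that overlap or are bookended (adjacent) are merged into one
    hotspot region carrying the contributing-window count and maximum z.
    """
    if profile.z is None:
        return []
    thr = null.thresholds[level]
    sig = [
        (w.start, w.end, float(profile.z[i]))
        for i, w in enumerate(profile.grid.windows)
        if profile.z[i] > thr
    ]
    if not sig:
        return []
    sig.sort()
    regions: list[HotspotRegion] = []
    cur_s, cur_e, cur_z, cur_n = sig[0][0], sig[0][1], sig[0][2], 1
    contig = profile.grid.region.contig_id
    for s, e, z in sig[1:]:
        if s <= cur_e + 1:  # overlapping or bookended
            cur_e = max(cur_e, e)
            cur_z = max(cur_z, z)
            cur_n += 1
        else:
            regions.append(
                HotspotRegion(profile.locus_id, contig, cur_s, cur_e, cur_n, cur_z, level)
            )
            cur_s, cur_e, cur_z, cur_n = s, e, z, 1
    regions.append(
        HotspotRegion(profile.locus_id, contig, cur_s, cur_e, cur_n, cur_z, level)
    )
    return regions


def locus_hotspots(
    ssrs: list[SSRRecord],
    region: AnalysisRegion,
    window_size: int = DEFAULT_WINDOW,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
) -> tuple[DensityProfile, PermutationNull | None, dict[int, list[HotspotRegion]]]:
    """Convenience composition: grid → profile → null → hotspots at 95/99."""
    grid = build_grid(region, window_size, offsets)
    profile = count_windows(ssrs, grid)
    null = permutation_null(
        len(ssrs), region, grid, profile.mu, profile.sigma, B=B, seed=seed
    )
    if null is None:
        return profile, None, {level: [] for level in LEVELS}
    calls = {level: call_hotspots(profile, null, level) for level in LEVELS}
    return profile, null, calls
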
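"""Super-enhancer landscape analysis on binned H3K27ac coverage.

The workflow mirrors the classic hockey-stick convention: normalize a track
to reads per 20 million mapped reads, call peaks as threshold runs of bins,
stitch peaks within 12.5 kb into enhancer regions, rank regions by summed
signal and cut the rank-signal curve where its discrete slope (on min-max
rescaled axes, scanned from the top down) first falls to 1.  Regions above
the cutoff are super-enhancers.

Differential analysis between two states uses a signed-area statistic, the
"directional surface": bin width times the summed per-bin normalized
difference (state B minus state A) over a region.  Induced regions are the
top-n by positive surface and feed motif enrichment downstream.

All intervals are 0-based half-open and must align to the track's bin grid.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Sequence

import numpy as np

from .containers import CoverageTrack, DifferentialRegion, EnhancerRegion, SuperEnhancerCall
from .errors import InputError
from .simulate import Gene

__all__ = [
    "TARGET_READS",
    "DEFAULT_STITCH_DISTANCE",
    "normalize_track",
    "auto_threshold",
    "call_peaks",
    "stitch_peaks",
    "call_superenhancers",
    "assign_region_genes",
    "differential_surface",
    "select_induced_regions",
]

TARGET_READS = 2.0e7
#: Stitching distance of the hockey-stick super-enhancer convention.
DEFAULT_STITCH_DISTANCE = 12_500


def normalize_track(track: CoverageTrack) -> CoverageTrack:
    """Scale counts to reads per 20 million mapped reads."""
    if track.total_mapped_reads <= 0:
        raise InputError("track has no mapped reads")
    factor = TARGET_READS / track.total_mapped_reads
    return track.with_counts(track.counts * factor, TARGET_READS)


def auto_threshold(track: CoverageTrack, multiple: float = 2.0) -> float:
    """A scale-free peak threshold: ``multiple`` times the mean bin value."""
    return multiple * float(track.counts.mean())


def call_peaks(
    track: CoverageTrack, threshold: float, min_width: int | None = None
) -> list[tuple[int, int]]:
    """Maximal runs of bins with value >= threshold, at least ``min_width`` wide.

    Returns sorted, non-overlapping half-open intervals on the track's grid.
    """

    if threshold < 0:
        raise InputError("threshold must be non-negative")
    min_width = track.bin_width if min_width is None else min_width
    above = track.counts >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    out = []
    for s, e in zip(starts, ends):
        a = track.start_offset + int(s) * track.bin_width
        b = track.start_offset + int(e) * track.bin_width
        if b - a >= min_width:
            out.append((a, b))
    return out


def stitch_peaks(
    peaks: Sequence[tuple[int, int]], stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> list[EnhancerRegion]:
    """Merge adjacent peaks with gap <= stitch_distance, transitively.

    Input must be sorted and non-overlapping; output regions record how many
    constituent peaks they absorbed.  Idempotent on its own output, and the
    number of regions is non-increasing in the stitch distance.
    """

    if stitch_distance < 0:
        raise InputError("stitch_distance must be non-negative")
    for (a0, a1), (b0, b1) in zip(peaks, peaks[1:]):
        if b0 < a1:
            raise InputError("peaks must be sorted and non-overlapping")
    regions: list[EnhancerRegion] = []
    for s, e in peaks:
        if e <= s:
            raise InputError(f"degenerate peak ({s}, {e})")
        if regions and s - regions[-1].end <= stitch_distance:
            prev = regions[-1]
            regions[-1] = EnhancerRegion(
                prev.start, e, constituent_count=prev.constituent_count + 1
            )
        else:
            regions.append(EnhancerRegion(s, e))
    return regions


def _region_signal(track: CoverageTrack, region: EnhancerRegion) -> float:
    return float(track.counts[track.bin_slice(region.start, region.end)].sum())


def call_superenhancers(
    regions: Sequence[EnhancerRegion], track: CoverageTrack
) -> SuperEnhancerCall:
    """Rank regions by summed normalized signal and cut at the elbow.

    Both axes are min-max rescaled to [0, 1]; scanning the discrete slope of
    the signal-vs-rank curve from the top down, the cutoff sits at the first
    rank where the slope is no longer above 1.  Regions whose signal
    strictly exceeds the cutoff signal are super, so plateaus and ties
    resolve toward fewer super-enhancers.  A perfectly flat curve yields no
    super-enhancers (with a warning); perfectly linear signals likewise
    yield none, because the slope equals 1 everywhere.
    """

    ranked = sorted(
        (replace(r, signal=_region_signal(track, r)) for r in regions),
        key=lambda r: (r.signal, r.start),
    )
    n = len(ranked)
    if n == 0:
        return SuperEnhancerCall([], 0, np.zeros(0, dtype=bool))
    signals = np.array([r.signal for r in ranked])
    if n < 3 or signals.max() == signals.min():
        if n and signals.max() == signals.min():
            warnings.warn("flat signal curve: no super-enhancers called", stacklevel=2)
        return SuperEnhancerCall(ranked, n - 1, np.zeros(n, dtype=bool))
    y = (signals - signals.min()) / (signals.max() - signals.min())
    x = np.arange(n) / (n - 1)
    slopes = np.diff(y) / np.diff(x)
    cutoff = 0
    for i in range(n - 2, -1, -1):
        if slopes[i] <= 1.0:
            cutoff = i + 1
            break
    is_super = signals > signals[cutoff]
    return SuperEnhancerCall(ranked, cutoff, is_super)


def assign_region_genes(
    regions: Sequence[EnhancerRegion], genes: Sequence[Gene]
) -> dict[tuple[int, int], list[str]]:
    """Assign each region the genes whose bodies it overlaps, else the nearest TSS.

    Distance to a TSS is the gap between the TSS and the region (zero if the
    TSS lies inside).  Equidistant ties break toward the lexicographically
    smaller gene id, making the assignment deterministic.
    """

    out: dict[tuple[int, int], list[str]] = {}
    for r in regions:
        overlapping = sorted(
            g.gene_id for g in genes if g.start < r.end and r.start < g.end
        )
        if overlapping:
            out[r.interval] = overlapping
        elif genes:
            best = min(
                genes,
                key=lambda g: (max(0, r.start - g.tss, g.tss - (r.end - 1)), g.gene_id),
            )
            out[r.interval] = [best.gene_id]
        else:
            out[r.interval] = []
    return out


def differential_surface(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    regions: Sequence[EnhancerRegion],
    epsilon: float = 0.0,
) -> list[DifferentialRegion]:
    """Signed-area difference (B minus A) per region, with a direction call.

    ``surface = bin_width * sum_bins (B - A)``; direction is ``increased``
    when surface > epsilon, ``decreased`` below ``-epsilon``, else
    ``unchanged``.  Swapping the tracks negates every surface exactly.
    """

    if (
        track_a.bin_width != track_b.bin_width
        or track_a.start_offset != track_b.start_offset
        or track_a.n_bins != track_b.n_bins
        or track_a.chrom != track_b.chrom
    ):
        raise InputError("tracks must share chromosome, binning and span")
    if epsilon < 0:
        raise InputError("epsilon must be non-negative")
    diff = track_b.counts - track_a.counts
    out = []
    for r in regions:
        sl = track_a.bin_slice(r.start, r.end)
        surface = track_a.bin_width * float(diff[sl].sum())
        if surface > epsilon:
            direction = "increased"
        elif surface < -epsilon:
            direction = "decreased"
        else:
            direction = "unchanged"
        out.append(DifferentialRegion(r.start, r.end, surface, direction))
    return out


def poisson_direction_filter(
    diffs: Sequence[DifferentialRegion],
    raw_a: CoverageTrack,
    raw_b: CoverageTrack,
    z: float = 3.0,
) -> list[DifferentialRegion]:
    """Demote noise-level surfaces to "unchanged" using Poisson error bars.

    For raw Poisson bin counts, the variance of a region's normalized
    surface is ``bin_width^2 * (fa^2 * sum_A + fb^2 * sum_B)`` with ``fa``,
    ``fb`` the reads-per-20-million factors of the two libraries.  Surfaces
    within ``z`` standard deviations of zero keep their value but read
    "unchanged", so rank-based selection of induced regions is restricted
    to changes the sequencing depth can support.
    """

    if z < 0:
        raise InputError("z must be non-negative")
    fa = TARGET_READS / raw_a.total_mapped_reads
    fb = TARGET_READS / raw_b.total_mapped_reads
    out: list[DifferentialRegion] = []
    for d in diffs:
        sl = raw_a.bin_slice(d.start, d.end)
        var = fa * fa * float(raw_a.counts[sl].sum()) + fb * fb * float(
            raw_b.counts[sl].sum()
        )
        thr = z * raw_a.bin_width * float(np.sqrt(var))
        if abs(d.surface) <= thr:
            out.append(DifferentialRegion(d.start, d.end, d.surface, "unchanged"))
        else:
            out.append(d)
    return out


def select_induced_regions(
    diffs: Sequence[DifferentialRegion], n: int
) -> list[tuple[int, int]]:
    """The n increased regions with the largest surface, leftmost-first on ties."""
    if n < 0:
        raise InputError("n must be non-negative")
    increased = [d for d in diffs if d.direction == "increased" and d.surface > 0]
    if not increased:
        warnings.warn("no regions with increased signal", stacklevel=2)
        return []
    if n > len(increased):
        warnings.warn(
            f"requested top {n} induced regions, only {len(increased)} available",
            stacklevel=2,
        )
        n = len(increased)
    ordered = sorted(increased, key=lambda d: (-d.surface, d.start))
    return [d.interval for d in ordered[:n]]
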
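"""Core in-memory containers shared across modules.

The expression container mirrors a detection-called microarray experiment:
a probeset x sample grid of linear-scale intensities, a congruent grid of
Present/Absent calls, and a per-sample metadata table (lineage, isogenic
pair id, time point, scenario and induction flags).  Coverage tracks are
fixed-width binned histone-mark signal on a single (toy) chromosome.

All genomic intervals in this package are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ExpressionMatrix",
    "CoverageTrack",
    "EnhancerRegion",
    "SuperEnhancerCall",
    "DifferentialRegion",
]

PRESENT = "P"
ABSENT = "A"


@dataclass
class ExpressionMatrix:
    """Probeset x sample linear intensities with detection calls and metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative linear-scale intensities, probesets as the
        index, sample ids as columns.
    detection
        DataFrame congruent to ``values`` holding ``"P"`` (Present) or
        ``"A"`` (Absent) calls.
    samples
        DataFrame indexed by sample id.  Recognised columns: ``lineage``
        (``MES``/``ADRN``/``unknown``), ``pair_id``, ``day``, ``scenario``,
        ``dox``, ``gsi``.  Extra columns are carried along untouched.
    """

    values: pd.DataFrame
    detection: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise InputError("probeset and sample ids must be unique")
        if self.values.shape != self.detection.shape:
            raise InputError("values and detection grids are not congruent")
        if not self.values.index.equals(self.detection.index) or not self.values.columns.equals(
            self.detection.columns
        ):
            raise InputError("values and detection grids are not aligned")
        if not self.samples.index.equals(self.values.columns):
            raise InputError("sample metadata does not match value columns")
        if (self.values.to_numpy() < 0).any():
            raise InputError("expression intensities must be non-negative")

    @property
    def probesets(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise InputError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(
            self.values[ids], self.detection[ids], self.samples.loc[ids]
        )


@dataclass
class CoverageTrack:
    """Fixed-width binned coverage on one chromosome segment.

    ``counts[i]`` covers ``[start_offset + i*bin_width,
    start_offset + (i+1)*bin_width)``.  ``total_mapped_reads`` is the library
    size used by reads-per-20-million normalization.
    """

    chrom: str
    bin_width: int
    start_offset: int
    counts: np.ndarray
    total_mapped_reads: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise InputError("counts must be one-dimensional")
        if self.bin_width <= 0:
            raise InputError("bin_width must be positive")
        if (self.counts < 0).any():
            raise InputError("coverage counts must be non-negative")
        if self.total_mapped_reads <= 0:
            raise InputError("total_mapped_reads must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def end(self) -> int:
        return self.start_offset + self.n_bins * self.bin_width

    def bin_slice(self, start: int, end: int) -> slice:
        """Indices of the bins fully covering [start, end); grid-aligned input."""
        if start < self.start_offset or end > self.end or end <= start:
            raise InputError(f"interval [{start}, {end}) outside track span")
        lo = (start - self.start_offset) // self.bin_width
        hi = -(-(end - self.start_offset) // self.bin_width)
        return slice(int(lo), int(hi))

    def with_counts(self, counts: np.ndarray, total: float) -> "CoverageTrack":
        return replace(self, counts=np.asarray(counts, dtype=float), total_mapped_reads=total)


@dataclass(frozen=True)
class EnhancerRegion:
    """A stitched enhancer: interval, summed normalized signal, peak count."""

    start: int
    end: int
    signal: float = 0.0
    constituent_count: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("enhancer region must be non-degenerate")
        if self.signal < 0:
            raise InputError("enhancer signal must be non-negative")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class SuperEnhancerCall:
    """Regions ranked ascending by signal with an elbow cutoff.

    ``is_super[i]`` flags region ``regions[i]``; regions at or above
    ``cutoff_rank`` on the rescaled rank-signal curve whose signal strictly
    exceeds the cutoff signal are super.
    """

    regions: list[EnhancerRegion]
    cutoff_rank: int
    is_super: np.ndarray

    def __post_init__(self) -> None:
        self.is_super = np.asarray(self.is_super, dtype=bool)
        sig = [r.signal for r in self.regions]
        if any(b > a for a, b in zip(sig[1:], sig)):
            raise InputError("regions must be sorted ascending by signal")

    @property
    def superenhancers(self) -> list[EnhancerRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if s]


@dataclass(frozen=True)
class DifferentialRegion:
    """Signed-area H3K27ac difference of a region between two states.

    ``surface`` is bin_width times the summed per-bin normalized difference
    (state B minus state A); ``direction`` follows its sign against a small
    configurable threshold.
    """

    start: int
    end: int
    surface: float
    direction: str  # "increased" | "decreased" | "unchanged"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)
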
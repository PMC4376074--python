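"""Peak calling on methylated-DNA enrichment (MIRA) tiling arrays.

Per-probe signal is the normalised log2(MIRA/input) ratio. A probe is
"positive" when its value lies strictly above the 95th percentile of all
probes on the same array (each sample carries its own threshold). A peak is
a maximal run of positive probes that may contain at most one interior
non-positive probe (the "gap") and must contain at least four positive
probes. Consensus peaks across biological replicates are the interval
intersections of per-replicate peaks that overlap in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVITY_PERCENTILE = 95.0
MIN_POSITIVE_PROBES = 4
MAX_GAPS = 1

__all__ = [
    "ArrayDesign",
    "SampleMeta",
    "MethylationSampleGroup",
    "Peak",
    "positivity_threshold",
    "positive_mask",
    "call_peaks",
    "consensus_peaks",
]


class ArrayDesign:
    """Ordered, non-overlapping probe intervals of one tiling-array platform.

    Probes are sorted by (chrom, start), coordinates are 0-based half-open,
    probe ids are unique. Chromosome blocks are contiguous in probe order.
    """

    def __init__(
        self,
        probe_ids: Sequence[str],
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
    ) -> None:
        self.probe_ids = np.asarray(probe_ids, dtype=object)
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        n = len(self.probe_ids)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == n):
            raise ValueError("probe_ids, chroms, starts, ends must have equal length")
        if n == 0:
            raise ValueError("ArrayDesign needs at least one probe")
        if np.any(self.ends <= self.starts):
            bad = np.flatnonzero(self.ends <= self.starts)[:5]
            raise ValueError(f"probe end <= start at indices {bad.tolist()}")
        if len(set(self.probe_ids)) != n:
            raise ValueError("duplicate probe ids")
        # chromosome blocks must be contiguous and sorted by start within a block
        self._chrom_bounds: dict[str, tuple[int, int]] = {}
        i = 0
        while i < n:
            c = self.chroms[i]
            j = i
            while j < n and self.chroms[j] == c:
                j += 1
            if c in self._chrom_bounds:
                raise ValueError(f"chromosome {c!r} appears in non-contiguous blocks")
            block_starts = self.starts[i:j]
            if np.any(np.diff(block_starts) <= 0):
                raise ValueError(f"probes on {c!r} not sorted by start / overlapping starts")
            if np.any(self.ends[i : j - 1] > block_starts[1:]):
                raise ValueError(f"overlapping probes on {c!r}")
            self._chrom_bounds[c] = (i, j)
            i = j

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def chrom_bounds(self) -> Mapping[str, tuple[int, int]]:
        """Map chrom -> (first probe index, one-past-last probe index)."""
        return self._chrom_bounds

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArrayDesign":
        return cls(
            df["probe_id"].to_numpy(),
            df["chrom"].to_numpy(),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrayDesign):
            return NotImplemented
        return (
            np.array_equal(self.probe_ids, other.probe_ids)
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ArrayDesign({self.n_probes} probes, {len(self._chrom_bounds)} chromosomes)"


@dataclass(frozen=True)
class SampleMeta:
    """Biological annotation of one array hybridisation."""

    generation: str  # G1R or G2R
    cell_type: str  # MGC, sperm, FGC
    treatment: str  # oil, BPA, VZ, DEHP
    platform: str = "custom"


@dataclass
class MethylationSampleGroup:
    """Replicated per-probe log2(MIRA/input) vectors sharing one ArrayDesign."""

    design: ArrayDesign
    sample_ids: list[str]
    metadata: list[SampleMeta]
    values: np.ndarray = field(repr=False)  # (n_samples, n_probes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x probes) array")
        if self.values.shape != (len(self.sample_ids), self.design.n_probes):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.design.n_probes} probes"
            )
        if len(self.metadata) != len(self.sample_ids):
            raise ValueError("metadata and sample_ids must have equal length")

    @property
    def n_replicates(self) -> int:
        return len(self.sample_ids)

    def mean_values(self) -> np.ndarray:
        """Replicate-averaged per-probe signal."""
        return self.values.mean(axis=0)


@dataclass
class Peak:
    """Genomic interval spanning the first to last probe of a positive run.

    For peaks from :func:`call_peaks`, ``n_positive_probes`` counts probes
    above the sample threshold; for consensus peaks it counts the probes
    contained in the replicate intersection.
    """

    chrom: str
    start: int
    end: int
    probe_indices: np.ndarray
    n_positive_probes: int

    def overlaps(self, other: "Peak") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def positivity_threshold(values: np.ndarray, percentile: float = POSITIVITY_PERCENTILE) -> float:
    """95th percentile of the per-probe signal (linear interpolation).

    A probe is positive iff its value is *strictly* greater than the returned
    threshold, so a constant array yields no positive probes.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite signal at probe indices {bad[:10].tolist()}")
    return float(np.percentile(values, percentile))


def positive_mask(values: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Boolean mask of probes strictly above the array-wide threshold."""
    values = np.asarray(values, dtype=float)
    if threshold is None:
        threshold = positivity_threshold(values)
    return values > threshold


def _scan_runs(mask: np.ndarray, min_positive: int, max_gaps: int) -> list[tuple[int, int, int]]:
    """Maximal gap-tolerant runs in a boolean vector.

    Returns (first, last, n_positive) index triples, leftmost-maximal and
    non-overlapping. A run may contain at most ``max_gaps`` interior False
    positions, each flanked by True, and must hold >= ``min_positive`` Trues.
    After a failed run the scan resumes just past the first gap used, so a
    later window re-using that gap budget is still found.
    """
    runs: list[tuple[int, int, int]] = []
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        gaps_used = 0
        first_gap = -1
        n_pos = 0
        last_pos = i
        k = i
        while k < n:
            if mask[k]:
                n_pos += 1
                last_pos = k
                k += 1
            elif gaps_used < max_gaps and k + 1 < n and mask[k + 1]:
                gaps_used += 1
                if first_gap < 0:
                    first_gap = k
                k += 1
            else:
                break
        if n_pos >= min_positive:
            runs.append((i, last_pos, n_pos))
            i = last_pos + 1
        elif first_gap >= 0:
            i = first_gap + 1
        else:
            i = last_pos + 2
    return runs


def call_peaks(
    design: ArrayDesign,
    values: np.ndarray,
    threshold: float | None = None,
    min_positive: int = MIN_POSITIVE_PROBES,
    max_gaps: int = MAX_GAPS,
) -> list[Peak]:
    """Call gap-tolerant peaks on one sample's per-probe signal.

    The positivity threshold is computed over *all* probes of the array
    (per-sample) unless supplied. Runs never cross chromosome boundaries;
    returned peaks are sorted and non-overlapping.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (design.n_probes,):
        raise ValueError(
            f"values length {values.shape} does not match design ({design.n_probes} probes)"
        )
    mask = positive_mask(values, threshold)
    peaks: list[Peak] = []
    for chrom, (lo, hi) in design.chrom_bounds.items():
        for first, last, n_pos in _scan_runs(mask[lo:hi], min_positive, max_gaps):
            gfirst, glast = lo + first, lo + last
            idx = np.arange(gfirst, glast + 1)
            idx = idx[mask[idx]]
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(design.starts[gfirst]),
                    end=int(design.ends[glast]),
                    probe_indices=idx,
                    n_positive_probes=n_pos,
                )
            )
    return peaks


def _intersect_sorted(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two sorted, disjoint interval lists (half-open)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def consensus_peaks(
    group: MethylationSampleGroup,
    min_positive: int = MIN_POSITIVE_PROBES,
    max_gaps: int = MAX_GAPS,
    threshold: float | None = None,
) -> list[Peak]:
    """Peaks supported by every replicate of a group.

    Each replicate is peak-called against its own array-wide threshold
    (or an explicit shared ``threshold``); the consensus is the interval
    intersection of peaks that mutually overlap (>= 1 bp) in all
    replicates. The probe set of a consensus peak is the probes fully
    contained in the intersection interval.
    """
    if group.n_replicates == 0:
        raise ValueError("consensus requires at least one replicate")
    per_rep = [call_peaks(group.design, v, threshold=threshold,
                          min_positive=min_positive, max_gaps=max_gaps)
               for v in group.values]
    consensus: list[Peak] = []
    for chrom, (lo, hi) in group.design.chrom_bounds.items():
        lists = [
            [(p.start, p.end) for p in peaks if p.chrom == chrom] for peaks in per_rep
        ]
        common = lists[0]
        for other in lists[1:]:
            common = _intersect_sorted(common, other)
            if not common:
                break
        starts = group.design.starts[lo:hi]
        ends = group.design.ends[lo:hi]
        for s, e in common:
            sel = np.flatnonzero((starts >= s) & (ends <= e)) + lo
            consensus.append(
                Peak(
                    chrom=chrom,
                    start=s,
                    end=e,
                    probe_indices=sel,
                    n_positive_probes=len(sel),
                )
            )
    return consensus
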
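"""Multi-level persistence analysis of differential-methylation hits.

Level-1 hits are per-comparison differential calls. Level 2 intersects two
hit lists across generations (G1R vs G2R, same cell type); level 3 across
cell types (prospermatogonia vs sperm, same generation); level 4 requires a
region to recur in all four germline samples — an immediate effect in
exposed G1R prospermatogonia maintained into G1R sperm, G2R
prospermatogonia, and G2R sperm, the operational definition of
transgenerational epigenetic inheritance. Two hits are "common" when their
regions overlap by at least 1 bp; overlapping hits are merged to the
intersection interval, and direction concordance is binary on the sign of
the log2 change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "CommonRegion",
    "PersistenceReport",
    "DirectionEnrichment",
    "intersect_calls",
    "tgi_level4",
    "direction_enrichment",
]


@dataclass
class CommonRegion:
    """A region overlapping a hit in every input list."""

    chrom: str
    start: int
    end: int
    directions: tuple[str, ...]

    @property
    def same_direction(self) -> bool:
        return len(set(self.directions)) == 1


@dataclass
class PersistenceReport:
    """Common-hit report for one level-2/3/4 intersection test."""

    level: int
    input_test_ids: tuple[str, ...]
    common_regions: list[CommonRegion] = field(default_factory=list)

    @property
    def n_common(self) -> int:
        return len(self.common_regions)

    @property
    def n_same_direction(self) -> int:
        return sum(r.same_direction for r in self.common_regions)

    def __repr__(self) -> str:  # Table-style "hits (same direction)" summary
        return (f"PersistenceReport(level={self.level}, "
                f"hits={self.n_common} ({self.n_same_direction}))")


def _hits(calls, passed_only: bool) -> list:
    if passed_only:
        return [c for c in calls if getattr(c, "passed", True)]
    return list(calls)


def _build_trees(items) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for it in items:
        trees.setdefault(it.chrom, IntervalTree()).addi(it.start, it.end, it)
    return trees


def _intersect_step(current: list[CommonRegion], calls) -> list[CommonRegion]:
    """Intersect running common regions with one more hit list."""
    trees = _build_trees(calls)
    out: list[CommonRegion] = []
    for region in current:
        tree = trees.get(region.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(region.start, region.end)):
            call = iv.data
            out.append(
                CommonRegion(
                    chrom=region.chrom,
                    start=max(region.start, call.start),
                    end=min(region.end, call.end),
                    directions=region.directions + (call.direction,),
                )
            )
    return out


def _seed_regions(calls) -> list[CommonRegion]:
    return [CommonRegion(c.chrom, c.start, c.end, (c.direction,)) for c in calls]


def intersect_calls(
    calls_x: Sequence,
    calls_y: Sequence,
    level: int = 2,
    test_ids: tuple[str, str] = ("X", "Y"),
    passed_only: bool = True,
) -> PersistenceReport:
    """Common changes between two level-1 hit lists (level 2 or 3).

    Every overlapping pair contributes one common region (the interval
    intersection) with the pair of directions; counts are symmetric in the
    input order.
    """
    regions = _intersect_step(_seed_regions(_hits(calls_x, passed_only)),
                              _hits(calls_y, passed_only))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return PersistenceReport(level=level, input_test_ids=tuple(test_ids),
                             common_regions=regions)


def tgi_level4(
    mgc_g1r: Sequence,
    sperm_g1r: Sequence,
    mgc_g2r: Sequence,
    sperm_g2r: Sequence,
    test_ids: tuple[str, str, str, str] = ("G1R_MGC", "G1R_sperm", "G2R_MGC", "G2R_sperm"),
    passed_only: bool = True,
) -> PersistenceReport:
    """Level-4 test for transgenerational inheritance.

    A region qualifies iff it overlaps a hit in all four lists;
    ``same_direction`` requires an identical direction in all four. Any
    empty input list empties the report.
    """
    lists = [mgc_g1r, sperm_g1r, mgc_g2r, sperm_g2r]
    regions = _seed_regions(_hits(lists[0], passed_only))
    for calls in lists[1:]:
        if not regions:
            break
        regions = _intersect_step(regions, _hits(calls, passed_only))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return PersistenceReport(level=4, input_test_ids=tuple(test_ids),
                             common_regions=regions)


@dataclass
class DirectionEnrichment:
    """Direction cross-tabulation statistics for common hits.

    ``table`` rows are the first list's direction (down, up), columns the
    second list's. ``fold`` is observed / expected under row-column
    independence per cell; ``fisher_p`` is the two-sided Fisher's exact
    p-value of the 2x2 table arranged around each cell; ``binomial_p`` is
    the exact two-sided test of the same-direction count against 0.5.
    """

    table: np.ndarray
    fold: np.ndarray
    fisher_p: np.ndarray
    binomial_p: float
    n_common: int
    n_same_direction: int


def direction_enrichment(
    n_common: int,
    n_same: int,
    table: np.ndarray | Sequence[Sequence[int]],
) -> DirectionEnrichment:
    """Fold enrichment and exact tests for direction concordance.

    Under perfectly independent margins every fold enrichment equals 1; a
    same-direction count of n/2 gives a binomial p of 1.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("direction table must be 2x2")
    if np.any(table < 0):
        raise ValueError("direction table entries must be non-negative")
    if n_same > n_common:
        raise ValueError("n_same_direction cannot exceed n_common")

    total = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    fold = np.full((2, 2), np.nan)
    fisher_p = np.full((2, 2), np.nan)
    for i in range(2):
        for j in range(2):
            expected = rows[i] * cols[j] / total if total > 0 else np.nan
            if expected and expected > 0:
                fold[i, j] = table[i, j] / expected
            sub = np.array(
                [
                    [table[i, j], rows[i] - table[i, j]],
                    [cols[j] - table[i, j], total - rows[i] - cols[j] + table[i, j]],
                ]
            )
            fisher_p[i, j] = float(stats.fisher_exact(sub, alternative="two-sided")[1])
    if n_common > 0:
        binom = float(stats.binomtest(n_same, n_common, 0.5, alternative="two-sided").pvalue)
    else:
        binom = 1.0
    return DirectionEnrichment(
        table=table,
        fold=fold,
        fisher_p=fisher_p,
        binomial_p=binom,
        n_common=n_common,
        n_same_direction=n_same,
    )
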
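"""Average-methylation scoring over named regions.

Imprinted DMRs and unique 1-kb IAP-flank regions are scored as the
unweighted mean log2(MIRA/input) over probes whose interval midpoint lies
inside the region, per replicate. Changes between conditions are tested
with a two-sample equal-variance Student's t-test at the +/-5% fold cutoff
(|delta log2| >= log2(1.05)) and P < 0.05, and the imprint-specific screen
flags maternally methylated DMRs that gain methylation or paternally
methylated DMRs that lose it under treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REGION_CLASSES = ("PAT_DMR", "MAT_DMR", "IAP_flank", "control")
FOLD_CUTOFF = 1.05
DELTA_LOG2_CUTOFF = float(np.log2(FOLD_CUTOFF))
P_CUTOFF = 0.05

__all__ = ["RegionSet", "region_mean", "region_change_test",
           "FOLD_CUTOFF", "DELTA_LOG2_CUTOFF", "P_CUTOFF"]


@dataclass
class RegionSet:
    """Named genomic regions with an imprinting class.

    Paternally methylated DMRs are expected to show positive mean
    log2(MIRA/input) in the male germline; maternally methylated DMRs
    negative. Coordinates are 0-based half-open.
    """

    frame: pd.DataFrame  # columns: name, chrom, start, end, region_class

    def __post_init__(self) -> None:
        required = {"name", "chrom", "start", "end", "region_class"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"RegionSet frame missing columns {sorted(missing)}")
        if self.frame["name"].duplicated().any():
            dup = self.frame.loc[self.frame["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate region name {dup!r}")
        if (self.frame["end"] <= self.frame["start"]).any():
            raise ValueError("region end must exceed start")
        bad = set(self.frame["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes {sorted(bad)}")

    @classmethod
    def from_records(cls, records) -> "RegionSet":
        return cls(pd.DataFrame(records, columns=["name", "chrom", "start", "end", "region_class"]))

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def __len__(self) -> int:
        return len(self.frame)

    def expected_sign(self, name: str) -> int:
        """+1 for PAT_DMR, -1 for MAT_DMR, 0 otherwise."""
        cls_ = self.frame.set_index("name").loc[name, "region_class"]
        return {"PAT_DMR": 1, "MAT_DMR": -1}.get(cls_, 0)


def region_mean(group, regions: RegionSet) -> pd.DataFrame:
    """Per-region, per-replicate mean log2(MIRA/input).

    A probe belongs to a region when its interval midpoint lies within the
    region (avoids double counting at shared borders). Regions covering no
    probe are reported as NaN rows with a warning.
    """
    if group.n_replicates == 0:
        raise ValueError("empty sample group")
    design = group.design
    mids = design.midpoints()
    out = {}
    empty = []
    for row in regions.frame.itertuples(index=False):
        sel = (design.chroms == row.chrom) & (mids >= row.start) & (mids < row.end)
        if not sel.any():
            empty.append(row.name)
            out[row.name] = np.full(group.n_replicates, np.nan)
        else:
            out[row.name] = group.values[:, sel].mean(axis=1)
    if empty:
        warnings.warn(f"regions with no probes reported as missing: {empty}", stacklevel=2)
    return pd.DataFrame(out, index=group.sample_ids).T


def _ttest_means(a: np.ndarray, b: np.ndarray) -> float:
    """Equal-variance two-sided t-test on per-replicate means, with the
    degenerate-variance conventions: both groups constant and equal -> p = 1;
    constant but unequal -> p = 0 with a warning."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 1.0
        warnings.warn("zero within-group variance with unequal means; p set to 0", stacklevel=3)
        return 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def region_change_test(
    group_a,
    group_b,
    regions: RegionSet,
    fold_cutoff: float = FOLD_CUTOFF,
    alpha: float = P_CUTOFF,
) -> pd.DataFrame:
    """Per-region change test between two conditions (A minus B).

    ``passed`` requires |delta log2| >= log2(fold_cutoff) and p < alpha.
    ``imprint_flag`` marks the screen outcome with A as the treated group:
    a MAT_DMR with significantly increased methylation or a PAT_DMR with
    significantly decreased methylation.
    """
    if group_a.n_replicates < 2 or group_b.n_replicates < 2:
        raise ValueError("region_change_test needs >= 2 replicates per group")
    means_a = region_mean(group_a, regions)
    means_b = region_mean(group_b, regions)
    cutoff = float(np.log2(fold_cutoff))
    rows = []
    for row in regions.frame.itertuples(index=False):
        a = means_a.loc[row.name].to_numpy()
        b = means_b.loc[row.name].to_numpy()
        if np.isnan(a).any() or np.isnan(b).any():
            continue
        delta = float(a.mean() - b.mean())
        p = _ttest_means(a, b)
        passed = abs(delta) >= cutoff and p < alpha
        flag = passed and (
            (row.region_class == "MAT_DMR" and delta > 0)
            or (row.region_class == "PAT_DMR" and delta < 0)
        )
        rows.append(
            {
                "name": row.name,
                "region_class": row.region_class,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "delta_log2": delta,
                "p_value": p,
                "passed": passed,
                "imprint_flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "region_class", "mean_a", "mean_b",
                 "delta_log2", "p_value", "passed", "imprint_flag"],
    )
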
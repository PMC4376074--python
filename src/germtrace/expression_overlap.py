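"""Differential expression contrasts and the G1R/G2R overlap analysis.

A per-transcript two-group linear contrast on log-scale expression stands
in for the original factorial ANOVA: log2 fold change from group means, a
two-sample equal-variance t-test, and Benjamini-Hochberg FDR. Named cutoff
profiles reproduce the screening grid: ``strict`` = |FC| >= 1.5 and FDR
q < 0.05; ``relaxed1`` = |FC| >= 1.5 and raw P < 0.05; ``relaxed2`` =
|FC| >= 1.05 and raw P < 0.05.

The overlap step asks whether changes seen in exposed-generation (G1R) germ
cells recur in the unexposed next generation (G2R): common transcripts pass
the profile in both lists, and direction concordance of the common set is
tested against the 50% expected for independent lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .persistence import DirectionEnrichment, direction_enrichment

#: profile name -> (minimum linear fold change, significance column, cutoff)
PROFILES: dict[str, tuple[float, str, float]] = {
    "strict": (1.5, "fdr_q", 0.05),
    "relaxed1": (1.5, "p_value", 0.05),
    "relaxed2": (1.05, "p_value", 0.05),
}

__all__ = ["PROFILES", "differential_expression", "g1_g2_overlap", "OverlapReport"]


def differential_expression(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    profile: str = "strict",
) -> pd.DataFrame:
    """Per-transcript contrast of two sample groups (A minus B, log2 scale).

    ``matrix`` is transcripts x samples on the log2 scale; ``group_a`` and
    ``group_b`` name sample columns (>= 2 each). Returns a frame indexed by
    transcript with log2_fc, p_value, fdr_q, direction, and ``passed`` under
    the named profile.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    a = matrix[group_a].to_numpy(float)
    b = matrix[group_b].to_numpy(float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance transcripts: no evidence
    q = multipletests(p, method="fdr_bh")[1]
    min_fold, sig_col, cutoff = PROFILES[profile]
    res = pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": p,
            "fdr_q": q,
            "direction": np.where(lfc > 0, "up", "down"),
        },
        index=matrix.index,
    )
    res.index.name = "transcript_id"
    res["passed"] = (np.abs(res["log2_fc"]) >= np.log2(min_fold)) & (res[sig_col] < cutoff)
    return res


@dataclass
class OverlapReport:
    """Common-change report between two differential-expression hit lists."""

    n_common: int
    n_same_direction: int
    common: pd.DataFrame  # transcript_id, direction_g1, direction_g2, same_direction
    enrichment: DirectionEnrichment


def g1_g2_overlap(de_g1: pd.DataFrame, de_g2: pd.DataFrame) -> OverlapReport:
    """Overlap and direction analysis of two DE result frames.

    Both frames must come from the same transcript universe (identical index
    sets) and already carry ``passed`` under the chosen profile. Multiple
    probes per transcript should be collapsed to one row (best p-value)
    before calling. Counts are symmetric in the list order.
    """
    if set(de_g1.index) != set(de_g2.index):
        raise ValueError("DE lists come from different transcript universes")
    hits1 = de_g1[de_g1["passed"]]
    hits2 = de_g2.loc[de_g2["passed"]]
    common_ids = hits1.index.intersection(hits2.index)
    common = pd.DataFrame(
        {
            "direction_g1": hits1.loc[common_ids, "direction"],
            "direction_g2": hits2.loc[common_ids, "direction"],
        }
    )
    common["same_direction"] = common["direction_g1"] == common["direction_g2"]
    n_common = len(common)
    n_same = int(common["same_direction"].sum())
    table = np.zeros((2, 2))
    for i, d1 in enumerate(("down", "up")):
        for j, d2 in enumerate(("down", "up")):
            table[i, j] = int(
                ((common["direction_g1"] == d1) & (common["direction_g2"] == d2)).sum()
            )
    return OverlapReport(
        n_common=n_common,
        n_same_direction=n_same,
        common=common,
        enrichment=direction_enrichment(n_common, n_same, table),
    )


def collapse_probes(de: pd.DataFrame, transcript_of: pd.Series) -> pd.DataFrame:
    """Collapse probe-level results to unique transcripts by best p-value."""
    de = de.copy()
    de["transcript"] = transcript_of.reindex(de.index)
    best = de.sort_values("p_value", kind="stable").groupby("transcript", sort=True).head(1)
    return best.set_index("transcript")
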
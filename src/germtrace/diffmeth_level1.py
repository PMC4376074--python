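"""Level-1 differential methylation between a treated and a control group.

Consensus peaks are first called in group A across its replicates; at each
peak the replicate-averaged per-probe signal defines the group means, and a
change is a hit when the mean difference exceeds the +/-5% fold cutoff
(|delta log2| >= log2(1.05), i.e. a minimum 1.05-fold increase or 0.95-fold
decrease) with a two-sided Fisher's exact test P < 0.05. The Fisher 2x2
table counts probes in the peak classified positive vs non-positive against
each replicate's own array-wide threshold, pooled over replicates, in group
A vs group B. Both A-vs-B directions are run so a change present in either
group's peaks is detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mira_peaks import (
    MethylationSampleGroup,
    Peak,
    consensus_peaks,
    positive_mask,
)

logger = logging.getLogger(__name__)

FOLD_CUTOFF = 1.05
DELTA_LOG2_CUTOFF = float(np.log2(FOLD_CUTOFF))
P_CUTOFF = 0.05
MIN_PEAK_PROBES = 4

__all__ = ["DifferentialCall", "level1_test", "bidirectional_level1",
           "FOLD_CUTOFF", "DELTA_LOG2_CUTOFF", "P_CUTOFF"]


@dataclass
class DifferentialCall:
    """One consensus-peak comparison between groups A and B."""

    chrom: str
    start: int
    end: int
    test_id: str
    mean_a: float
    mean_b: float
    delta_log2: float
    direction: str  # up / down, sign of delta_log2
    p_value: float
    passed: bool
    n_probes: int

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _fisher_table(
    probe_idx: np.ndarray,
    masks_a: np.ndarray,
    masks_b: np.ndarray,
) -> np.ndarray:
    """Pooled positive / non-positive probe counts for groups A and B.

    ``masks_*`` are (n_replicates, n_probes) boolean arrays of per-sample
    positivity. The table construction is isolated here so alternative
    contingency definitions can be swapped in.
    """
    pos_a = int(masks_a[:, probe_idx].sum())
    pos_b = int(masks_b[:, probe_idx].sum())
    tot_a = masks_a.shape[0] * len(probe_idx)
    tot_b = masks_b.shape[0] * len(probe_idx)
    return np.array([[pos_a, tot_a - pos_a], [pos_b, tot_b - pos_b]])


def level1_test(
    group_a: MethylationSampleGroup,
    group_b: MethylationSampleGroup,
    test_id: str = "Test",
    fold_cutoff: float = FOLD_CUTOFF,
    alpha: float = P_CUTOFF,
) -> list[DifferentialCall]:
    """Evaluate every consensus peak of group A against group B.

    Returns one :class:`DifferentialCall` per evaluated peak (hits are the
    calls with ``passed=True``). Consensus peaks retaining fewer than four
    probes after intersection are skipped with a logged warning.
    """
    if group_a.design is not group_b.design and group_a.design != group_b.design:
        raise ValueError("groups must share one ArrayDesign")
    if group_a.n_replicates < 2 or group_b.n_replicates < 2:
        raise ValueError("level-1 test needs >= 2 replicates per group")

    peaks = consensus_peaks(group_a)
    masks_a = np.vstack([positive_mask(v) for v in group_a.values])
    masks_b = np.vstack([positive_mask(v) for v in group_b.values])
    mean_a_probes = group_a.mean_values()
    mean_b_probes = group_b.mean_values()
    cutoff = float(np.log2(fold_cutoff))

    calls: list[DifferentialCall] = []
    for peak in peaks:
        if len(peak.probe_indices) < MIN_PEAK_PROBES:
            logger.warning(
                "%s: consensus peak %s:%d-%d has %d probes (<%d); skipped",
                test_id, peak.chrom, peak.start, peak.end,
                len(peak.probe_indices), MIN_PEAK_PROBES,
            )
            continue
        idx = peak.probe_indices
        mean_a = float(mean_a_probes[idx].mean())
        mean_b = float(mean_b_probes[idx].mean())
        delta = mean_a - mean_b
        table = _fisher_table(idx, masks_a, masks_b)
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        passed = abs(delta) >= cutoff and p < alpha
        calls.append(
            DifferentialCall(
                chrom=peak.chrom,
                start=peak.start,
                end=peak.end,
                test_id=test_id,
                mean_a=mean_a,
                mean_b=mean_b,
                delta_log2=delta,
                direction="up" if delta > 0 else "down",
                p_value=p,
                passed=passed,
                n_probes=len(idx),
            )
        )
    logger.info("%s: %d consensus peaks evaluated, %d hits (cutoff |dlog2|>=%.4f, p<%g)",
                test_id, len(calls), sum(c.passed for c in calls), cutoff, alpha)
    return calls


def bidirectional_level1(
    treated: MethylationSampleGroup,
    control: MethylationSampleGroup,
    labels: tuple[str, str] = ("treated_vs_control", "control_vs_treated"),
    fold_cutoff: float = FOLD_CUTOFF,
    alpha: float = P_CUTOFF,
) -> tuple[list[DifferentialCall], list[DifferentialCall]]:
    """Run the level-1 test in both directions (treated-as-A, control-as-A),
    so a change confined to either group's peaks is still detected."""
    fwd = level1_test(treated, control, labels[0], fold_cutoff, alpha)
    rev = level1_test(control, treated, labels[1], fold_cutoff, alpha)
    return fwd, rev
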
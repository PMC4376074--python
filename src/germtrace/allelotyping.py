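"""SNuPE allelotyping: calibration, linearity QC, and group comparison.

Single-nucleotide primer extension (SNuPE) on a mass-spec platform yields a
percent-maternal signal per SNP that carries a multiplicative instrument
skew. Calibration divides the observed maternal:paternal odds by the odds
measured on a known 50:50 standard (a true-heterozygote DNA sample for DNA,
a 50:50 RNA mix for RNA) — the unique monotone correction that fixes both
endpoints and maps the standard to exactly 50%. Mixing-series standards
(0, 10, 30, 50, 70, 90, 100 % maternal) verify a linear response.

Group comparisons follow the screening-table procedure: per SNP x organ x
endocrine disruptor, treated replicates are compared with vehicle ("oil")
replicates by an equal-variance two-sided Student's t-test; changes greater
than 5% with P < 0.05 are flagged (gt5; gt10 when greater than 10%), the
vehicle-group mean classifies the imprinted baseline (>= 80% maternal ->
MAT, <= 20% -> PAT, otherwise NO, i.e. erased or biallelic), and a
Bonferroni call at alpha/m over the declared family size marks the
comparisons that survive multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

FLAG_PCT = 5.0
FLAG_STRONG_PCT = 10.0
BASELINE_CUTOFF_PCT = 80.0
P_CUTOFF = 0.05

__all__ = [
    "skew_correct",
    "linearity_check",
    "LinearityResult",
    "compare_groups",
    "bonferroni_alpha",
    "BonferroniThreshold",
    "classify_baseline",
]


class CalibrationError(ValueError):
    """Degenerate calibration standard."""


def skew_correct(raw_maternal_pct, standard_observed_pct: float):
    """Correct a raw percent-maternal value against a 50:50 standard.

    Corrected odds = raw odds / standard odds, with odds = pct/(100 - pct);
    the endpoints 0 and 100 pass through unchanged and the standard itself
    maps to exactly 50. Accepts scalars or arrays.

    Raises :class:`CalibrationError` when the standard reads 0 or 100
    (odds undefined).
    """
    if not (0.0 < standard_observed_pct < 100.0):
        raise CalibrationError(
            f"standard observed at {standard_observed_pct}%: odds undefined"
        )
    raw = np.asarray(raw_maternal_pct, dtype=float)
    if np.any((raw < 0) | (raw > 100)):
        raise ValueError("raw_maternal_pct must lie in [0, 100]")
    s_odds = standard_observed_pct / (100.0 - standard_observed_pct)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = raw / (100.0 - raw) / s_odds
        corrected = np.where(raw >= 100.0, 100.0, 100.0 * odds / (1.0 + odds))
    return float(corrected) if corrected.ndim == 0 else corrected


class LinearityResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    passed: bool


def linearity_check(
    true_pct: np.ndarray,
    observed_pct: np.ndarray,
    r2_threshold: float = 0.95,
) -> LinearityResult:
    """OLS of (corrected) observed on true mixing percentages.

    QC passes when R^2 meets the threshold. Constant observations leave R^2
    undefined (NaN) and fail QC. Requires >= 3 distinct mixing points.
    """
    true_pct = np.asarray(true_pct, dtype=float)
    observed_pct = np.asarray(observed_pct, dtype=float)
    if len(np.unique(true_pct)) < 3:
        raise ValueError("linearity check needs >= 3 distinct mixing points")
    if np.ptp(observed_pct) == 0:
        return LinearityResult(np.nan, np.nan, np.nan, False)
    fit = stats.linregress(true_pct, observed_pct)
    r2 = float(fit.rvalue**2)
    return LinearityResult(float(fit.slope), float(fit.intercept), r2, r2 >= r2_threshold)


class BonferroniThreshold(NamedTuple):
    rounded: float  # alpha/m rounded half-up to 4 decimals, as printed
    exact: float  # unrounded, used for internal comparisons


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> BonferroniThreshold:
    """Family-wise threshold alpha/m, reported rounded half-up to 4 decimals."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    exact = alpha / m
    rounded = float(Decimal(repr(exact)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))
    return BonferroniThreshold(rounded, exact)


def classify_baseline(control_mean_maternal_pct: float) -> str:
    """Imprinted-baseline class from the vehicle-group percent maternal.

    >= 80% maternal -> "MAT"; <= 20% -> "PAT"; otherwise "NO" (erased or
    biallelic). The 80/20 boundaries are inclusive.
    """
    pct = float(control_mean_maternal_pct)
    if not (0.0 <= pct <= 100.0):
        raise ValueError("percent maternal must lie in [0, 100]")
    if pct >= BASELINE_CUTOFF_PCT:
        return "MAT"
    if pct <= 100.0 - BASELINE_CUTOFF_PCT:
        return "PAT"
    return "NO"


@dataclass
class ComparisonRow:
    """One SNP x organ x treatment comparison against vehicle."""

    snp_id: str
    organ: str
    treatment: str
    mean_oil: float
    mean_treated: float
    difference_pct: float
    sd_pct: float  # SD of the treated replicates
    p_value: float
    flag: str  # none / gt5 / gt10
    baseline: str  # MAT / PAT / NO
    bonferroni_significant: bool


def compare_groups(
    measurements: pd.DataFrame,
    family_size: int,
    alpha: float = P_CUTOFF,
    control_label: str = "oil",
    value_col: str = "maternal_pct",
) -> pd.DataFrame:
    """Screening-table comparison of treated vs vehicle per SNP x organ.

    ``measurements`` needs columns snp_id, organ, treatment, replicate and
    ``value_col`` (percent maternal, skew-corrected). Every stratum requires
    >= 2 replicates per treatment and a vehicle group. Returns one row per
    SNP x organ x non-vehicle treatment with the fields of
    :class:`ComparisonRow` as columns, ordered by difference.
    """
    required = {"snp_id", "organ", "treatment", value_col}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns {sorted(missing)}")
    threshold = bonferroni_alpha(alpha, family_size)
    rows: list[ComparisonRow] = []
    for (snp, organ), stratum in measurements.groupby(["snp_id", "organ"], sort=True):
        oil = stratum.loc[stratum["treatment"] == control_label, value_col].to_numpy(float)
        if len(oil) == 0:
            raise ValueError(f"missing {control_label!r} group for {snp}/{organ}")
        if len(oil) < 2:
            raise ValueError(f"{snp}/{organ}: {control_label!r} group needs >= 2 replicates")
        baseline = classify_baseline(float(oil.mean()))
        for trt, sub in stratum[stratum["treatment"] != control_label].groupby(
            "treatment", sort=True
        ):
            treated = sub[value_col].to_numpy(float)
            if len(treated) < 2:
                raise ValueError(f"{snp}/{organ}/{trt}: needs >= 2 replicates")
            diff = float(treated.mean() - oil.mean())
            if np.ptp(treated) == 0 and np.ptp(oil) == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                p = float(stats.ttest_ind(treated, oil, equal_var=True).pvalue)
            flag = "none"
            if abs(diff) > FLAG_PCT and p < alpha:
                flag = "gt10" if abs(diff) > FLAG_STRONG_PCT else "gt5"
            rows.append(
                ComparisonRow(
                    snp_id=snp,
                    organ=organ,
                    treatment=trt,
                    mean_oil=float(oil.mean()),
                    mean_treated=float(treated.mean()),
                    difference_pct=diff,
                    sd_pct=float(treated.std(ddof=1)),
                    p_value=p,
                    flag=flag,
                    baseline=baseline,
                    bonferroni_significant=p < threshold.exact,
                )
            )
    frame = pd.DataFrame([vars(r) for r in rows])
    if len(frame):
        frame = frame.sort_values("difference_pct", kind="stable").reset_index(drop=True)
    return frame
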
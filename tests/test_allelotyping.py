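"""Skew correction, linearity QC, baseline classes, and the comparison table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germtrace.allelotyping import (
    CalibrationError,
    bonferroni_alpha,
    classify_baseline,
    compare_groups,
    linearity_check,
    skew_correct,
)
from germtrace.synthetic_data import apply_skew


class TestSkewCorrect:
    def test_identity_when_standard_reads_50(self):
        assert skew_correct(73.0, 50.0) == pytest.approx(73.0)

    def test_standard_maps_to_exactly_50(self):
        assert skew_correct(66.667, 66.667) == pytest.approx(50.0)

    def test_twofold_skew_example(self):
        # raw odds 75/25 = 3, standard odds 2 -> corrected odds 1.5 -> 60%
        assert skew_correct(75.0, 200 / 3) == pytest.approx(60.0)

    def test_endpoints_pass_through(self):
        assert skew_correct(0.0, 66.0) == 0.0
        assert skew_correct(100.0, 66.0) == 100.0

    @pytest.mark.parametrize("standard", [0.0, 100.0])
    def test_degenerate_standard_rejected(self, standard):
        with pytest.raises(CalibrationError):
            skew_correct(50.0, standard)

    @given(
        f=st.floats(0.01, 0.99),
        skew=st.sampled_from([0.2, 0.5, 1.0, 2.0, 5.0]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inverts_generative_skew_exactly(self, f, skew):
        """Correction against the skewed 50:50 standard recovers the truth."""
        observed = 100.0 * apply_skew(f, skew)
        standard = 100.0 * apply_skew(0.5, skew)
        assert skew_correct(observed, standard) == pytest.approx(100.0 * f, abs=1e-9)

    def test_strictly_increasing_in_raw(self):
        raw = np.linspace(0.5, 99.5, 199)
        corrected = skew_correct(raw, 66.0)
        assert np.all(np.diff(corrected) > 0)


class TestLinearityCheck:
    SERIES = np.array([0.0, 10.0, 30.0, 50.0, 70.0, 90.0, 100.0])

    def test_perfect_series(self):
        result = linearity_check(self.SERIES, self.SERIES)
        assert result.slope == pytest.approx(1.0)
        assert result.intercept == pytest.approx(0.0)
        assert result.r_squared == pytest.approx(1.0)
        assert result.passed

    def test_skewed_then_corrected_series_near_identity(self):
        observed = 100.0 * apply_skew(self.SERIES / 100.0, 2.0)
        standard = 100.0 * apply_skew(0.5, 2.0)
        corrected = skew_correct(observed, standard)
        result = linearity_check(self.SERIES, corrected)
        assert result.r_squared == pytest.approx(1.0)
        assert 0.9 <= result.slope <= 1.1

    def test_constant_observations_fail_qc(self):
        result = linearity_check(self.SERIES, np.full(7, 42.0))
        assert np.isnan(result.r_squared)
        assert not result.passed

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linearity_check([0.0, 100.0], [1.0, 99.0])


class TestBonferroni:
    @pytest.mark.parametrize("m, expected", [(28, 0.0018), (56, 0.0009),
                                             (33, 0.0015), (1, 0.05)])
    def test_printed_thresholds(self, m, expected):
        assert bonferroni_alpha(0.05, m).rounded == expected

    def test_exact_value_times_m_recovers_alpha(self):
        for m in (1, 7, 28, 56, 33, 101):
            assert bonferroni_alpha(0.05, m).exact * m == pytest.approx(0.05)

    def test_zero_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestClassifyBaseline:
    @pytest.mark.parametrize("pct, expected", [
        (100.0, "MAT"),   # fully maternally methylated DMR
        (95.0, "MAT"),
        (80.0, "MAT"),    # cutoff inclusive
        (79.99, "NO"),
        (73.0, "NO"),     # erased / biallelic
        (20.01, "NO"),
        (20.0, "PAT"),    # cutoff inclusive
        (5.0, "PAT"),     # paternally methylated DMR
        (0.0, "PAT"),
    ])
    def test_partition(self, pct, expected):
        assert classify_baseline(pct) == expected

    @given(st.floats(0, 100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_total_partition_no_gaps(self, pct):
        assert classify_baseline(pct) in {"MAT", "PAT", "NO"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_baseline(101.0)


def measurements_for(snp, organ, treatment_values: dict) -> pd.DataFrame:
    rows = []
    for trt, values in treatment_values.items():
        for r, v in enumerate(values):
            rows.append({"snp_id": snp, "organ": organ, "treatment": trt,
                         "replicate": r + 1, "maternal_pct": v})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_strong_loss_of_maternal_bias_flagged_gt10(self):
        # fully maternal baseline dropping ~23%: strong flag, MAT baseline
        df = measurements_for("Peg10", "placenta", {
            "oil": [100.0, 100.0, 100.0],
            "VZ": [77.0, 76.0, 78.0],
        })
        rows = compare_groups(df, family_size=28)
        row = rows.iloc[0]
        assert row["baseline"] == "MAT"
        assert row["flag"] == "gt10"
        assert row["difference_pct"] == pytest.approx(-23.0)
        assert row["bonferroni_significant"]

    def test_paternal_baseline_classified(self):
        df = measurements_for("IG-DMR", "lung", {
            "oil": [5.0, 4.0, 6.0],
            "VZ": [10.0, 11.0, 10.3],
        })
        rows = compare_groups(df, family_size=28)
        assert rows.iloc[0]["baseline"] == "PAT"
        assert rows.iloc[0]["flag"] == "gt5"

    def test_erased_baseline_classified_no(self):
        df = measurements_for("Zac1", "placenta", {
            "oil": [73.0, 72.0, 74.0],
            "VZ": [70.0, 71.0, 69.0],
        })
        rows = compare_groups(df, family_size=28)
        assert rows.iloc[0]["baseline"] == "NO"

    def test_identical_groups_unflagged(self):
        df = measurements_for("s", "liver", {
            "oil": [60.0, 61.0, 59.0],
            "BPA": [60.0, 61.0, 59.0],
        })
        rows = compare_groups(df, family_size=10)
        assert rows.iloc[0]["difference_pct"] == 0.0
        assert rows.iloc[0]["flag"] == "none"

    def test_large_but_insignificant_difference_unflagged(self):
        # difference ~6% but very noisy replicates: p >> 0.05
        df = measurements_for("s", "liver", {
            "oil": [50.0, 70.0, 60.0],
            "BPA": [56.0, 76.0, 66.0],
        })
        rows = compare_groups(df, family_size=10)
        assert abs(rows.iloc[0]["difference_pct"]) > 5
        assert rows.iloc[0]["p_value"] > 0.05
        assert rows.iloc[0]["flag"] == "none"

    def test_missing_vehicle_group_rejected(self):
        df = measurements_for("s", "liver", {"BPA": [50.0, 51.0]})
        with pytest.raises(ValueError, match="oil"):
            compare_groups(df, family_size=10)

    def test_sd_column_is_treated_group_sd(self):
        treated = [70.0, 75.0, 80.0]
        df = measurements_for("s", "liver", {"oil": [50.0, 50.0, 50.0],
                                             "BPA": treated})
        rows = compare_groups(df, family_size=10)
        assert rows.iloc[0]["sd_pct"] == pytest.approx(np.std(treated, ddof=1))

    def test_chance_flag_rate_on_null_measurements(self, rng):
        """Null screen: flagged fraction stays near the per-test alpha bound."""
        rows = []
        for snp in range(60):
            for trt in ("oil", "VZ"):
                for r in range(3):
                    rows.append({"snp_id": f"s{snp}", "organ": "lung",
                                 "treatment": trt, "replicate": r + 1,
                                 "maternal_pct": float(np.clip(
                                     rng.normal(50, 4), 0, 100))})
        result = compare_groups(pd.DataFrame(rows), family_size=60)
        flag_rate = (result["flag"] != "none").mean()
        assert flag_rate <= 0.05 + 1.645 * np.sqrt(0.05 * 0.95 / 60)
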
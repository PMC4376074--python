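"""Generator contracts: determinism, generative formulas, persistence scenarios."""

import numpy as np
import pytest

from germtrace.synthetic_data import (
    AllelotypeSimConfig,
    ConfigurationError,
    ExpressionGroup,
    SimulationConfig,
    apply_skew,
    simulate_allelotypes,
    simulate_expression,
    simulate_methylome,
)


def small_cfg(**kw) -> SimulationConfig:
    base = dict(seed=7, n_chromosomes=2, probes_per_chromosome=400,
                n_spiked_regions=6, probes_per_region=8)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateMethylome:
    def test_identical_seeds_give_identical_outputs(self):
        d1, g1, t1 = simulate_methylome(small_cfg())
        d2, g2, t2 = simulate_methylome(small_cfg())
        assert d1 == d2
        assert sorted(g1) == sorted(g2)
        for label in g1:
            assert np.array_equal(g1[label].values, g2[label].values)
        assert t1.to_frame().equals(t2.to_frame())

    def test_all_eight_groups_present_with_replicates(self):
        _, groups, _ = simulate_methylome(small_cfg(n_replicates=3))
        assert len(groups) == 8
        for label, group in groups.items():
            assert group.n_replicates == 3, label

    def _spike_mask(self, design, truth):
        mids = design.midpoints()
        mask = np.zeros(design.n_probes, dtype=bool)
        for row in truth.frame.itertuples(index=False):
            mask |= (design.chroms == row.chrom) & (mids >= row.start) & (mids < row.end)
        return mask

    def test_effect_confined_to_immediate_group_when_no_persistence(self):
        cfg = small_cfg(persistence="none", effect_log2_delta=0.5)
        design, groups, truth = simulate_methylome(cfg)
        spike = self._spike_mask(design, truth)
        shift = {
            label: groups[label].values[:, spike].mean()
            - groups[label.replace("VZ", "oil")].values[:, spike].mean()
            for label in groups if label.endswith("VZ")
        }
        se = cfg.baseline_log2_sd / np.sqrt(spike.sum() * cfg.n_replicates) * np.sqrt(2)
        assert shift["G1R_MGC_VZ"] == pytest.approx(0.5, abs=3 * se)
        for label in ("G1R_sperm_VZ", "G2R_MGC_VZ", "G2R_sperm_VZ"):
            assert abs(shift[label]) < 3 * se

    def test_full_tgi_shifts_all_four_treated_groups(self):
        cfg = small_cfg(persistence="full_tgi", effect_log2_delta=0.5)
        design, groups, truth = simulate_methylome(cfg)
        spike = self._spike_mask(design, truth)
        se = cfg.baseline_log2_sd / np.sqrt(spike.sum() * cfg.n_replicates) * np.sqrt(2)
        for label in [l for l in groups if l.endswith("VZ")]:
            shift = (groups[label].values[:, spike].mean()
                     - groups[label.replace("VZ", "oil")].values[:, spike].mean())
            assert shift == pytest.approx(0.5, abs=3 * se), label

    def test_group_means_match_generative_formula(self):
        cfg = small_cfg()
        design, groups, truth = simulate_methylome(cfg)
        spike = self._spike_mask(design, truth)
        oil = groups["G1R_MGC_oil"]
        se_bg = cfg.baseline_log2_sd / np.sqrt((~spike).sum() * cfg.n_replicates)
        se_sp = cfg.baseline_log2_sd / np.sqrt(spike.sum() * cfg.n_replicates)
        assert oil.values[:, ~spike].mean() == pytest.approx(
            cfg.baseline_log2_mean, abs=3 * se_bg)
        assert oil.values[:, spike].mean() == pytest.approx(
            cfg.methylated_region_log2_mean, abs=3 * se_sp)

    def test_spiked_regions_disjoint_from_background(self):
        design, _, truth = simulate_methylome(small_cfg())
        spike = self._spike_mask(design, truth)
        assert spike.sum() == 6 * 8  # regions never overlap each other

    @pytest.mark.parametrize("field, value", [
        ("probes_per_chromosome", 0),
        ("probe_spacing_bp", -1),
        ("n_replicates", 1),
        ("persistence", "sometimes"),
    ])
    def test_invalid_configuration_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            simulate_methylome(small_cfg(**{field: value}))


class TestSimulateAllelotypes:
    def test_identity_skew_noise_free_passthrough(self):
        cfg = AllelotypeSimConfig(snp_ids=["s"], true_maternal_fraction={"s": 0.5},
                                  skew_ratio=1.0, noise_sd=0.0)
        meas, _ = simulate_allelotypes(cfg)
        assert meas["observed_maternal_fraction"].unique() == pytest.approx([0.5])

    def test_twofold_skew_on_heterozygote(self):
        # independent odds-scale computation: odds 1 * 2 = 2 -> 2/3
        cfg = AllelotypeSimConfig(snp_ids=["s"], true_maternal_fraction={"s": 0.5},
                                  skew_ratio=2.0, noise_sd=0.0)
        meas, standards = simulate_allelotypes(cfg)
        assert meas["observed_maternal_fraction"].unique() == pytest.approx([2 / 3])
        het = standards[standards["kind"] == "het_dna"]
        assert het["observed_maternal_pct"].iloc[0] == pytest.approx(100 * 2 / 3)

    @pytest.mark.parametrize("skew", [0.25, 0.5, 1.0, 2.0, 5.0])
    def test_boundaries_fixed_under_any_skew(self, skew):
        assert apply_skew(0.0, skew) == 0.0
        assert apply_skew(1.0, skew) == 1.0

    def test_default_standard_series(self):
        _, standards = simulate_allelotypes(AllelotypeSimConfig())
        mixing = standards[standards["kind"] == "mixing_point"]
        assert mixing["true_maternal_pct"].tolist() == [0, 10, 30, 50, 70, 90, 100]

    def test_nonpositive_skew_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_allelotypes(AllelotypeSimConfig(skew_ratio=0.0))

    def test_fractions_clipped_to_unit_interval(self):
        cfg = AllelotypeSimConfig(snp_ids=["s"], true_maternal_fraction={"s": 0.99},
                                  noise_sd=0.5, n_replicates=50, seed=3)
        meas, _ = simulate_allelotypes(cfg)
        obs = meas["observed_maternal_fraction"]
        assert obs.between(0, 1).all()
        assert (obs == 1.0).any()  # clipping actually engaged


class TestSimulateExpression:
    GROUPS = [
        ExpressionGroup("G1R_oil_F", "F", "G1R", "oil"),
        ExpressionGroup("G1R_oil_M", "M", "G1R", "oil"),
        ExpressionGroup("G1R_VZ_M", "M", "G1R", "VZ"),
    ]

    def test_null_simulation_has_empty_truth(self):
        _, _, truth = simulate_expression(
            200, self.GROUPS, sex_effect_log2=0.0, n_sex_genes=0,
            treatment_effect_log2=0.0, n_treatment_genes=0, seed=1)
        assert not truth["treatment_effect"].any()

    def test_sex_genes_dominate_female_male_contrast(self):
        matrix, meta, truth = simulate_expression(
            2000, self.GROUPS, sex_effect_log2=2.0, n_sex_genes=200,
            n_treatment_genes=0, noise_sd=0.1, seed=5)
        males = meta.loc[meta["group"] == "G1R_oil_M", "sample_id"]
        females = meta.loc[meta["group"] == "G1R_oil_F", "sample_id"]
        diff = matrix[list(males)].mean(axis=1) - matrix[list(females)].mean(axis=1)
        top = diff.nlargest(200).index
        expected = set(truth.loc[truth["sex_effect"], "transcript_id"])
        assert set(top) == expected

    def test_seed_reproducibility(self):
        m1, _, _ = simulate_expression(100, self.GROUPS, seed=9, n_sex_genes=10,
                                       n_treatment_genes=10)
        m2, _, _ = simulate_expression(100, self.GROUPS, seed=9, n_sex_genes=10,
                                       n_treatment_genes=10)
        assert m1.equals(m2)

    def test_empty_design_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_expression(10, [])
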
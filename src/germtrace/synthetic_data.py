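"""Synthetic inputs for every pipeline stage.

The generators emulate the data structure of a transgenerational
germline-methylation study: replicated log2(MIRA/input) tiling-array groups
for exposed (G1R) and unexposed-descendant (G2R) prospermatogonia (MGC) and
sperm, with spiked methylated regions whose treatment effect persists across
a configurable set of germline stages; SNuPE allele-fraction measurements
with a multiplicative instrument skew and mixing-series standards; and
log-scale expression matrices with sex, generation, and treatment effects.

Skew acts on the maternal:paternal odds: with true maternal fraction ``f``
and skew ratio ``s``, the observed fraction is ``s*f / (s*f + (1 - f))``,
matching how preferential allele incorporation biases mass-spec peak ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mira_peaks import ArrayDesign, MethylationSampleGroup, SampleMeta
from .region_summary import RegionSet

GROUP_CELLS: tuple[tuple[str, str], ...] = (
    ("G1R", "MGC"),
    ("G1R", "sperm"),
    ("G2R", "MGC"),
    ("G2R", "sperm"),
)

#: germline stages carrying the treatment effect, per persistence scenario:
#: the immediate effect is always present in exposed G1R prospermatogonia;
#: `persistence` states how far it survives reprogramming.
PERSISTENCE_GROUPS: dict[str, frozenset[tuple[str, str]]] = {
    "none": frozenset({("G1R", "MGC")}),
    "g1_only": frozenset({("G1R", "MGC"), ("G1R", "sperm")}),
    "g1_and_sperm": frozenset({("G1R", "MGC"), ("G1R", "sperm"), ("G2R", "MGC")}),
    "full_tgi": frozenset(GROUP_CELLS),
}

DEFAULT_STANDARD_RATIOS: tuple[float, ...] = (0.0, 10.0, 30.0, 50.0, 70.0, 90.0, 100.0)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Conditions for one simulated methylome experiment.

    Defaults mirror the study design: four germline stages x {oil, treated}
    hybridised on one shared array design, n = 3 biological replicates,
    Gaussian probe noise of 0.1 on the log2 scale. Spiked regions emulate
    regions of intermediate methylation sitting just above the positivity
    threshold in controls — the only regime in which the count-based
    differential test has power — elevated by ``methylated_region_log2_mean``
    in every group and additionally by ``effect_log2_delta`` in the treated
    groups selected by ``persistence``.
    """

    seed: int = 0
    n_chromosomes: int = 4
    probes_per_chromosome: int = 2500
    probe_spacing_bp: int = 100
    probe_length_bp: int = 50
    baseline_log2_mean: float = 0.0
    baseline_log2_sd: float = 0.1
    methylated_region_log2_mean: float = 0.15
    n_spiked_regions: int = 20
    probes_per_region: int = 10
    effect_log2_delta: float = 0.5
    persistence: str = "none"
    n_replicates: int = 3
    treatment: str = "VZ"
    platform: str = "custom"

    def validate(self) -> None:
        for name in ("n_chromosomes", "probes_per_chromosome", "probe_spacing_bp",
                     "probe_length_bp", "probes_per_region"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.probe_length_bp > self.probe_spacing_bp:
            raise ConfigurationError("probe_length_bp > probe_spacing_bp gives overlapping probes")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.n_spiked_regions < 0:
            raise ConfigurationError("n_spiked_regions must be >= 0")
        if self.persistence not in PERSISTENCE_GROUPS:
            raise ConfigurationError(
                f"persistence must be one of {sorted(PERSISTENCE_GROUPS)}"
            )
        per_chrom = self.n_spiked_regions * self.probes_per_region / self.n_chromosomes
        if per_chrom * 2 > self.probes_per_chromosome:
            raise ConfigurationError("spiked regions would cover more than half of each chromosome")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


def _build_design(cfg: SimulationConfig) -> ArrayDesign:
    ids, chroms, starts, ends = [], [], [], []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        for p in range(cfg.probes_per_chromosome):
            s = p * cfg.probe_spacing_bp
            ids.append(f"{chrom}_P{p:06d}")
            chroms.append(chrom)
            starts.append(s)
            ends.append(s + cfg.probe_length_bp)
    return ArrayDesign(ids, chroms, starts, ends)


def _spike_layout(cfg: SimulationConfig, rng: np.random.Generator,
                  design: ArrayDesign) -> tuple[np.ndarray, RegionSet]:
    """Choose disjoint spiked probe blocks; return probe mask and truth regions."""
    mask = np.zeros(design.n_probes, dtype=bool)
    records = []
    n_per_chrom = np.zeros(cfg.n_chromosomes, dtype=int)
    for i in range(cfg.n_spiked_regions):
        n_per_chrom[i % cfg.n_chromosomes] += 1
    region_i = 0
    for c, n_regions in enumerate(n_per_chrom):
        if n_regions == 0:
            continue
        # >= 2 background probes between blocks so the single-gap allowance
        # can never merge two spiked regions into one run
        slot_len = cfg.probes_per_region + 2
        n_slots = cfg.probes_per_chromosome // slot_len
        slots = rng.choice(n_slots, size=n_regions, replace=False)
        slots.sort()
        lo = c * cfg.probes_per_chromosome
        for slot in slots:
            first = lo + slot * slot_len
            idx = np.arange(first, first + cfg.probes_per_region)
            mask[idx] = True
            records.append(
                (
                    f"spike_{region_i:04d}",
                    f"chr{c + 1}",
                    int(design.starts[idx[0]]),
                    int(design.ends[idx[-1]]),
                    "control",
                )
            )
            region_i += 1
    return mask, RegionSet.from_records(records)


def simulate_methylome(
    cfg: SimulationConfig,
) -> tuple[ArrayDesign, dict[str, MethylationSampleGroup], RegionSet]:
    """Simulate replicated MIRA/input log2 arrays for all eight sample groups.

    Returns the shared array design, a mapping from group label (e.g.
    ``"G1R_MGC_oil"``) to its replicated sample group, and the spiked-region
    ground truth. Identical configs give identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = _build_design(cfg)
    spike_mask, truth = _spike_layout(cfg, rng, design)
    affected = PERSISTENCE_GROUPS[cfg.persistence]

    groups: dict[str, MethylationSampleGroup] = {}
    for generation, cell_type in GROUP_CELLS:
        for treatment in ("oil", cfg.treatment):
            label = f"{generation}_{cell_type}_{treatment}"
            mu = np.full(design.n_probes, cfg.baseline_log2_mean)
            mu[spike_mask] = cfg.methylated_region_log2_mean
            if treatment != "oil" and (generation, cell_type) in affected:
                mu[spike_mask] += cfg.effect_log2_delta
            values = mu[None, :] + rng.normal(
                0.0, cfg.baseline_log2_sd, size=(cfg.n_replicates, design.n_probes)
            )
            meta = SampleMeta(generation, cell_type, treatment, cfg.platform)
            groups[label] = MethylationSampleGroup(
                design=design,
                sample_ids=[f"{label}_r{i + 1}" for i in range(cfg.n_replicates)],
                metadata=[meta] * cfg.n_replicates,
                values=values,
            )
    return design, groups, truth


def simulate_dmr_methylome(
    regions: RegionSet,
    pat_log2: float = 1.0,
    mat_log2: float = -1.0,
    baseline_log2: float = 0.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    probes_per_region: int = 8,
    probe_spacing_bp: int = 100,
    probe_length_bp: int = 50,
    mat_shift: float = 0.0,
    pat_shift: float = 0.0,
    seed: int = 0,
) -> tuple[ArrayDesign, MethylationSampleGroup, MethylationSampleGroup, RegionSet]:
    """Male-germline methylome over imprinted DMRs and flank regions.

    Builds a probe design covering each region with ``probes_per_region``
    probes, an "oil" group with the expected sign pattern (paternally
    methylated DMRs positive, maternally methylated DMRs negative on the
    log2 MIRA/input scale), and a "treated" group optionally perturbed at
    MAT (``mat_shift``) or PAT (``pat_shift``) regions.
    """
    if n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    class_mu = {"PAT_DMR": pat_log2, "MAT_DMR": mat_log2,
                "IAP_flank": baseline_log2, "control": baseline_log2}
    ids, chroms, starts, ends, mu_oil, mu_trt = [], [], [], [], [], []
    df = regions.to_frame().sort_values(["chrom", "start"], kind="stable")
    offset: dict[str, int] = {}
    for row in df.itertuples(index=False):
        base = offset.get(row.chrom, 0)
        for p in range(probes_per_region):
            s = base + p * probe_spacing_bp
            ids.append(f"{row.name}_P{p:02d}")
            chroms.append(row.chrom)
            starts.append(s)
            ends.append(s + probe_length_bp)
            m = class_mu[row.region_class]
            mu_oil.append(m)
            shift = {"MAT_DMR": mat_shift, "PAT_DMR": pat_shift}.get(row.region_class, 0.0)
            mu_trt.append(m + shift)
        offset[row.chrom] = base + (probes_per_region + 2) * probe_spacing_bp
    design = ArrayDesign(ids, chroms, starts, ends)
    # rewrite regions onto the generated probe coordinates
    new_records = []
    i = 0
    for row in df.itertuples(index=False):
        s = int(design.starts[i])
        e = int(design.ends[i + probes_per_region - 1])
        new_records.append((row.name, row.chrom, s, e, row.region_class))
        i += probes_per_region
    placed = RegionSet.from_records(new_records)

    def _group(mu: list[float], treatment: str) -> MethylationSampleGroup:
        arr = np.asarray(mu)[None, :] + rng.normal(
            0.0, noise_sd, size=(n_replicates, design.n_probes)
        )
        meta = SampleMeta("G1R", "MGC", treatment, "custom")
        return MethylationSampleGroup(
            design=design,
            sample_ids=[f"{treatment}_r{i + 1}" for i in range(n_replicates)],
            metadata=[meta] * n_replicates,
            values=arr,
        )

    return design, _group(mu_oil, "oil"), _group(mu_trt, "VZ"), placed


@dataclass
class AllelotypeSimConfig:
    """Conditions for simulated SNuPE allele-fraction measurements."""

    seed: int = 0
    snp_ids: Sequence[str] = ("snp1",)
    true_maternal_fraction: Mapping[str, float] = field(default_factory=lambda: {"snp1": 0.5})
    skew_ratio: float = 1.0
    noise_sd: float = 0.0
    n_replicates: int = 3
    standard_ratios: Sequence[float] = DEFAULT_STANDARD_RATIOS

    def validate(self) -> None:
        if self.skew_ratio <= 0:
            raise ConfigurationError("skew_ratio must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for snp in self.snp_ids:
            f = self.true_maternal_fraction.get(snp)
            if f is None or not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"true_maternal_fraction for {snp!r} must lie in [0, 1]")


def apply_skew(f: np.ndarray | float, skew_ratio: float) -> np.ndarray | float:
    """Observed maternal fraction under multiplicative odds skew ``s``:
    ``s*f / (s*f + (1 - f))``. Fixes 0 and 1; the identity at s = 1."""
    f = np.asarray(f, dtype=float)
    out = skew_ratio * f / (skew_ratio * f + (1.0 - f))
    return float(out) if out.ndim == 0 else out


def simulate_allelotypes(cfg: AllelotypeSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw SNuPE maternal fractions plus calibration standards.

    The measurements table has one row per SNP x replicate with the skewed,
    noise-perturbed maternal fraction (clipped to [0, 1]). The standards
    table carries the mixing series and a true-heterozygote (f = 0.5)
    standard measured under the same skew.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for snp in cfg.snp_ids:
        f = cfg.true_maternal_fraction[snp]
        obs = apply_skew(f, cfg.skew_ratio) + rng.normal(0, cfg.noise_sd, cfg.n_replicates)
        obs = np.clip(obs, 0.0, 1.0)
        for r, o in enumerate(obs):
            rows.append({"snp_id": snp, "replicate": r + 1,
                         "true_maternal_fraction": f, "observed_maternal_fraction": float(o)})
    measurements = pd.DataFrame(rows)

    std_rows = []
    for pct in cfg.standard_ratios:
        f = pct / 100.0
        o = float(np.clip(apply_skew(f, cfg.skew_ratio)
                          + rng.normal(0, cfg.noise_sd), 0.0, 1.0))
        std_rows.append({"kind": "mixing_point", "true_maternal_pct": float(pct),
                         "observed_maternal_pct": 100.0 * o})
    o = float(np.clip(apply_skew(0.5, cfg.skew_ratio) + rng.normal(0, cfg.noise_sd), 0.0, 1.0))
    std_rows.append({"kind": "het_dna", "true_maternal_pct": 50.0,
                     "observed_maternal_pct": 100.0 * o})
    standards = pd.DataFrame(std_rows)
    return measurements, standards


@dataclass
class ExpressionGroup:
    """One expression sample group (e.g. G1R VZ male) with replicate count."""

    label: str
    sex: str  # F or M
    generation: str  # G1R or G2R
    treatment: str  # oil, BPA, VZ, DEHP
    n_replicates: int = 3


def simulate_expression(
    n_genes: int,
    groups: Sequence[ExpressionGroup],
    sex_effect_log2: float = 2.0,
    n_sex_genes: int = 500,
    treatment_effect_log2: float = 1.0,
    n_treatment_genes: int = 100,
    affected_groups: Sequence[str] = (),
    baseline_log2: float = 8.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log2-scale expression matrix with sex and treatment effects.

    A designated gene subset carries an additive sex effect (up in males),
    emulating sex as the dominant axis of variation in fetal germ cells;
    a disjoint truth subset carries the treatment effect in the groups named
    by ``affected_groups`` (up-regulated). Returns (matrix genes x samples,
    sample metadata, truth labels).
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if not groups:
        raise ConfigurationError("empty design")
    for g in groups:
        if g.n_replicates < 2:
            raise ConfigurationError(f"group {g.label!r} needs >= 2 replicates")
    if n_sex_genes + n_treatment_genes > n_genes:
        raise ConfigurationError("effect gene subsets exceed n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    sex_genes = np.arange(n_sex_genes)
    trt_genes = np.arange(n_sex_genes, n_sex_genes + n_treatment_genes)

    cols, meta_rows = [], []
    data = []
    for g in groups:
        mu = np.full(n_genes, baseline_log2)
        if g.sex == "M":
            mu[sex_genes] += sex_effect_log2
        if g.label in affected_groups:
            mu[trt_genes] += treatment_effect_log2
        for r in range(g.n_replicates):
            col = f"{g.label}_r{r + 1}"
            cols.append(col)
            meta_rows.append({"sample_id": col, "group": g.label, "sex": g.sex,
                              "generation": g.generation, "treatment": g.treatment,
                              "replicate": r + 1})
            data.append(mu + rng.normal(0, noise_sd, n_genes))
    matrix = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    matrix.index.name = "transcript_id"
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        {
            "transcript_id": gene_ids,
            "sex_effect": np.isin(np.arange(n_genes), sex_genes),
            "treatment_effect": np.isin(np.arange(n_genes), trt_genes)
            if affected_groups else False,
        }
    )
    return matrix, meta, truth
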
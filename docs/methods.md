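# Methods

## Problem and model

germtrace implements the computational side of a transgenerational
epigenetic inheritance (TGI) screen in the mouse male germline. The
question is whether an epigenetic change induced in exposed fetal germ
cells survives germline reprogramming: a true TGI candidate must appear in
exposed G1R prospermatogonia (MGC), be maintained into G1R sperm, recur in
the unexposed G2R prospermatogonia, and again in G2R sperm. The package
provides the four analysis arms around that question:

1. **MIRA-chip differential methylation.** Per-probe signal is the
   normalised log2(MIRA/input) ratio of methylated-DNA capture against
   input on a tiling array. A probe is *positive* when its value lies
   strictly above the 95th percentile of all probes on that sample's array
   (sorted-order linear interpolation). A *peak* is a maximal run of at
   least four positive probes allowing at most one interior non-positive
   probe; runs never cross chromosome boundaries. Consensus peaks of a
   replicated group are interval intersections of per-replicate peaks that
   overlap in every replicate. A level-1 differential call at a consensus
   peak of group A requires |mean_A − mean_B| ≥ log2(1.05) (the ±5% fold
   cutoff) and a two-sided Fisher's exact P < 0.05 on the 2×2 table of
   positive vs non-positive probe counts inside the peak, pooled over
   replicates, A vs B. Both A/B orientations are run so changes confined
   to either group's peaks are detected.
2. **Persistence intersection (levels 2–4).** Two hits are *common* when
   their regions overlap by ≥ 1 bp; common pairs are merged to the
   intersection interval. Level 2 intersects hit lists across generations,
   level 3 across germ-cell stages, level 4 across all four lists.
   Direction concordance is binary on the sign of the log2 change. For
   direction cross-tables, fold enrichment is observed/expected under
   row–column independence, with a two-sided Fisher exact p and an exact
   binomial test of the same-direction fraction against 0.5.
3. **Region averages.** Imprinted DMRs and unique 1-kb IAP-flank regions
   are scored as the unweighted mean log2(MIRA/input) over probes whose
   midpoint falls in the region, per replicate; changes are tested by an
   equal-variance Student's t at the same ±5% / P < 0.05 cutoffs. The
   imprint screen flags only the biologically harmful directions:
   maternally methylated DMRs gaining, or paternally methylated DMRs
   losing, methylation under treatment.
4. **SNuPE allelotyping.** Observed percent-maternal values carry a
   multiplicative skew on the maternal:paternal odds; calibration divides
   the raw odds by the odds of a measured 50:50 standard. This is the
   unique monotone correction fixing 0 and 100 and mapping the standard to
   exactly 50, and it inverts the generative skew exactly at zero noise.
   Screening comparisons use equal-variance t-tests with >5%/>10% flags at
   P < 0.05, an inclusive 80%/20% baseline classification (MAT/PAT/NO),
   and Bonferroni thresholds α/m reported rounded half-up to 4 decimals
   (0.05/28 → 0.0018, 0.05/56 → 0.0009, 0.05/33 → 0.0015).
5. **Expression overlap.** A per-transcript two-group contrast (equal-
   variance t, fold change from group means, Benjamini–Hochberg FDR)
   stands in for the original factorial ANOVA, whose exact model matrix is
   unpublished. Cutoff profiles: strict (|FC| ≥ 1.5, q < 0.05), relaxed1
   (|FC| ≥ 1.5, P < 0.05), relaxed2 (|FC| ≥ 1.05, P < 0.05). Probe-level
   results are collapsed to unique transcripts by best p-value before
   overlap counting.

## Synthetic-data generators

The generators produce every input the pipeline consumes with the
statistical structure the analysis assumes; nothing downstream depends on
external downloads.

`simulate_methylome` builds one shared array design (default 4 chromosomes
× 2,500 probes, 100-bp spacing, 50-bp probes — tiling density is not a
published quantity and is configurable) and the eight sample groups
{G1R, G2R} × {MGC, sperm} × {oil, treated} with n = 3 replicates and
Gaussian probe noise (sd 0.1 log2 units). Spiked regions (default 20 of 10
probes) are elevated in *all* groups to `methylated_region_log2_mean` and
additionally shifted by `effect_log2_delta` in treated groups selected by
the `persistence` scenario:

| persistence | affected treated groups |
|---|---|
| `none` | G1R MGC (immediate effect only) |
| `g1_only` | G1R MGC + G1R sperm |
| `g1_and_sperm` | + G2R MGC |
| `full_tgi` | all four stages |

The immediate effect in exposed G1R prospermatogonia is always present
when the effect size is non-zero; the scenario states how far it survives
reprogramming.

The default spike height is 0.15 log2 units — deliberately *near* the
95th-percentile positivity threshold of a control sample. This is a
property of the statistic, not a convenience: a region saturated above the
threshold in both groups yields a degenerate (all-positive) contingency
table and the count-based Fisher test has no power there, which is also
why real screens of this design find their hits at regions of low-to-
intermediate methylation. Spiked blocks are separated by at least two
background probes so the single-gap allowance can never merge two truth
regions into one peak. For null-calibration runs (1,000 regions, zero
effect) the spike height is raised to 0.25 so that most regions produce
consensus peaks and are genuinely evaluated rather than vacuously passed.

`simulate_dmr_methylome` lays probes over a named region set and emits an
expected-sign germline methylome (PAT DMRs at +1.0, MAT DMRs at −1.0 log2)
with optional class-specific perturbations, for the imprint screen.

`simulate_allelotypes` draws observed maternal fractions
s·f/(s·f + 1 − f) + N(0, noise) clipped to [0, 1], plus the standard
mixing series {0, 10, 30, 50, 70, 90, 100}% and a heterozygote standard
under the same skew. `simulate_expression` adds a male-up sex effect
(default 2.0 log2 on 500 genes, emulating sex as the dominant axis of
variation in fetal germ cells) and a disjoint treatment-truth subset to a
log2-scale matrix.

What the generators do *not* emulate: probe-sequence/GC effects, dye bias,
spatial artefacts, correlated noise along chromosomes, repeat-masking of
IAP flanks, and reciprocal-cross genome composition. Passing tests
therefore demonstrate correctness of the analysis logic under its own
model assumptions, not robustness to real microarray artefacts.

## Numerical choices

- Percentile: NumPy's default linear interpolation, matching sorted-order
  interpolation; "above" is a strict inequality so constant arrays have no
  positive probes.
- Peak scan: after a failed candidate run the scan resumes just past the
  first gap it consumed, so a later window with a fresh gap budget is
  found; the result equals exhaustive window enumeration with
  leftmost-longest greedy selection (property-tested on random arrays).
- Consensus peaks retaining fewer than four probes after intersection are
  skipped with a logged warning rather than tested.
- Degenerate variance in t-tests: both groups constant and equal → p = 1;
  constant but unequal → p = 0 with a warning.
- Zero-variance transcripts in DE receive p = 1 (no evidence) before FDR.
- Bonferroni thresholds are *compared* at full precision; the 4-decimal
  half-up rounding is for reporting only.
- All genomic coordinates are 0-based half-open (BED convention), on disk
  and in memory; interval overlap requires ≥ 1 shared base, so adjacent
  half-open intervals do not overlap.
- Seeds: every generator takes an explicit seed through
  `numpy.random.default_rng`; identical configurations are byte-identical.

## Design choices where the design was open

- The contingency-table construction for the "Fisher exact" level-1 test
  (positive/non-positive probe counts pooled over replicates) is not a
  published detail; it is isolated in one function
  (`diffmeth_level1._fisher_table`) so alternatives can be swapped.
- Consensus uses interval *intersection* across all replicates — the
  conservative choice for downstream intersection testing.
- The ±5% cutoff is interpreted on the linear fold-change scale
  (|Δlog2| ≥ log2 1.05) for both probe-level and region-level tests.
- Level-1 applies no multiple-testing correction: the screen deliberately
  uses permissive cutoffs so the higher-level intersections operate on a
  larger pool of primary hits, and the final evidence is the intersection,
  not any single test.
- Odds-scale skew correction was chosen over additive corrections because
  it is the only monotone map fixing both endpoints and the standard.
- Baseline classification treats the 80%/20% cutoffs as inclusive.

## Problem sizes

The test suite and acceptance script use a 10,000-probe array for
spike-in recovery (20 regions, Δlog2 = 1.0, noise 0.1) and a 250,000-probe
array for null calibration (1,000 zero-effect regions); the peak-caller
oracle runs 1,000 random arrays of up to 200 probes. These sizes give
stable Monte-Carlo estimates (binomial CIs are quoted in the tests) while
keeping a full run in seconds on one CPU.

## Known limitations

- The Fisher-count statistic is insensitive at saturated regions (see
  above); the level-1 false-negative rate on strongly methylated regions
  is therefore high by construction. Region-average t-tests cover that
  regime.
- `direction_enrichment` computes per-cell Fisher p-values from the 2×2
  cross-table of common hits only; enrichment against a full transcript
  universe would need the universe's membership counts.
- The DE stand-in tests each contrast separately and does not model
  treatment × sex × generation interactions.
- Replicate counts are uniform per group (the real study mixed n = 3 MGC
  with n = 2 sperm arrays); all statistics accept unequal group sizes, but
  the generator emits a single `n_replicates`.
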
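# Methods

## Design and data model

The analysis targets a two-group, two-condition bulk RNA-seq design:
genotypes partitioned into a resistant and a sensitive tolerance group
(default two genotypes each), every genotype profiled under control and
aluminum-stress conditions with replicated libraries (default two
biological replicates per cell; 16 samples in total). The primary input is
a gene × sample matrix of non-negative integer read counts. Fractional
counts (as produced by expectation-based quantifiers) are rounded
half-to-even at ingest with a logged warning, because the exact test
requires integers; the rounding convention is ours and is never silent.
The sample sheet must match the count matrix columns exactly — silent
subsetting hides design errors.

## Filtering and normalization

Genes whose raw CPM stays below 1.5 in all but fewer than `min_samples`
samples are removed. `min_samples` defaults to the replicate-group size
(2), which keeps a gene expressed in only one condition of one genotype —
the most interesting class for a divergence analysis. Library sizes are
deliberately *not* recomputed after filtering: filtering selects genes, it
does not change the sequencing depth, and recomputing totals would
silently rescale CPM.

Between-sample normalization is TMM with the published defaults: the
reference is the sample whose 75th-percentile count fraction is closest to
the mean; per sample, M (log2 ratio) and A (mean log2 abundance)
statistics are computed over genes positive in both sample and reference;
the M values are doubly trimmed (30% on M, 5% on A, rank-based) and
averaged with inverse delta-method binomial variances as weights; factors
are re-centred to geometric mean 1. The test suite pins this
implementation against an independent reference implementation of the same
published algorithm to 1e-6 on seeded data.

## Fold changes and the exact test

Fold change is the ratio of arithmetic-mean stress CPM to arithmetic-mean
control CPM with a pseudocount (default 0.5 CPM) added to both means, so
the ratio is defined when one arm is silent; log2FC is its binary
logarithm. CPM here uses effective (TMM-scaled) library sizes.

Significance uses a conditional NB exact test. Counts are rescaled to the
geometric-mean effective library size; a single common dispersion φ
(variance = μ + φμ²) is estimated across genes by a method-of-moments
ratio estimator, Σ(s² − μ̂)/Σμ̂² over within-arm sample moments, clipped at
zero. Because a sum of n i.i.d. NB(μ, φ) variables is NB with size n/φ,
the stress-arm total conditioned on the gene total follows a beta-binomial
with shapes n_stress/φ and n_control/φ; at φ = 0 it degenerates to a
binomial split proportional to arm sizes. Two-sided p-values double the
smaller tail and cap at 1 — the convention is stated because alternatives
(minimum-likelihood mass summation) give slightly different values. The
doubled-tail convention is mildly conservative away from the tails; on
all-null simulations the rejection rate at α = 0.05 lands near 0.05
(0.049–0.058 across seeds in the suite). No claim of numerical equivalence
with any particular DE package's dispersion machinery is made; ranking
uses ascending p, ties broken by descending |log2FC| then gene id, with BH
FDR appended.

## Consistency and delta-scores

For one gene and one group of n genotypes with per-genotype log2FC values,
the consistency score is

    C = |Σᵢ log2FCᵢ| / (n · maxᵢ |log2FCᵢ|),

taken as 1 when every value is exactly 0 (an unchanging group is perfectly
consistent; divergence is carried by the between-group term). This
algebraic form is a reconstruction: it is the simplest statistic that is
maximal exactly when within-group changes are unidirectional and close in
value, zero when they cancel, and scale-free so that magnitude enters the
ranking only once. Constant rescalings of the denominator cannot change
the induced ranking for fixed group size.

The delta-score multiplies both group consistencies, the larger absolute
group-mean log2FC, and the squared between-group mean difference:

    S_Δ = C_res · C_sens · max(|m_res|, |m_sens|) · (m_res − m_sens)².

The square realises the double weighting of between-group divergence on
the log scale. Useful invariants, all asserted in the suite: S_Δ is
symmetric under swapping the group labels; multiplying every log2FC by
λ > 0 multiplies S_Δ by exactly λ³; permuting genotypes within a group
changes nothing; any within-group sign disagreement with equal magnitudes
zeroes the score. Ties in S_Δ break by descending |m_res − m_sens| then
gene id, making top-k lists deterministic. No significance level is
attached to S_Δ — it is a ranking statistic, not a test.

## GO over-representation

Top lists per direction (up: log2FC > 0, down: < 0) are drawn from genes
significant at α = 0.05 in ranking order at sizes 50/100/300 plus the full
significant set; requested sizes beyond the significant count are capped
with a warning. The universe is the set of genes that survived expression
filtering — testing against all annotated genes would confound expression
with enrichment. Each term with at least 3 annotated universe genes gets
an upper-tail hypergeometric p; BH adjustment is applied within each
(direction, size) stratum. The weighted variant replaces the
hypergeometric with Wallenius' noncentral distribution, odds = mean weight
of annotated vs unannotated universe genes, and reduces exactly to the
central test at equal weights; it accepts any positive per-gene weights
(e.g. transcript-length weights). The annotation map is used as given —
no GO-DAG ancestor propagation — because flat annotation exports are the
expected input.

## qPCR ΔΔCt validation

Technical replicates are averaged per (gene, sample), biological
replicates per condition; ΔCt = mean target Ct − mean reference Ct per
condition; ΔΔCt = ΔCt(stress) − ΔCt(control); −ΔΔCt is the qPCR log2
fold-change estimate under 100% amplification efficiency (an efficiency
correction flag exists but is off by default, matching assays reporting
≥95% efficiency). −ΔΔCt rather than 2^−ΔΔCt is correlated with sequencing
log2FC so both axes share a scale; Spearman ranks are identical either
way. The permutation p-value is exact (full enumeration) for ≤10 pairs and
a normal approximation above.

## Phenotype declines

Per (cultivar, trait), decline % = 100 × stress mean / control mean,
rounded half-up to one decimal — the rule that reproduces the consistent
cells of the field-trial table. Two cells of that table are internally
inconsistent with this rule (one where the printed percentage corresponds
to the inverted ratio, one 0.1 off at the rounding boundary); no special
cases are implemented for them.

## Synthetic data generator

The generator emulates the downstream count matrix only — no reads, no
isoforms, no batch effects. Defaults, chosen once to resemble a modest
plant stress experiment: 5000 genes; log-normal baseline means with
meanlog = log 40, sdlog = 1.5 (median ≈ 20 CPM at the 2-million-read
nominal depth); per-gene NB dispersions gamma-distributed with mean 0.1
and shape 2 (typical biological-replicate overdispersion); library sizes
uniform on 0.8–1.2 × 2×10⁶; 15% of genes planted into response classes
(shared up/down, group-specific up, opposite-between-groups,
inconsistent-within-group) at a default effect of 2 log2 units, optional
genotype-level jitter via `within_group_sd`. Counts are NB draws with mean
baseline × 2^(planted log2FC if stress) × library-size factor. The truth
table records each gene's class, planted per-genotype log2FC, baseline
mean and dispersion, enabling calibration tests of the generator against
its own parameters.

What passing tests on this generator do show: the pipeline's estimators
are unbiased and correctly calibrated under the count model it assumes,
and planted divergence is recovered at high recall. What they do not show:
robustness to batch effects, mapping ambiguity, isoform switching, GC/
length bias (beyond the optional weighted enrichment), or any property of
real flax libraries. At the default dispersion, the sampling sd of a
2-vs-2 genotype-level log2FC is ≈0.4–0.5 for well-expressed genes, so
per-genotype fold changes are noisy estimates by construction; calibration
tests therefore check coverage of the generator's own ±3 sd bands rather
than a fixed absolute error. Raw (non-TMM) CPM fold changes are
composition-biased whenever planted regulation is asymmetric — the reason
TMM-corrected CPM is used throughout the fitted pipeline.

The Ct-table generator inverts the ΔΔCt computation: target base Ct
uniform in [26, 29] cycles, stress Ct shifted by −(planted log2FC),
condition-invariant reference gene, Gaussian cycle noise per technical
replicate, and clamping to the empirical 23–32 cycle assay window (with a
warning; large planted effects near the window edge can clip, which
slightly attenuates recovered effects at high noise).

## Numerical conventions and degenerate inputs

Round-half-even at count ingest, round-half-up for printed percentages;
p-values capped into (0, 1]; TMM returns unit factors when no M-value
exceeds 1e-6 in magnitude or the trim empties the gene set; genes with a
zero count in sample or reference are excluded from M/A; an all-zero arm,
an empty tolerance group, a gene missing a genotype log2FC, a non-positive
enrichment weight, and Ct tables missing the reference gene all raise
validation errors naming the offender. Result tables are TSV with '.'
decimals and positional notation down to 1e-4. The pipeline fans a single
seed out to fixed per-stage offsets so each stage is independently
reproducible; identical config + seed gives byte-identical outputs.

## Problem sizes

The shipped simulations use 200–5000 genes: 200 for normalization oracles,
1000–2000 for calibration and null-rate experiments, 5000 for the
divergence-recall experiment — sizes at which every Monte-Carlo property
in the suite is stable across seeds while the full suite stays fast.

## Known limitations

Common (not tagwise) dispersion; no GLM framework, so no covariates or
batch terms; no coexpression-module analysis; enrichment ignores the GO
DAG; the delta-score has no null distribution (a condition-label
permutation null would be a natural extension and is deliberately not
bundled with the published scoring); qPCR efficiency is assumed equal
across target and reference genes unless the correction flag is used.
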
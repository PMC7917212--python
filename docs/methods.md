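# Methods

This note documents the statistical model behind each component of
`rgstab`, the conventions and defaults chosen where the field leaves
room, and what the synthetic validation does and does not demonstrate.

## Data model and preprocessing

The central object is a genes × samples matrix of qPCR cycle-threshold
values (Crt/Cq), with a boolean detection mask and per-sample metadata
(donor, tissue).  All modelling is additive on the Cq scale, which is a
log₂ expression scale under the default amplification efficiency of 2.0
(one cycle = one doubling).  Efficiency is a single global parameter;
per-assay efficiency calibration from dilution curves is out of scope.

Preprocessing applies, in order:

1. **Detection filter.**  A well is "not present" when Crt exceeds
   `crt_threshold` (default 27 cycles) or its amplification score falls
   below `amp_score_threshold` (default 1.24) — the OpenArray
   manufacturer rules.  The default `filter_logic="either"` masks a well
   failing either rule, the common reading in practice; `"both"`
   requires a joint failure for workflows that treat the two rules as a
   conjunction.  Masking flips the detection flag but keeps the value.
   The spike-in row is exempt.  Genes not detected in every sample are
   excluded from the stability panel rather than imputed; imputed Cq
   values would enter every pairwise statistic below with spurious
   certainty.
2. **Spike-in equalization.**  With an exogenous spike (e.g.
   ath-miR-159a at fixed mass per sample), the per-sample offset is the
   spike Cq minus its mean across samples; subtracting it from every
   gene removes technical recovery/input differences exactly under the
   additive model.  The spike row becomes constant and keeps its mean.
3. **Global-mean centering.**  Each sample is shifted so its mean Cq
   over the usable panel equals the grand mean (post-condition enforced
   to 1e-9 cycles).  This removes residual sample-level effects (e.g.
   donor-level input differences) that the spike does not capture.

Steps 2 and 3 add per-sample constants, so every statistic built from
within-sample differences — geNorm M, comparative ΔCt, NormFinder after
its own per-sample centering, and all ΔΔCt folds — is exactly invariant
to them; only BestKeeper's raw dispersion changes.  Their order is
therefore immaterial, and applying them twice is a no-op.  One
consequence worth knowing: centering a G-gene panel leaves each gene a
shared residual of the panel-mean noise, variance Σ_h σ²_h / G², which
acts as a floor (~0.12 cycles for the default synthetic panel) below
which per-gene noise differences cannot be resolved.

Quantities for geNorm use the geNorm convention q = E^(Cq_min − Cq), so
the most expressed sample of each gene has q = 1.  All SD-based measures
are invariant to this per-gene reference choice.

## Stability algorithms

All four estimators fit on a complete samples × genes Cq matrix; lower
values mean more stable.  Within-algorithm ranks are ascending
competition ranks with ties at full floating precision.

**geNorm.**  V_jk = SD over samples (ddof 1) of log₂(q_j/q_k) and
M_j = mean over partners of V_jk.  The gene with the largest M is
recorded with its current M and removed; iteration stops at two genes,
which share the final pairwise M.  Ties for worst are broken by removing
the lexicographically last gene id, making reruns deterministic.  The
reported per-gene value is M at the gene's exclusion step, which yields
the monotone columns with a tied top pair familiar from published
tables.  The V_n/n+1 pairwise-variation trace of normalization factors
is available behind a flag but no recommendation of RG count is made.

**NormFinder.**  Input is log₂ expression (negated Cq); data are
per-sample gene-mean centered, z_g = y_g − mean over genes.  Centering
mixes the genes, so the naive variance of z_g is biased:
E[s²_g] = σ²_g(1 − 2/G) + T/G², whence the corrected estimator
σ̂²_g = max(0, (s²_g − T/(G(G−1))) · G/(G−2)) with T = Σ_g s²_g.  The
clamp at 0 guards against negative corrected estimates for genes quieter
than the panel average; G ≥ 3 is required (the correction factor
degenerates at G = 2).  Ungrouped stability is σ̂_g.  In grouped mode
the same correction is applied within each group; the intergroup bias
d̂_gi (group mean of z_g minus its overall mean) is shrunk toward zero
by the empirical-Bayes factor γ̂²/(γ̂² + σ̂²_gi/nᵢ) with
γ̂² = max(0, Σ d̂² /((G−1)(m−1)) − mean σ̂²_gi/nᵢ) — the standard moment
estimator for the between-group variance of the d's — and the stability
value is meanᵢ(|d̃_gi| + √(σ̂²_gi/nᵢ)).  The grouped mode is the default
for pooled multi-tissue analyses (`--group-by tissue`); single-condition
analyses use the ungrouped form.  Note a structural property verified in
the test suite: among genes with no true group effect, both grouped
terms shrink as 1/√n, so the grouped ranking does not converge with
sample size at a fixed number of groups — convergence statements about
rankings are made with the ungrouped estimator.

**BestKeeper.**  Per gene, `sd_cp` is the mean absolute deviation of Cq
around its arithmetic mean (the convention of the original spreadsheet
tool; sample SD available via `dispersion="sd"`), `cv_pct` is
100·sd_cp/mean, and `r_index` is the Pearson correlation with the
BestKeeper index, the per-sample geometric mean Cq of the candidates.  A
zero-variance gene gets a missing r, not an error.  Ranking is by
`sd_cp` ascending; the tool's "SD > 1 cycle" exclusion screen is
reported as a flag and never auto-applied.

**Comparative ΔCt.**  For each gene pair the SD over samples of
Cq_g − Cq_h; a gene's value is the mean over its partners.  With
efficiency 2 this is algebraically identical to first-iteration geNorm M
(SD(log₂(q_g/q_h)) = SD(Cq_h − Cq_g)), an identity the suite checks to
1e-12 on random matrices.

## Consensus

Each algorithm's values are converted to ascending competition ranks
("1, 1, 3"): ties share the minimum rank and the next rank skips by the
tie count.  geNorm's final pair enters as a forced rank-1 tie.  The
consensus score is the geometric mean of a gene's ranks across
algorithms, reported to 2 decimals; the final ordering uses the
unrounded score, with exact ties broken lexicographically and flagged.
The minimum-rank tie rule is the one consistent with published geomean
arithmetic — a tied pair at ranks (1, 1) followed by rank 3 reproduces
scores such as (1·1·3·1)^¼ = 1.32, whereas fractional 1.5/1.5 ranks
would not.

## ΔΔCt impact analysis

Folds are computed per donor within the matched design:
ΔCt = Cq_target − Cq_RG inside one sample, ΔΔCt subtracts the same
donor's calibrator-tissue ΔCt, and fold = E^(−ΔΔCt), so calibrator
folds are identically 1 and all sample-level terms cancel.  Donors
missing from either tissue are dropped with a warning; unpaired analysis
is deliberately not offered.  Each target × tissue cell carries the
per-donor folds, mean, sample SD, and a two-sided one-sample Student
t-test against 1 on the raw ratio scale (the convention of mainstream
GraphPad-style workflows; a log₂ option exists since ratio-scale testing
is statistically contestable).  Significance tiers are § p<0.1, *
p<0.05, ** p<0.01, *** p<0.001.  Degenerate sets (zero SD) are flagged
rather than silently propagated.  Grubbs screening is the single-outlier
two-sided test, G = max|x − x̄|/s against the t-quantile critical value
((n−1)/√n)·√(t²_{α/(2n),n−2}/(n−2+t²)), applied at most once per value
set at α = 0.05, and only ever reported, never auto-excluded.  The
per-tissue "mean modulation" summary is the mean ± sample SD of the
targets' mean folds.

## Multivariate views

PCA operates on row-scaled profiles (each feature centered and scaled to
unit variance, ddof 1); components come from the SVD of the scaled
matrix, scores are per sample, and variance explained is proportional to
squared singular values.  Missing cells are filled by iterative low-rank
SVD imputation — rank 2, at most 100 iterations, converged when the
largest fill change drops below 1e-6 — initialized at the row mean; with
no missing data the imputation path is inert and the result equals plain
SVD.  Component signs are fixed so each loading vector's
largest-magnitude entry is positive.  Hierarchical clustering uses
1 − Pearson r between (row-scaled) profiles and unweighted average
linkage (UPGMA), for rows, columns or both; scipy's deterministic
agglomeration keeps tie behavior reproducible.

## Synthetic data generator

One draw produces Cq[g, (t, d)] = baseline_g + tissue_effect_{g,t} +
donor_effect_d + sample_offset_{(t,d)} + ε with ε ~ N(0, noise_sd_g),
one sample per tissue × donor, a spike row carrying only the sample
offsets, and dropout flags for wells above the detection threshold.  A
single seeded generator stream drives everything; identical seeds give
bit-identical matrices.  Since sample-level terms are shared by all
genes, a gene's designed stability is the population variance of its
tissue effects plus its noise variance, and `ground_truth_ranking`
orders genes by that quantity (ties lexicographic).

The default study panel (`default_study_spec`) mirrors a donor-matched
three-tissue design: 3 donors × 3 tissues (CC, BMSC, ASC), 12 candidate
RGs, 4 target genes and one spike.  Baselines are drawn uniformly in
9–23 cycles, the span where abundant EV miRNAs are observed; technical
offsets have SD 0.5 cycles and donor shifts SD 0.2.  The candidate panel
contains one designed-stable gene (no effects, 0.05-cycle noise — an
idealized positive control), a noise ladder from 0.30 to 0.75 cycles for
the remaining neutral candidates, and one designed-unstable gene with
0.50-cycle noise plus a 1-cycle tissue effect of opposite sign in the
two MSC-like tissues.  The ladder's lower end sits deliberately above
the ~0.12-cycle panel-mean floor described earlier, and its range
matches the per-gene dispersions typical of real candidate panels
(roughly 0.3–0.9 cycles); a ladder starting lower would ask the pairwise
algorithms to resolve differences that nine samples cannot resolve.
Targets carry 0.10-cycle noise and no tissue effects, so downstream fold
deviations are attributable to the RG used.  A second scenario
(`rg_impact_spec`) isolates normalization impact: targets with true fold
1 everywhere, an ideal stable RG, and an unstable RG whose 1-cycle
tissue bias rides on ordinary 0.10-cycle noise, so the bias it induces
(a factor ~2 in every target) is never masked by its own noise.

What the generator does *not* emulate: amplification-curve shape and
per-assay efficiency variation, inter-plate batch effects,
non-Gaussian heavy-tailed outliers, and correlated co-regulation between
genes.  Passing the synthetic suites therefore demonstrates correctness
of the algorithms and the recoverability of additive-model structure,
not robustness to those real-data pathologies.

## Validation design and known limits

Every algorithm is checked against an independent oracle: brute-force
enumeration with explicit loops for geNorm, BestKeeper, ΔCt and UPGMA, a
second independent coding of the variance estimators for NormFinder, and
eigendecomposition for the PCA.  Deterministic identities (ΔCt ≡
first-pass geNorm M; preprocessing invariance of pairwise rankings) are
asserted at 1e-12/1e-9 over hundreds of random matrices.  Recovery
properties run as seeded replicate studies at the study's own scale
(12 genes × 9 samples, 200 replicates; 100 replicates for the
normalization-impact and clustering properties), sized to finish in
seconds on one CPU.

One honest limit: at nine samples, single-gene consensus recovery of the
designed-stable gene against a 0.30-cycle nearest competitor succeeds in
about 94–95% of replicates, right at the 95% target the suite asserts —
the pairwise algorithms (geNorm, ΔCt) dominate the failures because
their statistics are partner-noise dominated, so the designed-stable and
a lucky neutral gene are occasionally statistically indistinguishable.
The corresponding acceptance test may therefore fail by a handful of
replicates depending on the seed base; the bottom-three placement of the
designed-unstable gene and all deterministic checks are stable.
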
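# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `hicpop`.

## Phenotype definitions and conventions

**Binning.** Bins are 0-based half-open, bin k = [k·b, (k+1)·b) with
b = 40 kb by default; the last partial bin of a chromosome is kept (the 22
hg19 autosomes then tile into 72,036 bins). Read pairs are assigned by their
1-based 5′ positions.

**HiCNorm-style correction.** A Poisson GLM of upper-triangle counts on
log(effLen_i·effLen_j) and log(GC_i·GC_j) with log(map_i·map_j) as offset,
fit per chromosome (statsmodels). Distance is deliberately not a covariate,
following the original formulation of the cited method. Bins with any zero
covariate are NA throughout. If the GLM fails, the raw matrix is returned
with a `hicnorm_status='failed'` flag rather than silently propagating.

**Quantile normalization.** Reference = mean of per-sample order statistics;
NA entries are excluded from ranking and restored as NA; ties receive the
average of the tied reference values (average ranks interpolated on the
reference grid). When samples differ in their non-NA counts the sorted values
are interpolated onto a common quantile grid. Matrices are normalized on the
upper triangle and re-symmetrized.

**DI.** For a bin's upstream flank sum A and downstream sum B within the
window (2 Mb default, 200 kb for QTL scans), DI = sign(A−B)·(A−B)²/(A+B) —
algebraically equal to the two-term chi-square against equal flanks. Sign
convention: **positive = upstream bias** (some other implementations use the
opposite). A + B = 0 gives NA (the chi-square is undefined). A bin is NA when
more than five window bins are NA; bins whose window runs off the chromosome
count the missing bins as NA, which effectively masks chromosome ends.

**INS.** cross = mean O/E linking the upstream flank U = [i−w, i−1] and
downstream flank D = [i+1, i+w]; within = mean O/E over off-diagonal i<j
pairs inside U and inside D pooled (the diagonal is excluded as
self-contacts). INS = min(cross/within, 1): the clip implements the [0, 1]
range, 0 = absolute insulation. The alternative per-chromosome min–max
rescale is available via `clip=False` plus downstream scaling, but clipping
is the default and the tested path. NA when >50% of the used cells are NA or
a flank is truncated.

**PC1.** O/E columns (NA bins dropped, residual NaNs imputed by column
means) → Pearson correlation matrix → covariance → eigenvectors. The
chromosome is accepted only if eigenvector 1 beats eigenvectors 2 and 3 in
|correlation| with gene density; gene density is used only for this QC and
for orienting the sign (positive = gene-dense A compartment), never inside
the eigen computation.

**FIRE.** Per-bin cis-contact totals at anchor distances in (15 kb, 200 kb]
(at 40-kb bins: offsets 1–5), Poisson-regressed on log effLen and log GC with
log mappability offset per sample, observed/fitted, quantile normalized
across samples, log2(x+1), z-scored per sample. Calls at z > Φ⁻¹(0.95).

**TADs.** A 3-state Gaussian HMM on the **signed square root** of DI. The
raw DI is a signed chi-square statistic with extremely heavy tails; its
signed root is a z-like quantity on which Gaussian emissions are adequate.
Without the transform, EM routinely mislabels moderate-bias bins and boundary
recall collapses on some seeds. States are initialized from tertiles
(self-transition 0.9, symmetric otherwise), EM runs ≤200 iterations at tol
1e−6 with a fixed random state; NA gaps split the sequence into independently
decoded runs. A boundary is the first bin of a downstream-bias run whose most
recent biased state was upstream bias. Degenerate tracks (constant, or
unseparated state means) return no boundaries.

## BNBC

Counts → log2(CPM + 0.5), CPM per chromosome per sample (the total is the
sum over i ≤ j). Per band (fixed anchor distance): quantile normalization
across samples, then a ComBat-family parametric empirical-Bayes location/
scale batch adjustment of the samples × cells matrix. The 8 most distal
bands present are set to 0, as are the diagonal and bands beyond the
requested maximum; the output is on the corrected log-CPM scale.

One deliberate estimator choice: the prior variance τ² of the per-cell batch
means is estimated by moment matching **with the sampling variance
subtracted**, τ̂² = max(var(γ̂) − mean(δ̂²)/n_batch, 0), rather than the raw
var(γ̂) plug-in. With the raw plug-in, a cohort with *no* batch effect still
yields τ̂² ≈ sampling variance, so the shrinkage factor n·τ²/(n·τ² + δ²)
settles near ½ and the adjustment removes about half of each cell's batch-
mean noise — deflating every downstream batch F-statistic. The noise-
subtracted estimator sends τ̂² → 0 under the null (the adjustment reduces to
subtracting the band-wide mean shift, leaving per-cell noise intact and
post-correction batch tests uniform) while a genuine constant shift is still
removed exactly through the prior mean γ̄. Scale parameters keep the
standard inverse-gamma moment priors with the iterative joint solution
(tol 1e−4, ≤100 iterations). A band whose cells have (near-)constant δ̂
shrinks δ* fully to the mean. With a single batch the ComBat step is skipped
entirely (quantile normalization only): the literal standardization
round-trip is not an exact identity (a √((n−1)/n) factor survives the
variance-prior limit), and a no-op is the honest behavior when there is
nothing to correct. Batches with one sample raise by default;
`drop_singleton_batches=True` reproduces the upstream practice of dropping
those samples.

## Variability

**Moderated F.** Per bin, a one-way fixed-effects layout (individual as
factor) gives MS_between and the residual variance s²_g on d_g df. The
hyperparameters (d₀, s₀²) of the scaled-F prior are obtained by closed-form
moment matching on log s²_g (digamma/trigamma inversion, Newton; d₀ clamped
to (0, 1e6]); s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g); F̃ = MS_between/s̃² on
(k−1, d₀+d_g) df. The implementation reproduces R limma's `fitFDist`/
`eBayes` to machine precision on shared fixtures (a cross-check test runs
limma through Rscript). BH at FDR 0.1; adjacent significant bins merge into
maximal regions.

**Testability filters.** FIRE: a FIRE call in any replicate; DI: |DI| >
10.82757 in any replicate; INS: per-replicate z-scored INS < −1 in any
replicate (z computed per sample across bins); PC1: no metric filter. Then:
bins with a zero covariate and bins within 200 kb of them; configured
excluded regions (the MHC by default in genome terms); bins within the
metric-specific flank (FIRE 200 kb, INS 400 kb, DI 2 Mb, PC1 overlap-only)
of structural variants >10 kb.

**Matrix cells.** Cells at anchor distance < 28 Mb get a plain one-way F
test and an IHW-lite q-value: cells are split into ≤10 equal-count distance
strata (≥50 tests each, fewer strata otherwise), each stratum weighted by
its Storey (λ = 0.5) non-null proportion, floored at 0.1 so no stratum
becomes unrejectable, normalized to mean 1, then weighted BH. With one
stratum this is exactly BH. Effect sizes come from the balanced-design
ANOVA method-of-moments decomposition σ²_between = max((MS_b − MS_w)/r, 0),
which coincides with REML for balanced one-way layouts and avoids an
iterative fit per cell.

**Permutation machinery.** Variable regions collapse to the bin with the
strongest mean |external| signal; Spearman correlations across individuals
are computed as Pearson on pre-computed ranks (exact, and fast enough to
permute); the null permutes individual labels of the external track. Both
this test and the nominal-fraction bootstrap use **mid-p tie handling**:
p = (1 + #{perm > obs} + ½·#{perm = obs})/(n_perm + 1). Nominal fractions
are multiples of 1/size and Spearman medians are rank-discrete, so the plain
"≥ observed" rule is systematically conservative under the null (measured
mean p ≈ 0.6); mid-p restores uniformity, which the calibration tests
verify.

## QTL mapping

**Model.** y_ir = μ + β·dosage_i (+ covariates) + b_i + e_ir with
b_i ~ N(0, σ²_b), e_ir ~ N(0, σ²_e), fit by profile REML: for a single
grouping factor, V = σ²_e(I + γZZ′) is block diagonal, so given
γ = σ²_b/σ²_e the GLS solution is closed-form and REML is a 1-D bounded
minimization over log γ (with an explicit γ = 0 boundary check). The fit
agrees with statsmodels MixedLM to ~1e−5 on shared data and costs ~1 ms,
which is what makes 1000-simulation power grids and genome-style scans
tractable. The Wald test on β uses a t reference with df = N_obs −
n_individuals − 1; this single convention is used for bin-level and
cell-level scans alike (the upstream analyses used two different mixed-model
tools; unifying the df is a deliberate simplification, and the measured
type-I error at α = 0.05 stays within [0.03, 0.07] under the study design of
11 subjects × 2 replicates). REML boundary censoring (γ̂ ≥ 0) means the LMM
p can only be ≥ the matched-df OLS p when the true subject variance is zero;
the aggregate median ratio stays within ~10%. Non-convergence falls back to
OLS with a flagged record.

**Selection and calls.** Testable SNPs: biallelic SNVs outside the HindIII
exclusion list, in testable bins, MAF ≥ 0.05 with both alleles in ≥2
discovery individuals; perfect-LD groups (dosage vectors identical up to a
global allele swap, on discovery individuals) collapse to the
smallest-position tag. Calls: BH within phenotype at FDR 0.2 — DI bins first
classified upstream/downstream by the sign of the max-|DI| discovery value
and tested separately — then the smallest-p SNP per bin (ties by position).
C-QTLs: SNPs in either anchor bin of a variable cell, distance-weighted BH,
best SNP per cell with the leftmost of its perfect-LD group (recomputed
across both anchor bins) reported.

**Validation.** Held-out phenotypes are z-scored per bin, dosages oriented
by the discovery effect sign (missing dosages, coded −1, dropped), and
pooled into a single regression; the null draws same-size (bin, SNP) sets
from the testable universe (bins without replacement within a draw, one SNP
per bin), oriented by their own discovery betas.

**Power.** Per simulation: dosage = two Bernoulli(MAF) draws per subject
(monomorphic draws redrawn); response = mean + β·dosage + subject intercept
+ residual, 2 replicates/subject; the same LMM; power = rejection fraction
at α = 0.05 over n_sim = 1000.

## CTCF motifs and loops

Key positions are PWM columns whose maximum base probability strictly
exceeds 0.75 (JASPAR MA0139.1 has exactly 8). A SNP in a motif occurrence
maps to column pos − start on the plus strand and end − pos on the minus
strand; alleles are reverse-complemented on minus-strand motifs before
comparison with the consensus; a call requires a key column and exactly one
consensus-matching allele (that allele is S, reported on the forward
strand). Convergent loops are encoded as plus-strand motif on the left
anchor, minus-strand on the right. Loop strengths (quantile-normalized
contact values at the loop bin pair) are divided by each SNP's heterozygote
class mean — loops without heterozygotes are excluded and counted — and
pooled into a linear regression on S dose. Allelic imbalance keeps
(loop, individual) points with ≥10 phased loop reads and applies a
one-sample one-sided t-test of mean S fraction > 0.5.

## Synthetic cohort generator

The generator emulates a two-replicate LCL-style Hi-C cohort on one
synthetic chromosome. Expected counts multiply, on the log scale: power-law
distance decay (exponent 1.0), compartment coupling exp(0.3·comp_i·comp_j)
with a smooth ±1 block vector (~1-Mb blocks), a 1.6× within-TAD enrichment
(boundaries every ~18 bins with jitter), FIRE boosts (2.0× at 5% of bins),
focal loops (3×), per-dose QTL factors, and per-band additive log batch
shifts (two batches, replicate 1 vs replicate 2). Counts are
Poisson(λ) — matching the Poisson regression framework of the
normalization — with optional gamma overdispersion (default off); matrices
are symmetric; replicates share all genotype-driven terms. Total expected
depth is scaled to 2×10⁶ pairs per replicate on the default 400-bin (16-Mb)
chromosome — deep enough that phenotype-scale planted effects are
measurement-dominated, small enough for dozens of seeds per minute.
All randomness flows from one seed through `SeedSequence.spawn` with a fixed
consumer order (genotypes, truth, matrices, covariates, tracks, reads), so
identical configurations are byte-identical.

Planted QTL effects act on the local windows that define each phenotype:
FIRE effects scale the target bin's contacts at offsets ≤5 bins, INS effects
scale cross-boundary cells within ±5 bins, DI effects scale upstream
contacts only, contact/loop effects scale a single cell. Effect sizes in the
evaluation pipelines are 0.35/−0.4/0.5 natural-log units per dose, which
realize ≈1.5 phenotype standard deviations per allele under the default
depth. Because effects have finite footprints, the evaluation keeps null
SNP bins ≥6 bins (FIRE) or ≥11 bins (INS, whose window adds another ±5)
away from planted targets; closer bins genuinely carry signal and would be
miscounted as false positives.

What the generator does **not** emulate: restriction-fragment structure,
read-level artifacts, trans contacts, translocations/SVs in the matrices
themselves, linkage disequilibrium between SNPs (except planted perfect-LD
duplicates), population structure, or relatedness. Passing tests therefore
demonstrate the statistical machinery's correctness and calibration under a
known generative model, not robustness to every artifact of real Hi-C.

## Evaluation defaults and problem sizes

The recovery benchmarks run 11 individuals × 2 replicates on a 200-bin
(8-Mb) chromosome, 50 seeds per phenotype; type-I calibration uses 1000
simulated tests; BNBC evaluation uses 8 samples × 100 bins × 60 bands with a
planted 1.0 log-unit shift (reported as the median over 3 seeds — a single
KS statistic on ~4000 weakly QN-coupled cell p-values is noisy even when
calibration is correct); permutation calibration uses 60 runs × 300
permutations. These sizes keep the full benchmark under a few minutes on one
CPU while leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- The HiCNorm GLM assumes Poisson counts; strong overdispersion in real data
  would call for a negative-binomial variant.
- IHW-lite is a stratified weighted BH, not the full constrained-optimization
  weighting; it preserves the reduction-to-BH property and monotone gains on
  informative covariates but may be less powerful than the full method.
- The unified Wald-t df convention is mildly anticonservative (measured
  type-I ≈ 0.06 at α = 0.05 under the default design); Satterthwaite df
  would tighten this at the cost of a heavier per-fit computation.
- Matrix-cell effect sizes use the balanced-design moment decomposition;
  severely unbalanced designs (dropped replicates) would need the full REML
  decomposition.
- PC1 sign/QC needs a gene-density track; on chromosomes where compartments
  genuinely do not track gene density the QC will reject.
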
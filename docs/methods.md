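# Methods

## The state score

The central quantity is the first principal component score of a
row-standardized expression matrix, treated as a per-sample measure of
where each transcriptome sits along the dominant covarying program.
The modeling assumption is that one program dominates: thousands of
probes move together (in either direction) as a single latent state
varies across animals, and everything else is approximately
independent noise. Under that assumption the first PC direction is an
aggregate over all informative probes, which is why the score is (a)
nearly invariant to which probes are used, (b) invariant to per-probe
affine rescaling (and hence to the upstream summarization algorithm),
and (c) linearly related to the Euclidean distance between
transcriptomes. The package treats those three properties as testable
diagnostics rather than articles of faith.

Conventions, fixed once:

- **Standardization**: each probe row is z-scored with the sample
  (n−1) standard deviation. Correlations with PCA1 are insensitive to
  the denominator; the z values themselves are not, so the convention
  is stated. Rows with (numerically) zero variance are dropped with a
  warning before z-scoring; a relative tolerance of 1e-10 treats rows
  of identical floats — whose computed SD can be machine-epsilon-sized
  rather than zero — as flat.
- **Observations**: samples are observations, probes variables; the
  score is computed by SVD of the standardized matrix, and the
  variance-explained share of component *i* is λᵢ/Σλ (first four
  components reported by default).
- **Scale**: scores are normalized to unit sample variance. Every
  downstream use is a correlation, which is scale-free; a fixed scale
  makes scores comparable across probe subsets.
- **Sign**: a PC sign is arbitrary, so each score records its
  orientation rule. The reference (all-probe) score is oriented so the
  treated-arm mean exceeds the control-arm mean when treatment labels
  exist, else so the largest-|loading| probe loads positively;
  probe-subset scores are aligned to the reference by sign of their
  correlation with it. An exactly-zero alignment correlation leaves
  the sign unchanged and logs a warning.

## Subsampling protocol

Probes are partitioned into disjoint equal-size groups — ordered
blocks by probe-ID order (the default, group 1 = probes 1..2000, group
2 the next 2000, …) or seeded random blocks — with leftover probes
discarded so all groups are equal-sized. PCA1 is computed per group
(rows re-standardized within the group, a no-op when the input is
already z-scored), each group is sign-aligned to the all-probe
reference, and the full pairwise Pearson matrix with its minimum and
median off-diagonal entries is reported. Alignment guarantees each
group correlates non-negatively with the reference, not that every
off-diagonal pair is non-negative; the report never assumes the
latter. Default group size 2000 and five groups; 500/1000/4000 are
equally supported.

## Connectivity, distance, correlation tables

Two genes are *connected* when the two-sided p-value of their
cross-correlation (Pearson on z-scored profiles by default, Spearman
available) falls below 0.001. All correlation p-values use the exact
t transform `t = r·sqrt((n−2)/(1−r²))` with n−2 degrees of freedom.
Connectivity is connections divided by the number of genes analyzed.
The pairwise matrix is quadratic in gene count, so a seeded uniform
subsample (default 5,000 genes; the pipeline default uses 2,000) is
analyzed unless the full matrix is requested; connectivity is a
per-gene summary and is robust to this subsampling. The
connectivity-vs-state curve bins genes into equal-count quantile bins
(connectivity is heavy-tailed; equal-width bins would be mostly empty)
and reports the gene-level Spearman correlation between connectivity
and |r with PCA1|.

The distance profile takes the sample with minimum PCA1 as reference
(ties broken by lexicographically smallest sample ID, logged),
computes each sample's Euclidean distance over all probes of the
standardized matrix, and reports the Pearson correlation of distance
with PCA1. On exactly rank-1 data this correlation is 1 by
construction; at the generator's default noise it is high but not 1,
and it increases monotonically as noise shrinks (a property test).

Per-probe correlation with PCA1 is tested at α = 0.05, uncorrected.
The uncorrected choice is deliberate: the concordance statistics this
feeds (fractions of probes significant in one or both regions) are
only interpretable as fractions of a liberal per-probe test, and
multiplicity-corrected thresholds would collapse them.

## Fold changes and regional concordance

Log2 fold change is the treated-minus-control difference of group
means on the log2 scale, with a two-sided Welch t-test per probe.
Welch is also the default for behavioral group comparisons (a
pooled-variance Student option exists for literal replication of
classical usage). Identical groups yield p = 1; singleton groups yield
fold changes with p flagged unavailable. Cross-region concordance
reports the Pearson correlation of per-probe fold changes plus four
percentages: significant in ≥1 region, in both, and — among each of
those sets — changing in the same direction in the other region.
Probes with a fold change of exactly zero carry no direction and are
excluded from the direction percentages (count logged).

## Behavior association

Each correlation between a score vector and a behavioral measure runs
a Shapiro–Wilk test (α = 0.05) on both variables and uses Pearson only
when both pass, Spearman (average ranks for ties) otherwise. The
normality gate and its α are recorded in each result. NSF latencies
sit at a 480 s ceiling when censored; they are kept as-is — the rank
branch absorbs the ties — and the count at ceiling is logged. The
ambiguous-responder rule flags a treated animal as responding on a
test when its value is *below the control-arm median* for that test
(lower immobility / shorter latency = response) and as ambiguous when
it responds on exactly one of the two tests; thresholds are returned
for audit and are configurable, since "appeared to respond" admits no
unique operationalization. Exclusion is applied before correlating,
and changes nothing upstream of the behavior tables.

## The synthetic generator

The generator emulates the covariance structure the analysis targets,
not array physics. One scalar latent state per animal
(`s_a ~ N(δ·treated, σ_s²)`, δ = 1.2, σ_s = 1), perturbed per region
(σ_r = 0.25), is read out by probes through loadings that are zero
with probability 0.35 and otherwise signed lognormal
(`|β| ~ LogNormal(log 0.48, 0.4)`), on top of probe baselines
`μ_g ~ N(7, 1.5²)` log2 units and iid noise (σ_ε = 1). Present calls
are Bernoulli with probability `logistic(μ_g − 5)`; 15% of genes emit
two probe sets sharing the gene's loading; behaviors couple to the
*animal*-level state (FST = 150 − 22·s_a + N(0, 20²) clipped at 0;
NSF = 300 − 45·s_a + N(0, 42²) clipped to [0, 480] s). Cohort: 11
treated and 8 control animals, 45,000 probes, both regions — the
dimensions of the motivating study design.

The load-bearing parameters were calibrated once, jointly, against
the aggregate statistics the analysis is designed around — a first
component carrying ≈20% of variance, cross-region score correlation
≥ 0.9, behavior–state Spearman magnitudes in 0.5–0.9, five-group
minimum concordance ≥ 0.97, and roughly half to three-fifths of
present probes significantly PCA1-correlated in at least one region —
and then frozen. At the frozen defaults the measured values are: mean
PC1 share 21.7% over 25 seeds, cross-region |r| ≈ 0.96, behavior
Spearman ≈ −0.66/−0.72, five-group minimum r ≈ 0.995, present-probe
significant-in-≥1-region ≈ 55%.

What the generator does *not* emulate: batch and hybridization
effects, correlated noise beyond the single factor, multi-factor
latent structure, probe-sequence effects, or realistic per-gene
distributions. Passing tests on synthetic data therefore demonstrate
that the estimators recover what the single-factor model puts in, and
that the diagnostics behave as designed — not that real tissue data
contain a single dominant program. Its cross-region fold-change
concordance (r ≈ 0.6, ≈30%/≈6% significant in one/both regions,
≈88%/≈99% direction agreement at default settings) is qualitatively,
not numerically, matched to real-study behavior: a single-factor model
with iid noise cannot simultaneously pin the variance share and the
per-probe significance rates, and the variance share was given
priority.

## Problem sizes and determinism

Study-level checks run at the full default size (45,000 probes × 19
samples per region); sweeps use reduced probe counts (300–2,000)
because the checked properties — null uniformity of association
p-values, monotone trends in noise or linkage fraction — do not depend
on probe count. All randomness flows from explicit integer seeds;
pipeline runs expand a single root seed into named per-stage seeds
(generator, partition, connectivity) recorded in the report, so any
stage can be replayed.

## Known limitations

- The state model is intrinsically single-factor; data with two or
  more comparable programs will fold them into one score, and the
  subsampling concordance will degrade rather than fail cleanly.
- Connectivity p-values assume approximately normal profiles; the
  Spearman option relaxes this but the t-transform p-value is then an
  approximation.
- The GEO series-matrix reader parses the expression block only;
  sample metadata in such files is free-form and must be supplied
  separately in the documented TSV dialect.
- NSF censoring is handled by ranks, not by a survival model; heavy
  censoring would bias any correlation-based association.
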
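# Methods

This note documents the models, parameter choices and numerical conventions
behind `progmark`, and what the synthetic-data experiments do and do not
establish.

## The synthetic cohort model

`progmark.synthetic.simulate_cohort` draws the log2 expression of gene *g* in
sample *i* as

    x_gi = mu_g + beta_g * 1[rapid_i] + gamma_{g, batch(i)}
           + a_g * (age_i - mean age) + s_g * 1[male_i] + eps_gi

with `eps ~ N(0, noise_sd^2)` independent per gene and sample. Noise is
Gaussian on the log2 scale, the standard working assumption for normalized
log-intensity microarray data. All sampling consumes a single
`numpy.random.Generator` seeded once per run, in a fixed order (gene
baselines, effect assignment, covariate coefficients, sample covariates,
batch shifts, noise, outlier/low-RIN designation, RIN values), so equal
configs give bit-identical cohorts.

Defaults mirror the cohort design the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_slow`, `n_rapid` | 33, 34 | arrays entering expression analysis |
| `n_genes` | 20,014 | gene-level features on the array |
| `frac_de` | 200/20,014 | true-effect genes (the order of the ~220-gene permutation signature) |
| `effect_size` | 1.0 log2 | group shift on affected genes, ± with equal probability |
| `noise_sd` | 0.5 log2 | within-group SD, a moderate blood-array scale |
| `n_batches`, `batch_shift_sd` | 3, 0.3 | per-gene, per-batch additive shifts |
| `age_mean`, `age_sd` | 68, 8.5 yr | truncated to [40, 90]; elderly PD cohort |
| `age_effect_sd` | 0.005 /yr | per-gene linear age coefficients |
| `gender_effect_sd` | 0.1 | per-gene additive male-vs-female shifts |
| `n_low_rin` | 3 | degraded samples, RIN drawn in [4, 5.9) |
| `n_outliers`, `outlier_shift` | 2, 6.0 | failed-array samples, +6 log2 on 30% of genes |

No public effect-size or variance scales exist for the motivating cohort, so
`effect_size` and `noise_sd` are chosen for testability (effects at 2× the
noise SD are comfortably detectable at n = 33/34); conclusions from the tests
are about the *procedures*, not about expected power on real blood data.
`frac_de * n_genes` must be integral (it is the planted-truth count); the
validator accepts values within 1e-6 of an integer because exact decimal
fractions of 20,014 do not exist.

The outlier magnitude deserves a note: outliers are additive shifts on 30% of
genes, emulating a grossly failed hybridization. With 20,014 iid-noise genes
and 67 samples, the leading PCA axes are dominated by the noise bulk, and a
shift must be ~6 log2 units before the planted samples reliably own the top
components; smaller shifts model subtler artifacts but are not PCA-visible at
this shape, so 6.0 is the default. Real array noise is correlated across
probes, which makes real outliers visible at smaller magnitudes — another
respect in which passing synthetic tests understate real-data behaviour.

What the generator does **not** emulate: probe-level structure and
summarization artifacts, correlated noise across genes (co-expression),
heavy-tailed and gene-specific variances, RIN-correlated degradation
gradients, or missing values. Calibration and recovery results on these
cohorts therefore demonstrate correctness of the statistics under their
nominal assumptions, not robustness to the full messiness of blood arrays.

The qPCR generator (`simulate_ct_table`) draws a per-gene baseline Ct, a
per-sample loading offset (SD 0.5 cycles, which must cancel in ΔCt), shifts
target Ct by `-log2(fold)` in the rapid group, and adds `ct_sd` replicate
noise; at `ct_sd = 0` the ΔΔCt pipeline returns the injected folds exactly,
which is the round-trip identity the tests exploit.

## Preprocessing

**RIN filter.** Strict inequality: a sample at exactly the threshold (default
6.0) is retained. Missing RIN is an error naming the sample, not a silent drop.

**Variance pre-filter.** "Non-variant" is interpreted as lowest sample
variance (ddof = 1); the removal count is `k = ceil(fraction * n_genes)` —
the only rounding consistent with 20,014 → 17,011 at 15%. Ties break by gene
id so the removed set is deterministic. Low mean intensity or low IQR are
defensible alternative readings; variance is the common default and is fixed
here.

**PCA outliers.** Gene-centered data, sample scores on the first two
components (full SVD, deterministic); a sample is flagged when any retained
score is more than 3 robust SDs (1.4826 × MAD) from the component median.
The rule assumes unimodal score distributions: when a component instead
separates hybridization batches, the MAD understates the spread and extra
samples can be flagged. This is accepted behaviour of the simple rule;
adjust batches first, or raise `k_sd`, if it bites.

**Empirical-Bayes batch adjustment.** The parametric ComBat scheme: least-
squares fit of batch indicators plus fixed covariates (age numeric, gender
dummy-coded), gene-wise standardization by the pooled residual SD, per-batch
location/scale estimates shrunk toward a Normal prior (method-of-moments
mean/variance across genes) and an Inverse-Gamma prior (method-of-moments
shape/scale), iterated conditional posterior modes to 1e-4 relative
convergence (capped at 500 iterations), then back-transformation with the
covariate estimates restored. Group is deliberately not in the design;
with groups roughly balanced across batches this preserves the group contrast
(the tests require the injected effect back within 10%). Degenerate inputs:
zero pooled variance is clipped to 1e-12; a singleton batch is an error
advising a merge; a batch containing only one biological group triggers a
confounding warning but proceeds. The implementation agrees with
Bioconductor `sva::ComBat` (parametric priors, same design) to < 1e-6, which
is the independent oracle in the test suite.

One consequence worth stating: ComBat removes the *observed* (shrunken)
per-batch means, which include the batch-level noise component, so the
post-adjustment between-batch F statistic falls below the null median
(typically ≪ 1), not to ~1. The acceptance check asserts the collapse from
≫ 1 to ≤ ~1 accordingly.

## Differential expression

The base statistic is the Welch unequal-variance t (with Welch–Satterthwaite
df); the pooled-variance form appears implicitly in the ANOVA F, which for two
groups equals the squared pooled t. Degenerate rows follow fixed conventions:
both groups constant with equal means → p = 1; constant with unequal means →
p = 0 (logged); constant rows in ANOVA → p = 1.

**Bootstrap test.** "Cross-validation by bootstrapping" is formalized as the
bootstrap achieved-significance level: each group is centered to the grand
mean (null enforcement), B stratified with-replacement resamples are drawn
within groups, and the +1-smoothed exceedance proportion of |t*| over
|t_obs| is the p-value. The smoothing guarantees p ≥ 1/(B+1) and correct
type-I control. B defaults to 1000.

**Permutation test.** Group labels are reassigned; with
C(n, n_A) ≤ 20,000 all assignments are enumerated and the p-value is the
exact proportion (the identity assignment makes it ≥ 1/C); otherwise B
Monte-Carlo relabellings with +1 smoothing. Exhaustive mode is verified
against brute-force enumeration; Monte-Carlo converges to it (|Δ| < 0.01 at
B = 1e5 on a fixed small dataset).

**Thresholds.** Defaults 0.05 / 0.005 / 0.05 for ANOVA / bootstrap /
permutation. The bootstrap threshold is config-exposed because both 0.001
and 0.005 appear in the motivating analysis; 0.005 — the value attached to
its reported gene count — is the default. No multiple-testing correction is
applied by default (raw-p thresholds define the consensus); the per-test
flags make a Benjamini–Hochberg pass trivial to add downstream.

All resampling is vectorized across genes in chunks of 256 iterations
(memory ~tens of MB at 2,000 genes × 67 samples); a 2,000-gene cohort runs
the full three-test table in a few seconds on one CPU. The test suite and
acceptance script use 2,000-gene cohorts and B = 1000 for both resampling
tests; these sizes give binomial-CI-resolvable calibration estimates while
keeping a full run to minutes.

## Classification

Signature rows are z-scored with the sample-SD (n−1) convention — fixed for
determinism; (1,2,3) maps to (−1,0,1). UPGMA is implemented directly
(O(n³) scan with the Lance–Williams average update) with a documented
tie-break: equal merge heights resolve toward the lexicographically smallest
node pair. Cohorts are tens of samples, so the naive algorithm is instant
and its merge history fully reproducible; `scipy.cluster.hierarchy` is the
independent oracle in tests, never the implementation. The tree is cut into
k = 2 clusters and clusters map to labels by majority vote (ties: the more
frequent label overall, then lexicographic) — the operational reading of
"clustering-based classification" on a two-group heatmap. Chance behaviour
of this adaptive mapping is above 50%: with two size-c clusters the expected
null accuracy is E[max(X, c−X)]/c under a hypergeometric draw (~0.59 at
c = 8), approaching the majority frequency only for large cohorts; the tests
assert against the exact expectation.

## qPCR

ΔΔCt is computed from group means of ΔCt (unpaired groups), fold = 2^(−ΔΔCt),
fold > 1 ⇔ up-regulated in the rapid group. Amplification efficiency is
assumed exactly 2 (validated assays; no efficiency correction). Replicate
SD > 0.5 cycles is flagged (a common lab gate; the flag does not drop data).
Group t-tests are computed at the patient level after collapsing replicates —
testing triplicate wells as units would overstate n.

## Over-representation

Fisher p is the exact upper hypergeometric tail P(X ≥ k) via
`scipy.stats.hypergeom.sf`; EASE is the same tail with the overlap reduced by
one (k ≤ 1 → 1.0), hence always ≥ Fisher. Discrete tails are super-uniform
under the null — conservative, never anti-conservative; the tests verify
uniformity on the randomized-p transform. Kappa is Cohen's agreement between
binary membership vectors over an explicit universe, with κ ≡ 1 when chance
agreement is 1 (both terms = universe). Term grouping is greedy single-link
above κ = 0.4 (the conventional functional-grouping default), seeded in
ascending EASE order with lexicographic ties, producing a deterministic
partition. The background defaults to the filtered-matrix gene set and is
overridable; annotation comes from user-supplied GMT files only — no term
databases are bundled or downloaded.

## Cohort statistics

Summary-statistic t-tests (Welch default, pooled available) reproduce any
raw-data test with matching moments. The 2×2 chi-square applies Yates
continuity correction by default: the published gender comparison
(16/35 vs 18/35 males → p = 0.811) is reproduced only with the correction
(0.632 without), which pins the default. A known discrepancy is documented
rather than resolved: the motivating cohort table prints p = 0.8024 for age
at examination, but its own summaries (70.0 ± 8.4 vs 66.3 ± 8.7, n = 35/35)
give Welch p ≈ 0.075 — likely a typographical issue in the source table; no
test asserts that value.

## Pipeline and I/O

Stages run in the order QC → gene filter → EB adjustment → three-test DE →
consensus → signature clustering → (optional) enrichment. Every output
carries the config hash (over analysis parameters, excluding the output
directory) and the seed; logs omit timestamps so a rerun of an identical
config is bit-identical. All formats are plain text (expression TSV,
sample-sheet CSV, long Ct CSV, GMT); a minimal GEO series-matrix text reader
is provided for convenience and carries no test dependencies. Unknown config
keys are errors, not silent ignores.

## Known limitations

- Calibration/recovery evidence comes from iid-Gaussian synthetic cohorts
  (see above); the published per-dataset gene counts (1,251 ANOVA / 1,080
  bootstrap / 221 permutation) are data-dependent and can only be checked
  against the deposited accession, which this desk-scale package does not
  fetch.
- The bootstrap test's formalization is one defensible reading of an
  underspecified procedure; alternatives (e.g. out-of-bag cross-validation
  schemes) would differ.
- The PCA outlier rule is intentionally simple and can over-flag under strong
  multimodal batch structure.
- Moderated/shrinkage t statistics, non-parametric ComBat priors, and GO DAG
  propagation are out of scope.
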
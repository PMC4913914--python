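# progmark

Blood gene-expression analysis of Parkinson's disease (PD) progression, as a
tested, reusable pipeline. The scientific question it addresses: can whole-blood
transcriptional profiles separate PD patients who reach the postural-instability
milestone within ten years of motor onset ("rapid" progressors) from those who
do not ("slow" progressors)? The package implements the full analytical chain
for a two-group blood microarray cohort — sample and gene quality control,
empirical-Bayes batch/covariate adjustment, a three-test consensus
differential-expression procedure, clustering-based patient classification,
ΔΔCt qPCR validation statistics, and gene-set over-representation — together
with a synthetic-cohort generator that carries ground truth for every stage, so
the whole pipeline can be exercised and scored end to end without patient data.

## The statistical core

Given a log2 expression matrix $X \in \mathbb{R}^{p \times n}$ (genes ×
samples) and per-sample metadata (group, age, gender, hybridization batch, RIN):

1. **QC.** Samples with RNA Integrity Number < 6 are removed; samples whose
   score on either of the first two principal components deviates from the
   component median by more than $3 \times 1.4826 \cdot \mathrm{MAD}$ are
   flagged as outliers. The 15% of genes with the lowest sample variance are
   dropped (20,014 genes → 17,011 at the default fraction).
2. **Batch adjustment.** A parametric empirical-Bayes (ComBat-type) model:
   gene-wise standardization after fitting batch indicators plus fixed age and
   gender terms, shrinkage of per-batch location/scale parameters toward
   Normal / Inverse-Gamma priors estimated across genes, then back-
   transformation. The biological group label is excluded from the design, so
   the slow-vs-rapid signal passes through. (Verified against Bioconductor's
   `sva::ComBat` to < 1e-6.)
3. **Differential expression, three ways, per gene:**
   - one-way ANOVA F-test (equivalent to the squared pooled t for two groups);
   - a bootstrap achieved-significance-level t-test: both groups centered to
     the grand mean to enforce the null, B = 1000 stratified resamples, Welch
     t recomputed on each, $p = (1 + \#\{|t^*| \ge |t_{obs}|\})/(B+1)$;
   - a permutation t-test on relabelled samples, enumerated exhaustively when
     $\binom{n}{n_A} \le 20{,}000$ and Monte-Carlo otherwise.
   Genes significant under all three (defaults $p_{ANOVA} \le 0.05$,
   $p_{boot} \le 0.005$, $p_{perm} \le 0.05$) form the consensus signature.
4. **Classification.** Samples are clustered on the z-scored signature rows
   (Euclidean distance, average linkage / UPGMA), the tree is cut into two
   clusters, clusters are mapped to clinical labels by majority vote, and
   per-group correct counts are reported.
5. **qPCR validation.** Replicate Ct values are collapsed,
   $\Delta Ct = Ct_{target} - Ct_{RPLP0}$,
   $\Delta\Delta Ct = \overline{\Delta Ct}_{rapid} - \overline{\Delta Ct}_{slow}$,
   fold change $= 2^{-\Delta\Delta Ct}$, with Welch t-tests on ΔCt.
6. **Over-representation.** Fisher exact (upper hypergeometric tail) and the
   conservative EASE variant (one overlap gene removed) against user-supplied
   GMT gene sets; enriched terms grouped by Cohen's kappa (single linkage at
   κ ≥ 0.4).

## Worked example

Simulate a study-shaped cohort (67 samples, here 2,000 genes of which 100
carry a true group effect of 1 log2 unit ≈ 2× the within-group noise SD), run
QC + adjustment, then the three-test consensus:

```sh
$ progmark simulate --n-genes 2000 --frac-de 0.05 --n-slow 33 --n-rapid 34 \
    --seed 7 --out-dir sim
wrote 2000 genes x 67 samples to sim

$ progmark preprocess --matrix sim/matrix.tsv --sheet sim/samples.csv \
    --out adjusted.tsv --out-sheet samples_qc.csv
removed 3 low-RIN and 2 outlier samples, 300 low-variance genes; wrote adjusted.tsv

$ progmark de --matrix adjusted.tsv --sheet samples_qc.csv \
    --b-boot 1000 --b-perm 1000 --seed 7 --out de.tsv
106 consensus genes; wrote de.tsv
```

The 3 low-RIN and 2 outlier samples are exactly the planted ones
(`sim/truth.tsv` lists them), and the 106 consensus genes contain all 100
planted effects; the head of `de.tsv` for consensus genes:

```
gene_id mean_slow mean_rapid log2_fc  t_stat   p_anova p_boot p_perm consensus
G0007   4.0134    5.0438     1.0304   -10.2426 0.0     0.001  0.001  True
G0028   11.1309   10.2143    -0.9165  6.9736   0.0     0.001  0.001  True
G0055   6.2929    5.2344     -1.0586  9.5222   0.0     0.001  0.001  True
```

`p_boot = p_perm = 0.001` is the resolution floor $1/(B+1)$ at B = 1000.
Clustering the remaining 62 samples on the bootstrap-significant genes
classifies every sample correctly here (`slow 31/31, rapid 31/31`). A qPCR
table simulated with true fold changes {RAD18: 2.19, ABCA1: 3.09, FOXP1: 0.35}
and 0.15-cycle replicate noise returns:

```
gene_id      ddct      fold          t             p
ABCA1   -1.766115  3.401368  38.367762  3.280463e-15
FOXP1    1.490724  0.355834 -23.387125  2.270561e-10
RAD18   -1.278907  2.426550  22.145200  4.618564e-11
```

(fold > 1 means up-regulated in the rapid group; estimates scatter around the
injected truth at this noise level and recover it exactly at zero noise).

The same stages are available as library functions (`progmark.preprocess`,
`progmark.diffexpr`, `progmark.classify`, `progmark.qpcr`, `progmark.enrich`,
`progmark.cohort_stats`) and as a single YAML-configured run
(`progmark run --config pipeline.yaml`).

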
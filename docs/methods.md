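# Methods

`statinsig` implements a cross-ancestry pharmacotranscriptomic signature
analysis for statin LDL-cholesterol (LDLC) response, together with a
synthetic-data generator that reproduces the statistical structure the
analysis assumes. This note documents the models, the defaults and why
they were chosen, the numerical conventions, and what the bundled
simulations can and cannot show about real data.

## The analysis

### Input and preprocessing

The pipeline starts from two variance-stabilized expression matrices
(genes × samples) for the same cell lines incubated with statin and with
control buffer, plus a phenotype table (ancestry, responder class, LDLC
percent change, age, sex, smoking, batch). Delta expression is the
statin-minus-control difference per gene and sample. Processing order:

1. delta computation;
2. across-sample quantile normalization (columns mapped to the mean order
   distribution; ties receive the mean of the reference values they span);
3. per-gene least-squares regression on the experiment-batch factor;
4. PCA of the between-sample covariance of the gene-centered delta matrix
   (via SVD; `variance_explained_k = eigenvalue_k / trace`);
5. progressive removal of leading PCs: for each k = 1..k_max, every gene
   is residualized on score columns 1..k (joint regression with
   intercept — equivalent to sequential removal because score columns are
   orthogonal), and the residuals are quantile normalized again.

Leading PCs act as proxies for unmeasured technical confounders. The
number of PCs worth removing is bounded by a selection rule — up to 25
PCs, stopping before the first component explaining less than 0.5% of
the variance — and refined by the classification sweep below. PCA is
computed once on the uncorrected (normalized, batch-adjusted) matrix and
reused for every k; a `recompute_pca_per_k` switch enables sequential
re-estimation instead (default off, for determinism and speed).

A PC–covariate diagnostic table (Spearman for numeric covariates,
Kruskal–Wallis for categorical ones, per leading PC) shows confounder
structure fading as k grows. One caveat discovered during development:
quantile normalization is nonlinear, so when confounders are strong the
initially-normalized matrix retains a small component of
covariate-associated structure that linear PC removal cannot reach.
Associations fade markedly with correction but need not vanish exactly.

### Signature statistic

For gene *i* with high- and low-responder deltas, the moderated relative
difference is

    d(i) = (x̄_H(i) − x̄_L(i)) / (s(i) + s0)

with `s(i) = sqrt((1/n_H + 1/n_L) (SS_H + SS_L) / (n_H + n_L − 2))`, the
pooled two-sample standard error. With `s0 = 0`, `d` is exactly the
pooled two-sample t statistic (asserted against an independent oracle in
the tests). The fudge factor `s0` is a single table-level constant that
stabilizes the variance of `d` across the range of `s`, preventing
low-variance genes from dominating the ranking. Default selection
(`cv_min`): candidates are the 0th, 5th, …, 100th percentiles of
`{s(i)}`; genes are binned into ~100 equal-count windows by `s(i)`; the
candidate minimizing the coefficient of variation of the per-window
median absolute deviation of `d` wins, ties going to the smallest
candidate. `percentile:q` and `fixed:v` are explicit overrides.

Significance is assessed by permuting high/low labels uniformly over the
labeled samples (never the unlabeled background), recomputing `d` with
`s0` held at its observed-data value so the statistic's scale is
comparable across permutations. The empirical p-value is the fraction of
B permutations whose |d| reaches the observed |d|, two-sided via the
absolute value; zero exceedances are reported as p < 1/B with a floor
flag (at the default B = 5000 the floor is 0.0002). Genes are ranked by
|d| descending, ties broken by gene id.

### Cross-ancestry classification

Signature genes discovered in the European-ancestry (EA) tails are
evaluated as classifier features in the African-ancestry (AA) tails.
The classifier is a radial-basis-kernel SVM (cost C = 1; kernel width
from the median heuristic, `gamma = 1 / median(squared pairwise training
distances)`), with decision scores oriented so higher means more
"high-responder". Evaluation repeats a class-stratified random 90/10
split: one fold of ten is held out, the rest train, and the held-out
decision scores are pooled over repeats (default 5000). The pooled
scores give one ROC curve and its AUC, computed as the tie-corrected
rank statistic (equal to the trapezoidal ROC area). Training and
testing are both within the validation cohort by default; a
`train_on_discovery` switch instead trains on the EA tails and scores
every AA sample once.

Two refinement sweeps mirror the study design: the 25 progressively
corrected datasets are each evaluated with the top-100 panel to choose
the number of PCs, and panel sizes 70–90 (step 1) are evaluated at the
chosen correction to choose the panel, ties to the smallest panel.

A known property of pooled repeated-split scores at this sample size
(26 validation samples): the pooled AUC conditions on the particular
cohort draw. Under a zero-signal simulation it is unbiased (mean ≈ 0.49
across replicate studies) but has a conditional standard deviation of
roughly 0.15, so single-study null AUCs outside [0.35, 0.65] occur by
chance; calibration claims in the tests therefore use the median across
replicate studies.

### Phenotype association

Clinical phenotype changes are delta-log measures, `ln(mean
on-treatment) − ln(mean pre-treatment)` (natural log; every downstream
use is rank-based, so the base is inert). Each panel gene's corrected
delta is associated with the cellular cholesterol-ester (CE) change by
Spearman rank correlation (average ranks; two-sided p from the
t-approximation `t = rho·sqrt((n−2)/(1−rho²))`), Bonferroni-adjusted
over the panel size. Group comparisons of high vs low responders use
the two-sided pooled-variance two-sample t-test. A least-squares
residualization helper supports covariate adjustment of phenotypes
before correlation.

## The synthetic-data generator

The generator emulates a two-ancestry in-vitro statin study: EA cohort
of 104 lines (25 high + 25 low responders at the tails of the LDLC
percent-change distribution plus 54 background lines), AA cohort of 26
(12 high + 14 low). Responder-class LDLC changes are drawn from normals
calibrated to the emulated study's clinical table (EA high −59.1 ± 3.9%,
EA low −22.2 ± 8.0%, AA high −57.5 ± 3.2%, AA low −21.5 ± 6.5%);
background lines are uniform between the tails (−47 to −33%). Classes
are then assigned by tail selection on the drawn values, so tail
membership holds by construction. Covariates (age, sex, smoking, batch)
are linked to the latent confounders below with correlation 0.5, so the
PC–covariate diagnostics have structure to find.

Delta expression follows a linear latent-factor model on a
variance-stabilized-like (log2-ish Gaussian) scale:

    delta[g, i] = mu_g + beta_g z_i + sum_k lambda_gk f_ki
                  + b_batch(i),g + eps_gi

with `z` = +1/−1/0 for high/low/unlabeled, `beta_g = ±effect_size/2`
for the 80 planted signature genes (signs fixed per gene, shared across
ancestries — required for cross-ancestry replication to be achievable),
`f` standard-normal latent confounders with loadings
`lambda ~ N(0, 4²)`, a per-batch gene offset (sd 0.5) and unit Gaussian
noise. Defaults: 2000 genes, 80 planted, effect 1.5 (in noise-sd
units), 3 confounders. The effect size gives per-gene pooled-t signal
≈ 5 after correction (strong but not trivial at n = 25 + 25), while the
confounder loadings are strong enough that the uncorrected data bury
the signal — discovery and cross-ancestry prediction succeed only after
PC removal, which is the behavior the pipeline exists to exploit. The
within-class variance of expression changes is a free parameter of the
generator, not an estimate from data.

One designated planted gene (fixed positive class sign; effect scaled
1.25×, making it reliably one of the most differential panel members,
like its real-data analog) is coupled to the cellular CE change:

    ce_delta = ce_coupling · standardize(x) + class offset + noise

where `x` is the gene's *within-class* biological delta (class shift
and technical terms removed). Coupling to the within-class variation
keeps the other 81 panel genes' correlations with CE at the null level;
coupling to the full delta would correlate every class-differential
panel gene with CE through the shared class indicator and make the
designated gene's primacy unattainable at the calibrated effect. Any
class-level CE difference is expressed separately through
`ce_class_offset` (default 0). The default coupling −0.52 with unit CE
noise calibrates the observed Spearman correlation between the
PC-corrected gene delta and CE to ≈ −0.35 at n = 103 (one EA line is
left unmeasured, matching the emulated assay's coverage). Free
cholesterol is pure noise. The AA cohort has no lipid assay.

Every operation is a pure function of its inputs and the config seed
(per-operation seed streams), so a fixed config reproduces the study —
and the whole pipeline output bundle — byte for byte.

### What the simulations do not show

The generator is Gaussian and linear: no count noise, no
mean–variance relationship beyond what quantile normalization imposes,
no linkage structure among genes beyond the shared factors, no
population stratification within ancestry, and identical effect sizes
for all planted genes. Passing tests demonstrate that the pipeline
recovers the structure it assumes, at the stated sample sizes — not
that real statin-response signatures have this structure, nor that the
emulated study's specific gene panel would replicate.

## Numerical conventions and edge cases

- Quantile-normalization ties take the mean of the spanned reference
  values; the operation is idempotent and column-exchangeable.
- PCA components carry a deterministic sign (largest-magnitude loading
  positive). PC-removal residuals exclude the intercept, so corrected
  matrices are gene-centered before re-normalization.
- Batch levels need at least 2 samples; single-level batches are a
  no-op.
- `s + s0 = 0` genes are rejected; all-zero pooled sds abort s0
  estimation.
- Permutation p-values lie on the grid {0, 1/B, …, 1}; a warning is
  raised when fewer than B distinct label assignments exist.
- ROC points advance jointly on tied scores; AUC counts tied
  positive–negative pairs as 1/2.
- Ranking and panel ties resolve by gene id; sweep AUC ties resolve to
  the smaller configuration.
- Constant inputs to Spearman yield flagged NaN results rather than a
  value.

## Problem sizes used by the checks

The bundled acceptance script and tests run the full-scale generator
(2000 genes × 130 samples) but reduce Monte-Carlo depth where the
quantity converges quickly: repeated-split evaluations use 300–2000
repeats instead of 5000, and replication counts are 5 seeds for
parameter recovery and 50 for the association scan. Permutation
p-values use the full B = 5000 where the reporting floor itself is the
quantity of interest.
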
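# Methods

This note documents the models, statistical conventions, and design
choices behind `vascage`, in the order a dataset flows through the
package.

## Aging screen

### Model

For each gene g in tissue t, expression y (TPM) is related to donor age
x by the Pearson correlation R and the OLS slope b of y on x. The
two-sided p-value uses the exact transform t = R·√((n−2)/(1−R²))
against Student's t with n−2 degrees of freedom. Q-values are
Benjamini–Hochberg step-up, computed **within tissue** — never pooled
across tissues — because each artery is an independent screen with its
own sample size and power.

Genes with zero variance (notably silent genes, which dominate
annotation-wide matrices) carry a `degenerate` flag and are excluded
from the BH denominator m; a configuration switch could include them
as p = 1, but shrinking m is the default because a silent gene is not
a tested hypothesis. P-values are floored at the smallest positive
normal double and never reported as 0.

### Concordance sets

*Pan-arterial*: q < α (default 0.05) in all three tissues and an
identical sign of R throughout. *Extended*: q < α in both primary
(well-powered) tissues with agreeing signs, |R₁+R₂+R₃| > 0.5 with the
sum's sign matching the primary signs, and the secondary tissue's R
directionally consistent with |R| > 0.1. The sum cutoff is applied to
the absolute value with a sign-consistency requirement so that
decreasing and increasing genes are treated symmetrically.

The effect-size proxy is mean TPM × slope (TPM/year): a rank statistic
favouring abundant genes with large absolute yearly change, which is
what matters for tissue-level protein economy. Ties break
lexicographically on gene id so ranked lists are deterministic.

Age-bin summaries floor ages to integers and assign them to the closed
decade-pair bins [20, 39], [40, 59], [60, 79]; public cohort ages are
integer years or decade brackets, so 39.9 belongs to the first bin and
40.0 to the second. Differences across bins use Kruskal–Wallis with
tie correction.

### Regulon attrition

The panel deviation statistic takes a gene panel's R-values in one
tissue and tests them against μ₀ = median R over all non-degenerate
genes of that tissue (close to 0 in a null screen) with a one-sample
Wilcoxon signed-rank test. Values equal to μ₀ are dropped (classic
convention rather than Pratt's; configurable in principle but the
difference is immaterial for continuous R). The exact null
distribution is computed by convolution over doubled midranks — exact
even under ties — for effective n ≤ 25; beyond that a tie-corrected
normal approximation is used. Panel symbols map case-insensitively;
members absent from the tissue's table are excluded and logged, and a
panel mapping below 50% aborts the run with the unmapped list.

The confounder model is plain OLS of target TPM on age, sex (coded
1/2, deliberately not recentred, so coefficients stay comparable
across runs), and covariate gene TPMs, with rank-deficiency reported
as a named error listing the collinear columns.

### qPCR quantification

2^−ΔΔCt with a reference gene: ΔCt = Ct_gene − Ct_ref per sample,
ΔΔCt subtracts the control-group mean ΔCt, fold = 2^−ΔΔCt. The
control group's geometric-mean fold is exactly 1 by construction, and
the output is invariant to adding a constant to all Ct values of a
sample (input-amount normalization). Downstream statistics should use
the emitted `log2_fold`, not the fold itself.

## Proteomics differential expression

### Permutation FDR

After log2 transform and filtering to ≥ 3 valid values in every group,
each protein gets d = (mean₁ − mean₂)/(pooled SE + s₀). The default
s₀ = 0 makes d the plain two-sample Student t, matching a "two-sided
Student's t test" reading; s₀ is exposed because the Perseus lineage
of this workflow supports variance moderation.

Group labels are permuted by balanced reassignment: all C(n, n₁)
distinct assignments form the pool, the identity is excluded, and
n_perm = 250 are sampled without replacement (for 6 vs 6 there are 924
distinct assignments, so 250 is a proper subsample; designs with fewer
distinct assignments fall back to full enumeration, which also makes
the result seed-invariant). For a symmetric threshold c on |d|,

    FDR(c) = mean over permutations of #{|d*| ≥ c} / #{|d| ≥ c},

and a protein with |d| = v receives q(v) = min over c ≤ v of FDR(c),
which is non-increasing in v; the significant set {q ≤ target} is
therefore the largest threshold set whose estimated FDR meets the
target, with ties at the boundary included. No π₀ correction is
applied — the plain ratio is the simplest defensible estimator and is
conservative (it assumes all hypotheses null), which the calibration
tests confirm. Numerical identity with any particular GUI
implementation of this workflow is not claimed.

Proteins with fewer than two valid values in a group are reported
untested. The reported per-protein p always comes from the plain
Student t reference; significance, however, is defined solely by the
permutation FDR flag, and downstream overlap analytics consume only
that flag.

### Imputation, z-score, clustering, PCA

Missing values are imputed only for PCA, per sample column: draws from
Normal(μ − 1.8σ, (0.4σ)²) where μ, σ are the column's observed mean
and sample SD — the standard downshifted-Gaussian model of
intensity-dependent (MNAR) missingness. Observed cells are never
altered (bitwise). Defaults width = 0.4, downshift = 1.8.

Sample SD (n−1 denominator) is used everywhere, including row
z-scoring, so a row (1, 2, 3) maps to (−1, 0, 1). Constant rows are an
error rather than silently producing NaN. Clustering is average
linkage on Euclidean distances, rows and columns separately, with an
optional seeded k-means preprocessing step that clusters centroids and
attaches members (off by default; the matrices here are small).
Dendrograms serialize to Newick. PCA is an SVD of the protein-centred
matrix with a fixed sign convention (the largest-magnitude loading per
component is positive), making scores deterministic.

## Synthetic data

### Expression cohorts

Ages are uniform over [20, 79] (optionally decade-bracket midpoints,
mimicking public metadata). Baseline TPM per gene is log-normal
(median 20, log-SD 1.5 — a heavy-tailed abundance distribution
spanning ~4 orders of magnitude). A fraction (default 10%) of genes
carries a **linear trend on the TPM scale**, matching the screen's
assumption of TPM-vs-age linearity: expected TPM =
baseline·(1 + s·(age − 49.5)/29.5), with the signed relative slope
|s| ~ Uniform(0.1, 0.5). Designated panels receive coordinated
negative s. Multiplicative log-normal noise with CV 0.5 approximates
between-donor biological plus technical variability; no claim is made
that these moments match any real cohort — real tissue data have
correlated genes, batch structure, and ancestry effects that the
simulator deliberately omits, so passing recovery tests demonstrates
correctness of the *procedure*, not field performance. Negative
expected values are truncated at zero, with a validation error if
truncation would touch more than 1% of cells (the advice being a
smaller slope scale). Default cohort sizes are 300/200/120 donors for
the three tissues — the same 2.5 : 1.7 : 1 power ordering as the
motivating public arterial cohorts at roughly half scale, keeping the
20-seed experiments fast.

One global seed expands into per-stream child seeds (structure,
baselines, slopes, per-tissue ages/sex/noise) via seed-sequence
spawning, so adding a stream never perturbs the others and identical
spec + seed is byte-reproducible.

### Proteomes

Per-protein baselines are Normal(25, 2) on the log2 scale (the
`base_spread` of 2 gives the MNAR mechanism an intensity range to act
on); within-group noise is Normal(0, 0.3). A fraction (default 10%)
of proteins receives a ±2 log2 fold-change in the second group —
deliberately strong effects, as expected for direct targets of a
knocked-out transcription factor. Each cell goes missing independently
with probability sigmoid((20 − intensity)·1.0), i.e. ~50% dropout at
intensity 20 falling below 1% at 25, yielding ~3% overall missingness
concentrated in low-abundance proteins. Parameters producing > 90%
missingness are rejected. Note the steepness-0 limit is a flat 50%
coin, not "no dropout"; the no-dropout limit is a steep sigmoid
centred far below the intensity range.

## Validation experiments (`vascage.evaluation`)

* **Screen recovery** (20 seeds): sensitivity of both concordance sets
  for *strong* trends, defined as |s| ≥ 0.3 (at CV 0.5 and n ≥ 120
  this corresponds to population R ≈ 0.33, comfortably detectable);
  measured ≈ 0.94 (pan) and ≈ 0.99 (extended) with a median of 0
  false positives.
* **Null screens** (20 seeds): the triple q < 0.05 overlap is so
  conservative that the pan-arterial set is empty in ≥ 19/20 runs.
* **Panel calibration**: 1,000 uniform random panels on a null cohort
  reject at ≤ α + 2·MC error; the injected negative panel is detected
  (p < 0.05, negative direction) in ≥ 95% of seeds.
* **Permutation-FDR calibration**: pure-null proteomes give a median
  significant-set size of 0; mixed proteomes give realized FDR ≈ 0.05
  (target ≤ 0.10) and sensitivity ≈ 1.0.
* **Imputation moments**: 10,000 imputed cells in a μ = 20, σ = 1
  column have mean 18.2 ± 0.02 and SD 0.4 ± 0.02.

## Known limitations

* The screen assumes linear TPM–age trends; saturating or threshold
  trajectories lose power by design.
* Panel deviation treats panel genes' R-values as exchangeable draws;
  co-expressed panels violate independence, which real-data users
  should remember when reading very small p-values.
* The permutation FDR needs balanced or near-balanced designs; with
  very small groups the distinct-assignment pool limits resolution
  (all assignments are then enumerated and the limitation is logged).
* Identifier matching is exact case-insensitive symbol equality; no
  alias or ortholog resolution is attempted.
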
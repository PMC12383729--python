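# Methods

This note documents the models implemented in `silentdropout`, the defaults
of the synthetic generator, and the numerical choices made where the
procedure left room for interpretation.

## The detection problem

Acellular ("ghost") capillaries are an early, pre-symptomatic lesion of
diabetic retinopathy. Their density (counts/mm²) can only be measured
destructively (trypsin digest), so the practical question is whether
non-destructive evidence — an image classifier's probability and a cheap
clinical covariate, diabetes duration — can stand in for it. The package
implements that chain: define the dropout state from density, model the
duration prior, fuse it with classifier evidence, and quantify the gain.

## Dropout cutoff

Densities in [10, 16] counts/mm² are treated as normal and [20, 22] as
clearly affected; the dropout cutoff is the midpoint of the gap,
(16 + 20)/2 = 18 counts/mm², and a density **≥ 18** (ties positive) defines
the dropout class. `derive_cutoff` also reports Wilcoxon rank-sum
comparisons of blood glucose and diabetes duration between band members, the
evidence that risk shifts sharply across the gap. Tests are two-sided by
default (sidedness is a caller choice; nothing in the procedure forces one
direction).

**Rank-sum numerics.** The statistic is the mid-rank sum of the first
sample. For pooled size ≤ 20 with no ties the p-value is exact by
enumerating all C(n+m, n) rank assignments; the two-sided exact p is
P(|W − E W| ≥ |w − E W|), which for the symmetric tie-free null equals the
doubled one-sided tail. Otherwise a normal approximation with tie-corrected
variance and a 0.5 continuity correction is used; in the tie-free case the
tail is additionally sharpened with an Edgeworth term using the closed-form
excess kurtosis −(6/5)(n² + m² + nm + n + m)/(nm(N+1)), which brings the
worst-case disagreement with enumeration at 8+8 from ≈0.011 to <0.001.

## Duration prior

P(CD|D) = σ(β₀ + β₁D), D in weeks throughout. The Bernoulli likelihood is
maximised by Newton–Raphson starting at (logit of the label mean, 0) with
step-halving (a step is halved until it does not decrease the
log-likelihood), gradient tolerance 1e-10, at most 100 iterations. Standard
errors are the square roots of the diagonal of the inverse observed
information at the optimum. The reported log-likelihood uses the natural
log, so it is always ≤ 0 and invariant comparisons (nesting against the
intercept-only model) hold. Complete separation is detected when a
coefficient passes 30 on the log-odds scale — probabilities are numerically
saturated beyond that — and raised as an error naming the divergence
direction rather than returned as a huge pseudo-estimate.

The prior is fit in-sample on the same animals later evaluated, matching the
simplest protocol; callers who want a held-out prior can fit on any subset
and fuse on another, since fitting and fusion are separate calls.

## Bayesian fusion

The posterior combines two probability estimates of the same binary event
under conditional independence:

P(CD|AI,D) = p·q / (p·q + (1−p)(1−q)),  p = P(CD|AI), q = P(CD|D),

equivalently logit(posterior) = logit(p) + logit(q). The independence
assumption is inherited from the product form and documented, not corrected.
Inputs are clamped to [1e-12, 1−1e-12] because the expression is 0/0 at the
conflicting corners (0,1) and (1,0); evaluation is on the log-odds scale so
no intermediate overflows. Useful consequences, all tested: fuse(0.5, ·) is
the identity, fuse is symmetric and strictly increasing in each argument,
and fusing a stratum with a common prior never reorders its scores. The
posterior surface defaults to a classifier axis 0–1 in steps of 0.01 and a
duration axis 0–60 weeks in steps of 1.

## Evaluation

AUC follows the Mann–Whitney convention (ties count ½), computed via
mid-ranks; the ROC step curve groups tied scores so its trapezoidal area
equals the pairwise statistic exactly. The paired DeLong test computes
per-positive and per-negative placement values for both score vectors, their
2×2 empirical covariances, the variance of the AUC difference
(S₁₀ terms)/m + (S₀₁ terms)/n, and a two-sided normal p. Identical vectors
give Δ = 0 with p = 1 by convention; zero variance with nonzero Δ is an
error, not a p-value. Stratified k-fold assignment shuffles each class
independently (seeded) and deals round-robin, so per-fold class counts are
within one of perfect stratification; splitting by animal rather than image
is recommended when animals contribute multiple images (pass animal-level
labels), since image-level splits leak within-animal correlation.

Percentages are rounded half-up to 2 decimals, matching how printed
percentages are conventionally reported.

## Permutation importance

The regression forest is implemented directly (trees as flat arrays,
exhaustive variance-reduction split search over `mtry` sampled features)
because the importance definition needs per-tree bootstrap/OOB bookkeeping
and one fresh permutation per (tree, feature) pair. "Accuracy" for a
regression tree is not standard; it is defined here as **negative OOB mean
squared error**, so MDA = mean over trees of (baseline − permuted accuracy)
is positive for informative features. The raw MDA scale is therefore in
squared target units; only the ranking is comparable across datasets.
Defaults follow regression-forest convention: 500 trees, mtry = ⌈p/3⌉,
min_leaf = 5. Constant features get MDA exactly 0 (their permutation is a
no-op on a tree that cannot split on them). Trees with an empty OOB set are
excluded from averages with a warning. Categorical covariates (sex, diet)
enter as indicator columns.

## Synthetic generator

The generator defines the study conditions for every simulation-based test;
it is deterministic given (config, seed) with a single seeded RNG threaded
through all stages.

**Cohort** (default n = 124 animals): diet is high-fiber or high-caloric
(50/50); the probability of being diabetic is 0.75 on the high-caloric diet
and 0.20 on high-fiber; diabetic animals have duration ~ U(2, 52) weeks,
non-diabetic exactly 0. Random blood glucose is N(120, 12) mg/dL for
non-diabetic animals and 150 + 2.2·duration + N(0, 25) for diabetic ones,
so ~28 weeks of diabetes sits near 210 mg/dL. Density is a truncated linear
Gaussian model:

density = 6.5 + 0.28·duration + 0.03·(RBG − 120) + 2.0·[high-caloric]
          + 0.04·age + 0·[male] + N(0, 2.5), clipped at 0.

These coefficients put non-diabetic animals around 10–14 counts/mm² and
long-duration animals in the 20+ band, and order the planted effect sizes
duration > glucose > diet > age ≫ sex (sex is pure noise by default; an
optional interaction lets males diverge beyond 20 weeks). Enrollment age is
drawn independently of duration (a cross-sectional simplification: the
generator does not enforce age > onset age + duration). What the generator
does **not** emulate: measurement error in the digest counts, litter/batch
structure, censoring by euthanasia at extreme glucose, or any nonlinearity
in the duration–density relationship — passing tests show the chain recovers
structure it planted, not that real cohorts are this clean.

**Classifier scores**: negatives ~ Beta(c, ck), positives ~ Beta(ck, c)
with c = 2 and k solved numerically (Gauss–Legendre quadrature + Brent root
find) so P(score⁺ > score⁻) equals the target AUC, default 0.86. Beta laws
are used because scores are bounded probabilities; a target of exactly 1
switches to disjoint uniform supports. Two images per animal by default
(≈ the 94-images-from-51-animals ratio); both images share the animal's
label, and scores are drawn independently given the label — real per-animal
image correlation is not modelled.

**Expression**: per-gene baseline means are log-normal
(log₂ mean 6, SD 1.5); planted genes are multiplied by the fold change in
pre-dropout samples only (up-regulation only, matching the screen's
directional use case). Both matrices share the mean structure and gene
lengths (U{500..5000} bp) and differ only in NB overdispersion α
(variance = μ + αμ²): default α = 0.5 for the noisy "cross-species
imputation"-like method and α = 0.05 for the "direct genome mapping"-like
method. The default design is 24 normal vs 4 pre-dropout samples; the
marker-screen power analyses use 12 vs 4.

## Expression computations

TPM divides counts by gene length and scales each sample to 1e6 (columns of
all-zero samples are returned as zeros with a warning). Median-of-ratios
size factors use the per-gene geometric mean over samples as reference,
restricted to genes with all-positive counts, and take the per-sample
median of count/reference on the ratio scale. The overdispersion ratio is
variance/mean (ddof = 1) of size-factor-normalised counts per gene, with
zero-mean genes flagged undefined; the two-method comparison is a paired
per-gene one-sided Wilcoxon signed-rank (mid-ranks, tie-corrected normal
approximation, continuity correction), testing whether method A's ratios
exceed method B's. A distribution-level alternative is a one-line rank-sum
call on the two ratio vectors if pairing is not wanted.

The quantile SD profile resolves the "group genes by quantile" idea as: for
each level q ∈ {25%, 30%, …, 75%}, take the q-quantile of expression within
each sample (type-7 linear interpolation, numpy's default) and report the SD
of those per-sample values across samples. This is the reading under which
genes are ranked solely by expression level and between-sample variation at
a fixed rank is technical; the alternative reading (pool all genes whose
within-sample rank falls into a 5% bin, SD over the pooled values) mixes
between-gene biological spread into the estimate and was not adopted.

**Marker screen.** The screen is a transparent NB Wald test rather than an
empirical-Bayes engine: counts are size-factor normalised; per gene, a
shared method-of-moments dispersion α̂ = pooled (s² − m)/m² (floored at 0)
feeds a delta-method variance of the log group mean, (1/m + α̂)/n; the Wald
statistic compares log means between groups, two-sided normal p-values get
Benjamini–Hochberg adjustment. A gene is a marker iff fold-change of group
**medians** of normalised counts (pre-dropout / normal) exceeds 2 **and**
FDR < 0.05 — the gates are conjunctive, so a significant 1.5-fold gene is
never flagged. Medians (not means) keep the fold-change robust at n = 4.
Genes with a zero mean in either group are untestable (p = NaN, never
flagged via FDR); a zero normal-group median with a positive pre-dropout
median yields fold-change ∞, which still requires the FDR gate.

## Problem sizes used in the checks

The simulation-based checks run at: 100 replicates of 500-image cohorts for
the fusion/DeLong properties; 200 replicates at n = 500 for logistic
recovery; 50 replicates of the 124-animal cohort at 500 trees for the MDA
ranking; 400 genes × 500 samples for the overdispersion moment checks; and
20 seeds of 2,000 genes (12 vs 4 samples) for the marker screen. These sizes
give Monte-Carlo error comfortably inside each asserted band while keeping
the default test run fast.

## Known limitations

- The fusion posterior assumes the classifier score and duration are
  conditionally independent given the dropout state; correlated evidence
  would make the posterior overconfident.
- The prior is typically fit on the same animals it is evaluated with
  (in-sample optimism); the package supports but does not default to a
  held-out split.
- The NB Wald screen with method-of-moments dispersion is anti-conservative
  for very small groups in principle; the conjunctive fold-change gate
  absorbs most of that in practice (verified only under the generator's
  conditions).
- MDA values are in squared target units and depend on feature correlation;
  correlated predictors (e.g. glucose and duration) share credit.
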
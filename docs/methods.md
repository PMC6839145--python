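# Methods

## Study design and model

The package analyses a three-arm monozygotic-twin cohort: *discordant*
pairs (exactly one affected co-twin), *concordant-affected* pairs, and
unaffected *control* pairs. Because co-twins are genetically identical and
share age, sex and early environment, the within-pair contrast in the
discordant arm isolates non-shared environmental and stochastic
contributions; the case-control analysis over all pairs captures effects of
any origin.

Gene counts are modelled per gene `g` and sample `s` as negative binomial,

    y_gs ~ NB(mu_gs, phi_g),       Var(y) = mu + phi * mu^2
    ln mu_gs = beta_0g + pair_{p(s),g} + case_s * beta_g + ln(L_s * f_s)

with pair membership as a fixed blocking factor, a binary case indicator,
and TMM-scaled effective library sizes `L_s * f_s` as offsets. The case
coefficient is tested per gene by a likelihood-ratio test against
chi-square(1); multiplicity is controlled by Benjamini–Hochberg, with FDR
10% as the default reporting threshold (a discovery-oriented choice).
Reported logFC is the natural-log case coefficient divided by ln 2.

In the case-control model, pairs in which both members share the same case
status can make the case column collinear with pair blocks when no
discordant pairs are present; the design builder resolves aliasing by a
greedy rank-preference rule that drops aliased *pair* columns (warning
emitted) and never the case column, and rejects designs where case itself
is unestimable.

## Normalisation

TMM factors follow the canonical recipe: per sample vs a reference (the
sample whose 75th CPM percentile is closest to the mean of those
percentiles), genes expressed in both are summarised by
`M = log2((y_s/L_s)/(y_r/L_r))` and `A = ½ log2((y_s/L_s)(y_r/L_r))`,
doubly trimmed (30% of the M tails, 5% of the A tails), and combined as a
precision-weighted mean of M with delta-method weights
`w = (1/y_s − 1/L_s + 1/y_r − 1/L_r)^{-1}`; factors are rescaled to
geometric mean exactly 1. Trim fractions are the standard defaults; the
analysis convention only names the method.

## GLM fitting and dispersion estimation

Coefficients are fitted by iteratively reweighted least squares with step
halving, vectorised across genes (batched normal equations, a 1e-10 ridge
for numerical safety, linear predictor clipped to ±30). Convergence is
|Δloglik| < 1e-8 or 100 iterations; non-converged genes are flagged, never
dropped.

Dispersions are estimated on a log2-spaced grid (2^-20 … 2^5, 41 points) by
the Cox–Reid adjusted profile likelihood
`APL_g(phi) = loglik(beta_hat(phi); phi) − ½ ln det(X'WX)`, with quadratic
interpolation of the grid maximum. The fitted coefficients warm-start each
successive grid point. The trend is the maximiser of the bin-averaged APL
within 20 equal-count bins of average logCPM; tagwise estimates maximise
`APL_g + prior_df · (bin-average APL)` with `prior_df = 10` by default, so
`prior_df` counts equivalent prior genes: 0 gives the raw per-gene MLE,
infinity the trend, and estimates are clipped into the MLE–trend interval.
This is a deliberately specifiable simplification of the reference
empirical-Bayes machinery (which uses a locfit trend and adaptive prior
df); it is validated by parameter recovery, not numeric identity with any
package. On data simulated with constant phi = 0.2 the common-dispersion
estimate is accurate to three decimals.

Known limitation: with 5 discordant pairs the residual df is 4, and *any*
shrinkage estimator leaves mild mid-range miscalibration of null LRT
p-values under heterogeneous true dispersions (tail behaviour at p < 0.05
stays nominal). The realised false-discovery proportion at BH 10% therefore
runs a few points above nominal in the simulation conditions; the same
behaviour is observed with the reference implementation on identical data.
Users should read the FDR column as approximate at this sample size.

## Within-pair comparisons

Per-pair log2 fold changes use a 0.5 prior count on TMM-effective library
sizes, case vs co-twin in discordant pairs and twin-2 vs twin-1 (sheet
order) otherwise. |logFC| values pooled over genes and pairs per group are
compared by Welch t (unequal variances — the safer default where only "t
test" is conventional) and two-sample KS with the asymptotic Kolmogorov
p-value at effective n = n_a n_b/(n_a+n_b). Pooled values are strongly
dependent across genes; no dependence correction exists in the standard
workflow and none is applied — every report carries this caveat in its
header.

## Gene-set enrichment

A competitive mean-rank test: genes are ranked by DE p-value (1 = most
significant), a set's statistic is the mean rank of its in-universe
members, and the null is the mean rank of `n_perm` uniformly drawn
same-size subsets of the post-filter universe (conditioning on the tested
universe, as competitive tests must). `p = (1 + #{T* ≤ T})/(n_perm + 1)`,
one-sided toward low mean rank by default, two-sided optional. Rotation
(ROMER-style) testing is deliberately not implemented; pathway collections
are screened with the same permutation machinery and the output carries a
`method` column so results cannot be misread as rotation tests. Per-set
generators are seeded from the master seed plus a content hash, so a set's
p-value does not depend on its position in the file.

## Methylation integration

Beta values are clamped on load to [1e-6, 1−1e-6] (boundary Betas are
routine array artefacts) and transformed to `M = log2(Beta/(1−Beta))`,
whose distribution suits linear modelling. Per probe, ordinary least
squares of M on the same paired design gives the case effect and a
two-sided t p-value; no variance moderation is applied (the workflow being
mirrored describes a plain linear model). Probes with zero residual
variance get p = 1 and a flag.

Spatial adjustment follows the Stouffer–Liptak–Kechris scheme: probe
p-values become `z = Phi^{-1}(1−p)`; the autocorrelation of z between
same-chromosome probe pairs is estimated in 500-bp distance bins up to
2000 bp (bins under 10 pairs inherit the nearest populated bin, negative
estimates floor at 0); each probe's z is combined with its neighbours
within ±2000 bp as `z_comb = Σz_j / sqrt(Σ_jk σ_jk)` with `σ_jk` the binned
correlation off the diagonal and 1 on it. An isolated probe keeps its raw
p exactly. Two-sided input p-values are used as-is in the one-sided z
transform — an ambiguity inherited from the workflow being mirrored, and
stated here rather than resolved silently. Gene-level methylation evidence
is the minimum adjusted p over the gene's probes (an evidence summary, not
a multiplicity-adjusted quantity). Region calling (seed threshold / merge)
is not on the main path because the gene summary uses per-probe values.

Expression and methylation p-values are combined per gene by empirical
Brown's method: the per-gene data vectors (CPM across shared samples;
median Beta across the gene's probes) are reduced to evidence scores
`w_s = −2 ln(rank(v_s)/n)` (max-rank ECDF, so the sample maximum maps to 0
— the published convention; off-by-one ECDF choices change the covariance),
`c = cov(w_x, w_y)` sets the scaled-chi-square null `f = 32/(8+2c)`,
`gamma = (8+2c)/8`, and the Fisher statistic
`X = −2(ln p_expr + ln p_meth)` is referred to `gamma * chi2_f`. `c = 0`
recovers Fisher exactly; positive dependence inflates `gamma` and makes the
combination appropriately less extreme. Per-gene covariance is the default;
a single assay-wide covariance is a plausible alternative reading and is
not the default. Genes measured in both assays are ranked by combined p
(ties by gene id) and the top 20 reported. Spearman correlation between
CPM and median Beta accompanies each record. No causal ordering between
methylation, expression and trait is inferred.

## Surrogate variables

A two-step estimator: residualise logCPM on the design, SVD the residual
matrix, and retain leading right singular vectors whose variance fractions
exceed the (1−alpha) quantile of the same fraction under row-wise
permutations of the residuals. Permuted matrices are re-residualised so
both spectra live in the same rank-reduced sample space — without this the
observed top fraction always wins and the rule is anti-conservative.
Retention stops at the first failing component and is capped below the
residual df. SVs are orthonormal and orthogonal to the design span by
construction; they (or user-supplied covariates such as inferred
cell-composition scores) are appended to the design for sensitivity reruns.
This replaces the full iteratively-reweighted estimator because the
sensitivity analysis only needs a specifiable, testable variant.

## Synthetic cohort generator

Defaults emulate the target study structure at desk scale: 5 discordant +
4 concordant-affected + 8 control complete pairs (34 samples; optional
singletons excluded from paired analyses), 2000 genes with baseline logCPM
uniform on (0, 8), per-gene NB dispersions from Gamma(shape 2, rate 10)
(mean phi 0.2, typical for blood RNA-seq), per-pair per-gene effects with
sd 0.5 log2 units shared by co-twins (this produces the within-pair >
unrelated correlation ordering), target library sizes 1–5M, 50 DE genes at
|log2FC| = 2 with random signs applied to affected individuals.
Methylation: probes per gene ~ Poisson(1.5) at 500-bp spacing, M-value
noise AR(1) along position with rho = 0.6 and unit marginal sd, baseline
probe M ~ N(0, 1.5), a +2 M-unit case shift for differentially methylated
genes, Beta = 2^M/(2^M+1). Ten of the DE genes are "linked" (effects in
both assays) and an equal number of non-DE genes receive methylation-only
effects so integration has true negatives to rank against.

The generator is deterministic given its seed (bit-identical outputs). It
does **not** emulate: cell-composition mixtures, batch structure (unless
planted explicitly), gene–gene co-expression beyond shared pair effects,
annotation structure, or realistic 27K probe placement. Passing tests
therefore demonstrate statistical correctness of the machinery under the
stated generative model, not robustness to every artefact of real blood
RNA-seq/array data. Problem sizes in tests and the acceptance script
(2000 genes, 5–17 pairs, 5–20 replicates) are desk-scale choices that keep
full runs in minutes while leaving the statistical checks well-powered.

## Numerical conventions

- logCPM prior count 0.5, with 2×prior added to the library size.
- Probe positions 1-based; all distances are |pos_i − pos_j| bp.
- p-values floored at 1e-15 (integration) / 1e-300 (LRT) before logs.
- Sorting ties broken by gene id everywhere, for deterministic output.
- Every stochastic stage derives its own generator from the master seed
  and the stage name, so toggling one stage never shifts another's stream.
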
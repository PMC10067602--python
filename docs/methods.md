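# Methods

## The gene-pair order statistic

All downstream modelling rests on a single binary feature. For an ordered
gene pair (A, B) and a sample *s* with expression x:

    I(A|B, s) = 1  if x(A, s) > x(B, s)
                0  otherwise  (ties fall in the 0 branch)

Because the indicator depends only on the ordering of two measurements taken
*within the same sample*, it is invariant to any strictly increasing
per-sample transform of the expression vector — log transforms, quantile
shifts, scanner gain, library-size scaling. That is the point: a signature
built on these indicators ports across platforms and batches with no
normalization step, at the cost of discarding magnitude information. Ties
map to 0 by the definition above; with continuous expression they have
measure zero, but the worked micro-fixture includes one deliberately so the
branch is pinned by a test.

Pairs are enumerated once per signature (n genes give n(n−1)/2 pairs; 66
give 2,145) with a fixed lexicographic orientation. Orientation carries no
information — flipping a tie-free pair complements the indicator — and the
Cox coefficient sign absorbs direction.

Pairs whose indicator is nearly constant across the training cohort cannot
discriminate anything, so pairs with a frequency of 1s outside [0.2, 0.8]
are removed. The bounds are inclusive (the deletion rule is "< 0.2 or
> 0.8"). Frequencies are computed on the training cohort only; test cohorts
are encoded with the training pair list, so no test information leaks into
feature selection.

## Risk-model assembly

The funnel reduces the informative pairs to a small multivariate model:

1. **Univariate screen.** One proportional-hazards fit per pair (Breslow tie
   handling throughout; partial-likelihood maximization via `statsmodels`
   PHReg), Wald test, pass at p < 0.05. The pair-level alpha of 0.05
   mirrors the gene-level screen convention.
2. **L1-penalized Cox.** Coordinate-descent elastic net with pure L1 penalty
   (`scikit-survival` Coxnet) over the passing pairs. The penalty is chosen
   by K-fold (default 10) cross-validation: for each fold and each penalty
   on the full-data path, the held-out Breslow partial log-likelihood is
   evaluated at the training-fold coefficients, and the penalty maximizing
   the summed held-out likelihood wins (the `lambda.min` convention, which
   matches the aggressive reductions this style of funnel reports). Folds
   are re-drawn (at most 5 times) if any fold lacks an event.
3. **Multivariate refit with one backward step.** A joint Cox fit over the
   selected pairs; pairs with multivariate Wald p ≥ 0.05 are dropped and the
   model refit once. A single step is the minimal reading of "pairs
   associated with survival in the joint model"; the step can be disabled.

The per-sample risk score is `exp(Σ coef·indicator)`. The high/low cutoff
is the **median score of the training cohort**, frozen into the model and
applied unchanged to every test cohort. Because the score is an exponential
the cutoff is necessarily positive, and flipping one indicator multiplies
the score by exactly `exp(coef)`.

A published seven-term colon-cancer model of this form is bundled verbatim
(coefficients to their printed precision, cutoff 1.0544). The source
formula prints seven terms while its surrounding text counts eight pairs;
the package ships exactly the printed seven and does not invent an eighth.

An empty model (nothing survives selection) is a reported outcome — "no
prognostic pairs" — not an error, so null cohorts degrade cleanly.

## Survival evaluation

Kaplan–Meier curves come from `lifelines`; samples censored exactly at an
event time count as at risk there (the standard convention). The k-group
log-rank statistic is referred to a χ² distribution with k−1 degrees of
freedom (asymptotic p-values; at cohort sizes of hundreds a permutation
reference adds nothing).

Time-dependent discrimination uses the **cumulative-case / dynamic-control
AUC with inverse-probability-of-censoring weights** (IPCW). At horizon t,
cases are samples with an observed event by t (weight 1/Ĝ(T⁻)), controls
are samples still under observation after t (weight 1/Ĝ(t)), with Ĝ the
Kaplan–Meier estimate of the censoring distribution; tied scores contribute
1/2. Several "time-dependent ROC" definitions circulate; the IPCW
cumulative/dynamic form is consistent under independent censoring and is
the one implemented here (the test suite cross-checks it against
scikit-survival's independent implementation). Horizons are given in years
and converted at 365.25 days/year when survival times are in days. A
horizon with no case, no control, or beyond the last follow-up is reported
as missing, never defaulted to 0.5.

## Subtype discovery and classification

Consensus clustering: for each candidate k (default 2–6), 1,000 (default)
subsampled runs of partitioning-around-medoids on Euclidean distances, each
on 80% of samples; consensus(i,j) is the fraction of co-sampled runs in
which i and j co-cluster. Final labels cut an average-linkage tree of
1 − consensus. PAM is a small in-package implementation (greedy BUILD
initialization, then alternate assignment/update sweeps): no k-medoids
implementation ships with the installed scientific stack.

k is selected from the consensus CDF area A(k). The incremental series is
Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1))/A(k−1) beyond; the chosen k is the
one after which the incremental gain collapses — the largest drop
Δ(k) − Δ(k+1), with Δ past the top of the range taken as 0 and ties going
to the smaller k. This automates the elbow that consensus-clustering
practice reads off the delta-area plot. Two caveats, verified on synthetic
cohorts: the criterion is reliable when subtypes are well separated and of
comparable size, and it cannot be expected to split off a very small
minority subtype (separating a ~10% cluster adds little CDF area, so the
knee stays at the smaller k).

Clustering and classification operate on whatever matrix they are given;
for log-normal expression the examples and pipeline pass log-scale values,
since Euclidean distances on the raw scale are dominated by a handful of
high-magnitude genes.

Two classifiers port discovered subtypes to new cohorts, both over per-gene
z-scaled expression with constants frozen from training (unscaled genes
would let high-variance genes dominate):

- **Nearest medoid.** Per-cluster medoid = the member minimizing summed
  within-cluster Euclidean distance (PAM-consistent); a new sample takes the
  label of its nearest medoid, distance ties breaking to the lowest cluster
  index.
- **MLP.** Three hidden layers of 16, 64 and 64 units; an exhaustive grid
  over 4 activations × 5 L2 penalties (1e-5 … 1e-1) × 3 solvers = 60
  combinations, scored by stratified K-fold cross-validated accuracy
  (N correct / N total) and refit on all data. Stratification protects
  minority subtypes; the whole search is deterministic given one seed.

`compare_classifiers` labels a test cohort with both, runs a log-rank test
across each predicted labelling, and prefers the smaller p (ties to the
first listed). A classifier predicting a single class is reported "not
evaluable" rather than failing.

## Tumour characterization

**ssGSEA.** Per sample, genes are ranked by expression (average ranks on
ties, highest expression → rank N); walking the descending list, the score
of a gene set is the integrated difference between the weighted in-set ECDF
(weights |rank|^0.25, the original single-sample default) and the uniform
out-of-set ECDF. Scores are rank-based and therefore bit-invariant under
per-sample monotone transforms. No cross-sample normalization by default
(scores represent relative abundance within a cohort); a min-max flag
exists. Set genes absent from the matrix are dropped with a warning; an
empty overlap yields a missing score.

**TMB.** Mutations per megabase: counted mutation records divided by the
captured territory, default 38 Mb (the conventional whole-exome size — the
denominator is configurable because reporting conventions differ).
Counted classes default to the nonsynonymous set (missense, nonsense,
frameshift, in-frame, splice-site, nonstop, translation-start); also
configurable. Risk-group burden comparisons use the two-sided Wilcoxon
rank-sum test with tie correction and no continuity correction (identical
groups give p = 1 exactly); categorical clinical comparisons use plain
Pearson χ² without Yates correction.

## Risk-related genes

Differential expression between risk groups uses a moderated two-sample t:
per-gene pooled variances are shrunk toward a scaled-inverse-χ² prior fitted
by method of moments on log-variances (Fisher-distribution identities, with
the prior degrees of freedom solved from the excess spread of log s² via a
trigamma inversion), t referred to d + d₀ degrees of freedom, Benjamini–
Hochberg adjustment, DEG call at adjusted p < 0.01. Genes with zero
variance in both groups get p = 1 with a warning.

On the DEGs, two regressions of the continuous risk linear predictor (a
binary-group mode exists behind a flag; the continuous target is what an
RMSE selection criterion implies):

- **L1 arm:** lasso on standardized expression, penalty by K-fold CV under
  the one-standard-error rule — the sparsest penalty within one SE of the
  CV minimum. The 1-SE rule matters: on a flat CV curve (pure-noise
  target) the minimizing penalty routinely admits chance genes, and both
  arms tend to admit the *same* chance genes, so the intersection alone is
  not a sufficient guard.
- **RF arm:** random-forest regression, genes ranked by permutation
  importance, and the importance-ranked prefix whose cross-validated RMSE
  is smallest is kept (the "smallest RMSE" point).

The final risk-related genes are the intersection of the two selections; an
empty intersection is a valid, logged outcome.

## Synthetic cohorts

The generator produces the statistical shape this analysis assumes, with
every estimand known:

- **Expression**: log-normal, `log x = mu_g + delta_{g,subtype} + eps`,
  `mu_g ~ N(2, 1)`, noise sd 1.0. Subtype shifts `delta ~ N(0, sep²)`
  (default sep 1.5) on the signature genes only, so non-signature genes are
  pure noise and clustering-recovery tests quantify signal directly.
- **Cohort shape**: default 400 samples, 500 genes, 66 signature genes,
  three subtypes with a 217/188/43-style imbalance (balanced proportions
  are used where a test needs symmetric subtypes).
- **Hazard**: `eta = Σ beta_p · I(pair_p)` over planted pairs (plus an
  optional per-subtype term); survival times from Weibull proportional
  hazards (default shape 1.2, scale 1500 days) by inverse CDF. Planting a
  pair equalizes the two genes' baseline means by default so the indicator
  is a fair coin rather than degenerate; planted-pair genes are excluded
  from subtype shifts so the two planted structures do not confound.
- **Censoring**: independent exponential, rate calibrated by bisection so
  the expected censored fraction hits the target (default 0.4; the target
  must lie strictly inside (0, 1)).
- **Batch effects**: optional per-sample strictly increasing maps
  `a·x^b + c` (a, b > 0), which by construction preserve every pair
  indicator — the property the encoding exists for.
- **Mutations** (for burden tests): per-sample Poisson counts, assigned
  random genes and a missense classification — sufficient for burden
  arithmetic, nothing more.
- **Population vs cohort seeds**: gene means and subtype shifts derive from
  a `population_seed`, everything sample-level from `seed`, so train/test
  cohorts can share a population while resampling individuals.

What the generator does **not** emulate: gene–gene correlation beyond the
shared subtype factor, platform-specific noise models, informative
censoring, copy-number or mutation-signature structure, or real pathway
composition. Tests passing on these cohorts therefore demonstrate
correctness of the algorithms and calibration of the statistics under the
stated model — not clinical performance on real tumours.

## Numerical and design choices

- Breslow tie handling in all Cox fits; the synthetic data draw continuous
  times so oracle comparisons are exact. Small-instance fits agree with a
  brute-force Newton maximization of the written partial likelihood to 1e-6.
- One global seed; stage seeds derive by SHA-256 of (seed, stage name),
  keeping stages decoupled but reproducible, and below 2³¹.
- Model JSON stores coefficients as decimal strings, parsed once, so
  serialization round-trips bit-exactly across platforms.
- Gene identifiers are whitespace-trimmed, case-sensitive symbols; no alias
  resolution. Duplicate expression rows collapse by mean (the common
  microarray convention); duplicate sample columns are an error.
- Degenerate inputs are contracts, not crashes: zero-variance pairs are
  skipped with a warning, empty models report "no prognostic pairs",
  undefined AUC horizons are missing, empty gene-set overlaps are missing,
  single-class predictions are "not evaluable".
- Default problem sizes in the test suite and acceptance script (cohorts of
  150–400 samples, signatures of 20–66 genes, 100–250 consensus
  repetitions) were chosen as the smallest sizes at which the statistical
  claims under test are comfortably identifiable.
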
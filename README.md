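# pairsurv

Gene-pair rank-based prognostic modelling for tumour transcriptomics.

## The problem

Prognostic expression signatures trained on one cohort routinely fall apart
on another because absolute expression values carry platform and batch
effects. `pairsurv` implements a signature family that sidesteps
normalization entirely: the unit of information is the **within-sample
ordering of a gene pair**,

    I(A|B, s) = 1 if expression(A, s) > expression(B, s), else 0,

which is invariant to any strictly increasing per-sample transform of the
data. On top of this encoding the package builds the full analysis a
colon-cancer prognostic study of this type runs:

- **Pair features** — pair enumeration (n genes → n(n−1)/2 pairs), order
  indicators with ties → 0, and the informative-frequency filter that keeps
  pairs whose fraction of 1s lies in [0.2, 0.8] on the training cohort.
- **Risk model** — univariate Cox screen (Breslow ties, Wald p < 0.05) →
  L1-penalized Cox with K-fold cross-validated penalty (lambda.min) →
  multivariate refit with one backward step. The risk score is
  `exp(Σ coef·indicator)`; the high/low cutoff is the frozen training
  median. The published seven-term colon-cancer model (coefficients such as
  +1.028064·MPP2|CPT1C, cutoff 1.0544) ships with the package.
- **Survival evaluation** — Kaplan–Meier, k-group log-rank, and IPCW
  cumulative/dynamic time-dependent AUC at 1/3/5 years.
- **Subtypes** — consensus clustering (subsampled PAM, Euclidean, consensus
  CDF-area k selection) plus the two portable classifiers: nearest medoid
  and a 16/64/64 MLP tuned by an exhaustive 4×5×3 grid search.
- **Characterization** — single-sample gene-set enrichment (rank-based
  running sum), tumour mutation burden (mutations/Mb), Wilcoxon and χ²
  group tests.
- **Risk-related genes** — moderated-t differential expression (BH,
  adjusted p < 0.01) followed by the intersection of lasso and
  random-forest selections against the continuous risk score.
- **Synthetic cohorts** — a generator with planted subtypes, planted
  prognostic pairs under Weibull proportional hazards, calibrated
  censoring and optional monotone batch distortions, so every claim above
  is testable with known ground truth.

Intended users: computational biologists reproducing or extending
pair-based prognostic signatures, and method developers who need a fully
specified, simulation-backed reference implementation.

## Worked example

`examples/02_train_risk_model.py` plants three prognostic pairs (log hazard
ratios +1, +1, −1) among 40 decoys in a 300-sample cohort and runs the
funnel:

```
Funnel (count surviving each reduction step):
  pairs_enumerated: 43
  pairs_informative: 43
  pairs_univariate: 7
  pairs_lasso: 6
  pairs_final: 6

Final model (planted pairs were G0001|G0002 +1, G0003|G0004 +1, G0005|G0006 -1):
  G0001|G0002: coefficient +0.988  (hazard ratio 2.68)
  G0003|G0004: coefficient +1.295  (hazard ratio 3.65)
  G0005|G0006: coefficient -0.894  (hazard ratio 0.41)
  G0031|G0032: coefficient -0.402  (hazard ratio 0.67)
  G0055|G0056: coefficient +0.379  (hazard ratio 1.46)
  G0077|G0078: coefficient +0.362  (hazard ratio 1.44)

Risk cutoff (training median score): 2.3032
```

All three planted pairs survive every stage with fitted coefficients near
the planted ±1 (hazard ratios near e^±1 ≈ 2.72 / 0.37); three decoys with
small coefficients also clear the p < 0.05 retention threshold on this
single draw, which is the expected false-discovery behaviour at these
settings (across 100 replicates the type-I rate of the screen is at its
nominal 5% — that is one of the test suite's checks). The cutoff is the
median training score, so by construction half the training cohort is
called high risk.

Other examples cover pair encoding on a hand-checkable micro-cohort (01),
scoring with the bundled published model (03), subtype discovery and
classifier comparison (04), held-out evaluation and tumour
characterization (05), and risk-related gene selection (06). A thin CLI
(`pairsurv simulate|encode|train|score|cluster|classify|evaluate|ssgsea|tmb|rrg|run`)
wraps the same functions for shell use; `pairsurv run --config cfg.yaml`
drives the whole pipeline with per-stage manifests.

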
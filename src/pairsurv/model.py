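"""Gene-pair risk model assembly and scoring.

The model-building funnel works on binary pair indicators and overall
survival:

1. univariate proportional-hazards screen (one Cox fit per pair, Breslow tie
   handling, Wald p < alpha to pass);
2. L1-penalized Cox over the surviving pairs, penalty chosen by K-fold
   cross-validated partial likelihood at the maximizing penalty (the
   ``lambda.min`` convention);
3. joint multivariate Cox fit with a single backward-elimination step (pairs
   with Wald p >= keep_alpha are dropped and the model refit once).

The fitted risk score for a sample is ``exp(sum_i coef_i * indicator_i)``;
the high/low risk cutoff is frozen at the median score of the training
cohort and applied unchanged to any test cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.duration.hazard_regression import PHReg

from .io import PairRiskModel
from .pairs import GenePair, PairFeatureMatrix, encode_pairs, pair_label

logger = logging.getLogger(__name__)

__all__ = [
    "univariate_screen",
    "lasso_select",
    "multivariate_fit",
    "score_mkpc",
    "score_expression",
    "train_funnel",
    "published_model",
    "PUBLISHED_CUTOFF",
    "FunnelReport",
]

#: Median training-cohort risk score of the bundled published model.
PUBLISHED_CUTOFF = 1.0544

_PUBLISHED_TERMS: list[tuple[GenePair, float]] = [
    (("MPP2", "CPT1C"), 1.028064),
    (("PPARGC1A", "CD36"), -1.09876),
    (("NOG", "CD1B"), 0.573201),
    (("GAMT", "CCL22"), 0.661607),
    (("GSR", "MAGEF1"), -0.57286),
    (("NGF", "CD1B"), 0.593767),
    (("CRIP2", "ACTR8"), 0.927301),
]


def published_model() -> PairRiskModel:
    """The published colon-cancer gene-pair risk model, verbatim.

    Seven terms (five hazardous with positive coefficients, two protective
    with negative coefficients) over indicators such as ``MPP2|CPT1C``; the
    surrounding text speaks of eight pairs, but only seven appear in the
    printed formula, so seven are bundled — no eighth term is invented.  The
    cutoff 1.0544 is the training-cohort median score.
    """
    return PairRiskModel(
        terms=list(_PUBLISHED_TERMS),
        cutoff=PUBLISHED_CUTOFF,
        metadata={"source": "published colon-cancer model", "note": "7 printed terms"},
    )


def _align(pfm: PairFeatureMatrix, survival: pd.DataFrame):
    """Common samples of a feature matrix and survival table, order-stable."""
    common = [s for s in pfm.sample_ids if s in survival.index]
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared between features and survival")
    X = pfm.indicators[common].to_numpy().T.astype(float)  # samples x pairs
    surv = survival.loc[common]
    return X, surv["time"].to_numpy(float), surv["event"].to_numpy(int), common


def breslow_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow log partial likelihood at a fixed coefficient vector."""
    beta = np.asarray(beta, float)
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, time_o, event_o = eta[order], time[order], event[order]
    log_cumsum = np.logaddexp.accumulate(eta_o)
    # risk set at an event time = all samples with time >= t; with decreasing
    # order and ties grouped, cumulative logsumexp up to the last tied index
    ll = 0.0
    i = 0
    n = len(time_o)
    while i < n:
        j = i
        while j + 1 < n and time_o[j + 1] == time_o[i]:
            j += 1
        denom = log_cumsum[j]
        for k in range(i, j + 1):
            if event_o[k]:
                ll += eta_o[k] - denom
        i = j + 1
    return float(ll)


def _phreg(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    model = PHReg(time, X, status=event, ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100)


def univariate_screen(
    pfm: PairFeatureMatrix, survival: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """One single-covariate Cox fit per pair; Wald test at ``alpha``.

    Returns a DataFrame indexed by pair label with columns ``coef``, ``se``,
    ``hr``, ``p`` and ``passed``.  Pairs with zero variance across samples are
    skipped with a warning (they cannot occur after the informative-frequency
    filter, but are guarded against).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    X, time, event, _ = _align(pfm, survival)
    if event.sum() < 2:
        raise ValueError("need at least 2 observed events for the screen")
    rows = []
    for j, pair in enumerate(pfm.pairs):
        x = X[:, [j]]
        if x.std() == 0:
            logger.warning("pair %s has zero variance; skipped", pair_label(pair))
            rows.append((pair_label(pair), np.nan, np.nan, np.nan, np.nan, False))
            continue
        res = _phreg(x, time, event)
        coef = float(res.params[0])
        se = float(res.bse[0])
        p = float(res.pvalues[0])
        rows.append((pair_label(pair), coef, se, float(np.exp(coef)), p, bool(p < alpha)))
    return pd.DataFrame(
        rows, columns=["pair", "coef", "se", "hr", "p", "passed"]
    ).set_index("pair")


def _event_balanced_folds(n: int, event: np.ndarray, n_folds: int, seed: int):
    """K-fold splits re-drawn (<=5 attempts) until every fold holds an event."""
    from sklearn.model_selection import KFold

    for attempt in range(5):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        splits = list(kf.split(np.arange(n)))
        ok = all(
            event[tr].sum() > 0 and event[te].sum() > 0 for tr, te in splits
        )
        if ok:
            return splits
    raise RuntimeError("could not build folds with events in every fold (5 attempts)")


def lasso_select(
    pfm: PairFeatureMatrix,
    survival: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
) -> list[GenePair]:
    """L1-penalized Cox selection at the cross-validated optimum penalty.

    The penalty path comes from a coordinate-descent elastic net with pure L1
    penalty; the penalty is chosen to maximize the summed held-out Breslow
    partial log-likelihood over ``n_folds`` folds (lambda.min).  Returns the
    pairs with nonzero coefficients in the full-data refit at that penalty,
    deterministically for a given seed.
    """
    if not pfm.pairs:
        raise ValueError("no pairs to select from")
    X, time, event, _ = _align(pfm, survival)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    cv_ll = np.zeros(len(alphas))
    splits = _event_balanced_folds(len(time), event, n_folds, seed)
    for tr, te in splits:
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold.fit(X[tr], Surv.from_arrays(event=event[tr].astype(bool), time=time[tr]))
        fitted = np.asarray(fold.alphas_)
        coefs = np.asarray(fold.coef_)  # (n_features, n_fitted)
        for i, a in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted - a)))
            cv_ll[i] += breslow_partial_loglik(coefs[:, j], X[te], time[te], event[te])

    best = int(np.argmax(cv_ll))
    coef_best = np.asarray(path.coef_)[:, best]
    selected = [p for p, c in zip(pfm.pairs, coef_best) if c != 0.0]
    logger.info(
        "lasso: penalty %.5g (index %d/%d) keeps %d of %d pairs",
        alphas[best], best, len(alphas), len(selected), len(pfm.pairs),
    )
    return selected


def multivariate_fit(
    selected_pairs: list[GenePair],
    pfm: PairFeatureMatrix,
    survival: pd.DataFrame,
    keep_alpha: float = 0.05,
    backward_step: bool = True,
) -> PairRiskModel:
    """Joint Cox fit over the selected pairs, one backward step, frozen cutoff.

    Pairs with multivariate Wald p >= ``keep_alpha`` are dropped and the model
    refit once.  The cutoff is the median risk score of the training cohort.
    An empty selection (or a backward step that removes everything) yields an
    empty model with unit cutoff and a logged "no prognostic pairs" notice
    rather than an error, so a pipeline run on a null cohort degrades cleanly.
    """
    def empty_model(note: str) -> PairRiskModel:
        logger.warning("no prognostic pairs: %s", note)
        return PairRiskModel(terms=[], cutoff=1.0, metadata={"note": f"no prognostic pairs ({note})"})

    if not selected_pairs:
        return empty_model("empty selection")
    sub = pfm.subset(selected_pairs)
    X, time, event, _ = _align(sub, survival)

    res = _phreg(X, time, event)
    pairs = list(selected_pairs)
    if backward_step:
        keep = [i for i in range(len(pairs)) if res.pvalues[i] < keep_alpha]
        if len(keep) < len(pairs):
            if not keep:
                return empty_model("backward elimination removed every pair")
            pairs = [pairs[i] for i in keep]
            X = X[:, keep]
            res = _phreg(X, time, event)

    terms = [(p, float(c)) for p, c in zip(pairs, res.params)]
    model = PairRiskModel(
        terms=terms,
        cutoff=1.0,  # placeholder until the training median is known
        metadata={
            "n_selected": len(selected_pairs),
            "n_final": len(pairs),
            "se": [float(s) for s in res.bse],
            "p": [float(p) for p in res.pvalues],
        },
    )
    scores = score_mkpc(model, pfm)
    model.cutoff = float(np.median(scores["mkpc_score"]))
    return model


def score_mkpc(model: PairRiskModel, pfm: PairFeatureMatrix) -> pd.DataFrame:
    """Score samples with a fitted model from precomputed pair indicators.

    Returns a DataFrame indexed by sample with columns ``linear_sum``,
    ``mkpc_score`` (= exp(linear_sum)) and ``risk_group`` (high iff score
    strictly exceeds the model cutoff).  Raises if any model pair cannot be
    read from the feature matrix; there is no silent imputation.
    """
    labels = []
    for p in model.pairs:
        lab = pair_label(p)
        if lab not in pfm.indicators.index:
            missing = [
                pair_label(q) for q in model.pairs if pair_label(q) not in pfm.indicators.index
            ]
            raise KeyError(f"model pairs missing from feature matrix: {missing}")
        labels.append(lab)
    coefs = np.array([c for _, c in model.terms])
    if labels:
        ind = pfm.indicators.loc[labels].to_numpy().astype(float)
        linear = coefs @ ind
    else:
        linear = np.zeros(len(pfm.sample_ids))
    score = np.exp(linear)
    return pd.DataFrame(
        {
            "linear_sum": linear,
            "mkpc_score": score,
            "risk_group": np.where(score > model.cutoff, "high", "low"),
        },
        index=pd.Index(pfm.sample_ids, name="sample"),
    )


def score_expression(model: PairRiskModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Score samples directly from an expression matrix.

    Encodes exactly the model's pairs (in the model's stored orientation) and
    scores them; raises listing any missing gene symbols.
    """
    missing = sorted(set(model.genes) - set(expr.index))
    if missing:
        raise KeyError(f"genes required by the model are missing: {missing}")
    pfm = encode_pairs(expr, model.pairs)
    return score_mkpc(model, pfm)


@dataclass
class FunnelReport:
    """Feature counts at every reduction step of the training funnel."""

    n_enumerated: int
    n_informative: int
    n_univariate: int
    n_lasso: int
    n_final: int
    screen: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict[str, int]:
        return {
            "pairs_enumerated": self.n_enumerated,
            "pairs_informative": self.n_informative,
            "pairs_univariate": self.n_univariate,
            "pairs_lasso": self.n_lasso,
            "pairs_final": self.n_final,
        }


def train_funnel(
    pfm: PairFeatureMatrix,
    survival: pd.DataFrame,
    alpha: float = 0.05,
    n_folds: int = 10,
    seed: int = 0,
    low: float = 0.2,
    high: float = 0.8,
    keep_alpha: float = 0.05,
) -> tuple[PairRiskModel, FunnelReport]:
    """Run the full reduction funnel on an encoded training cohort.

    frequency filter -> univariate screen -> L1 selection -> multivariate fit;
    the report carries the count after each step (the classic
    enumerate/informative/screened/selected/final narrative).
    """
    from .pairs import filter_informative

    informative = filter_informative(pfm, low=low, high=high)
    if not informative.pairs:
        model = multivariate_fit([], informative, survival)
        return model, FunnelReport(len(pfm.pairs), 0, 0, 0, 0, None)
    screen = univariate_screen(informative, survival, alpha=alpha)
    passed = [p for p, ok in zip(informative.pairs, screen["passed"]) if ok]
    if not passed:
        model = multivariate_fit([], informative, survival)
        return model, FunnelReport(len(pfm.pairs), len(informative.pairs), 0, 0, 0, screen)
    selected = lasso_select(informative.subset(passed), survival, n_folds=n_folds, seed=seed)
    model = multivariate_fit(selected, informative, survival, keep_alpha=keep_alpha)
    report = FunnelReport(
        n_enumerated=len(pfm.pairs),
        n_informative=len(informative.pairs),
        n_univariate=len(passed),
        n_lasso=len(selected),
        n_final=len(model.terms),
        screen=screen,
    )
    return model, report
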
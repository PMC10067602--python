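"""Risk-related gene selection.

Two stages: (1) differential expression between the high- and low-risk groups
using a moderated two-sample t statistic (empirical-Bayes shrinkage of the
per-gene variance toward a cross-gene prior, Benjamini-Hochberg adjustment,
DEG call at adjusted p < 0.01); (2) on the DEGs, two regressions of the
continuous risk target on expression — L1-penalized linear regression with a
cross-validated penalty, and a random forest whose feature count minimizes
cross-validated RMSE over importance-ranked subsets — with the final
risk-related genes defined as the intersection of the two selections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special, optimize
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["differential_expression", "select_rrg", "RrgResult"]


def _fit_inv_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square variance prior.

    Matches the first two moments of log(s^2) under the hierarchical model
    s^2 | sigma^2 ~ sigma^2 chi^2_d / d, sigma^2 ~ s0^2 d0 / chi^2_d0, using
    digamma/trigamma identities; returns (d0, s0^2).  Infinite d0 (no excess
    spread in the observed variances) is capped at 1e6, which is numerically
    the no-moderation-needed limit.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return 1e6, float(np.median(s2[ok])) if ok.any() else (1e6, 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = max(np.var(e, ddof=1) - special.polygamma(1, df / 2.0), 0.0)
    if e_var <= 1e-10:
        d0 = 1e6
    else:
        # solve trigamma(d0/2) = e_var
        def f(x):
            return special.polygamma(1, x / 2.0) - e_var

        lo, hi = 1e-3, 1e6
        if f(lo) < 0:
            d0 = lo
        elif f(hi) > 0:
            d0 = 1e6
        else:
            d0 = optimize.brentq(f, lo, hi)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def differential_expression(
    expr: pd.DataFrame, group_labels: pd.Series, adj_p_threshold: float = 0.01
) -> pd.DataFrame:
    """Moderated two-sample t test per gene with BH adjustment.

    Returns a DataFrame indexed by gene with columns ``mean_diff`` (group 2
    minus group 1, groups in sorted label order), ``t``, ``p``, ``adj_p`` and
    ``deg`` (adjusted p < threshold).  Genes with zero variance in both
    groups get p = 1 with a warning.
    """
    group_labels = group_labels.loc[expr.columns]
    names = sorted(group_labels.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    a = expr.loc[:, group_labels == names[0]].to_numpy()
    b = expr.loc[:, group_labels == names[1]].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    d0, s0_sq = _fit_inv_chisq_prior(s2, df)
    s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
    zero_both = s2 == 0
    if zero_both.any():
        logger.warning("%d gene(s) with zero variance in both groups: p set to 1", zero_both.sum())

    diff = m2 - m1
    denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    df_total = min(df + d0, 1e6)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero_both, 1.0, p)
    adj_p = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"mean_diff": diff, "t": t, "p": p, "adj_p": adj_p, "deg": adj_p < adj_p_threshold},
        index=expr.index,
    )
    return out


@dataclass
class RrgResult:
    lasso_selected: set[str]
    rf_selected: set[str]
    final: set[str]
    rf_subset_rmse: dict[int, float]

    def __post_init__(self) -> None:
        assert self.final == (self.lasso_selected & self.rf_selected)


def select_rrg(
    expr: pd.DataFrame,
    target: pd.Series,
    seed: int = 0,
    n_folds: int = 5,
    n_trees: int = 300,
    mode: str = "linear",
) -> RrgResult:
    """Intersect L1 and random-forest selections of risk-related genes.

    ``expr`` should be restricted to the DEGs; ``target`` is the continuous
    per-sample risk linear predictor (``mode="linear"``) or a 0/1 group
    indicator (``mode="binary"``, still fit by regression as the RMSE
    criterion implies).  The L1 arm standardizes genes and takes nonzero
    coefficients at the cross-validated penalty under the one-standard-error
    rule; the RF arm ranks genes by
    permutation importance and keeps the importance-ranked prefix whose
    cross-validated RMSE is smallest.  Deterministic for a fixed seed.  An
    empty intersection is a valid (logged) outcome.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 candidate genes")
    if mode not in ("linear", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    common = expr.columns.intersection(target.index)
    X = expr[common].to_numpy().T  # samples x genes
    y = target.loc[common].to_numpy(float)
    genes = list(expr.index)

    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    lasso_cv = LassoCV(cv=cv, random_state=seed, max_iter=50000)
    lasso_cv.fit(Xs, y)
    # one-standard-error rule: the sparsest penalty whose CV error is within
    # one SE of the minimum (guards against chance selections on flat curves)
    mse_mean = lasso_cv.mse_path_.mean(axis=1)
    mse_se = lasso_cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lasso_cv.mse_path_.shape[1])
    i_min = int(np.argmin(mse_mean))
    threshold = mse_mean[i_min] + mse_se[i_min]
    eligible = np.where(mse_mean <= threshold)[0]
    alpha_1se = float(lasso_cv.alphas_[eligible].max())
    lasso = Lasso(alpha=alpha_1se, max_iter=50000)
    lasso.fit(Xs, y)
    lasso_selected = {g for g, c in zip(genes, lasso.coef_) if c != 0.0}

    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = permutation_importance(rf, X, y, n_repeats=5, random_state=seed, n_jobs=1)
    order = np.argsort(-imp.importances_mean, kind="stable")

    sizes = sorted({m for m in (1, 2, 3, 5, 8, 12, 20, 30, 50, len(genes)) if m <= len(genes)})
    rmse_by_size: dict[int, float] = {}
    for m in sizes:
        cols = order[:m]
        errs = []
        for tr, te in cv.split(X):
            sub_rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
            sub_rf.fit(X[np.ix_(tr, cols)], y[tr])
            pred = sub_rf.predict(X[np.ix_(te, cols)])
            errs.append(np.mean((pred - y[te]) ** 2))
        rmse_by_size[m] = float(np.sqrt(np.mean(errs)))
    best_m = min(rmse_by_size, key=lambda m: (rmse_by_size[m], m))
    rf_selected = {genes[i] for i in order[:best_m]}

    final = lasso_selected & rf_selected
    if not final:
        logger.info("empty intersection of L1 and RF selections")
    return RrgResult(
        lasso_selected=lasso_selected, rf_selected=rf_selected,
        final=final, rf_subset_rmse=rmse_by_size,
    )
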
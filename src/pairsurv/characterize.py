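"""Tumour characterization: ssGSEA immune scores, mutation burden, group tests.

ssGSEA here is the single-sample running-sum statistic: for one sample, genes
are ranked by expression, and the enrichment score of a gene set is the
integrated difference between the weighted in-set ECDF (weights =
|rank|^exponent) and the uniform out-of-set ECDF over the ranked list.  Being
purely rank-based, the scores are invariant to any strictly increasing
transform of a sample's expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import NONSYNONYMOUS_CLASSES

logger = logging.getLogger(__name__)

__all__ = ["ssgsea_score", "compute_tmb", "wilcoxon_rank_sum", "chi_square_test"]

DEFAULT_EXOME_MB = 38.0


def ssgsea_score(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    weight_exponent: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (gene sets x samples).

    Per sample: rank all genes by expression (descending; average ranks for
    ties, highest expression gets rank N), then walk the ranked list
    accumulating ``P_in - P_out`` where ``P_in`` weights in-set genes by
    |rank value|^``weight_exponent`` and ``P_out`` steps uniformly over
    out-of-set genes; the enrichment score is the sum over all positions.
    Set genes absent from the matrix are dropped with a warning; a set with
    no overlap gets NaN.  ``normalize=True`` min-max rescales each gene-set
    row across samples to [0, 1].
    """
    n_genes = expr.shape[0]
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    memberships = {}
    for name, genes in gene_sets.items():
        present = [g for g in dict.fromkeys(genes) if g in gene_pos]
        missing = len(set(genes)) - len(present)
        if missing:
            logger.warning("set %s: %d gene(s) absent from matrix dropped", name, missing)
        memberships[name] = np.array([gene_pos[g] for g in present], dtype=int)

    vals = expr.to_numpy()
    scores = np.full((len(gene_sets), expr.shape[1]), np.nan)
    for s in range(expr.shape[1]):
        x = vals[:, s]
        ranks = stats.rankdata(x)  # 1..N, highest expression -> N, ties averaged
        order = np.argsort(-ranks, kind="stable")  # descending expression
        rank_desc = ranks[order]
        for gi, (name, members) in enumerate(memberships.items()):
            if len(members) == 0:
                continue
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[members] = True
            in_set_desc = in_set[order]
            w = np.abs(rank_desc) ** weight_exponent
            w_in = np.where(in_set_desc, w, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            step_out = np.where(in_set_desc, 0.0, 1.0)
            p_out = np.cumsum(step_out) / (n_genes - len(members))
            scores[gi, s] = float(np.sum(p_in - p_out))
    out = pd.DataFrame(scores, index=list(gene_sets), columns=expr.columns)
    if normalize:
        rng_ = out.max(axis=1) - out.min(axis=1)
        out = out.sub(out.min(axis=1), axis=0).div(rng_.replace(0, 1.0), axis=0)
    return out


def compute_tmb(
    mutations: pd.DataFrame,
    exome_size_mb: float = DEFAULT_EXOME_MB,
    counted_classes: frozenset[str] | set[str] = NONSYNONYMOUS_CLASSES,
    sample_roster: list[str] | None = None,
) -> pd.DataFrame:
    """Tumour mutation burden: counted mutations per megabase per sample.

    Only records whose variant classification is in ``counted_classes``
    contribute (default: the nonsynonymous classes).  Samples listed in
    ``sample_roster`` but absent from the table get a burden of zero.
    """
    if exome_size_mb <= 0:
        raise ValueError("exome_size_mb must be positive")
    if len(mutations):
        counted = mutations[mutations["variant_classification"].isin(counted_classes)]
        counts = counted.groupby("sample").size()
    else:
        counts = pd.Series(dtype=int)
    if sample_roster is not None:
        counts = counts.reindex(sample_roster, fill_value=0)
    out = pd.DataFrame({"mutation_count": counts.astype(int)})
    out["tmb"] = out["mutation_count"] / exome_size_mb
    out.index.name = "sample"
    return out


def wilcoxon_rank_sum(values: pd.Series, groups: pd.Series) -> dict:
    """Two-sided Wilcoxon rank-sum test between exactly two groups.

    Normal approximation with tie correction (no continuity correction, so
    identical groups give p = 1 exactly).
    """
    groups = groups.loc[values.index]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    a = values[groups == names[0]].to_numpy(float)
    b = values[groups == names[1]].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    stat, p = stats.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=False, method="asymptotic"
    )
    return {"statistic": float(stat), "p": float(p), "groups": names}


def chi_square_test(table: pd.DataFrame | np.ndarray) -> dict:
    """Plain Pearson chi-square test of independence (no Yates correction)."""
    arr = np.asarray(table, float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c contingency table with r, c >= 2")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return {"chi_square": float(chi2), "p": float(p), "dof": int(dof)}
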
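"""Within-sample gene-pair order indicators.

The feature "A|B" for a sample is 1 when gene A's expression strictly exceeds
gene B's in that sample, and 0 otherwise (ties fall in the 0 branch).  Because
the indicator depends only on the within-sample ordering of two genes, it is
invariant to any strictly increasing per-sample transform of the expression
values — the property that makes a pair-based signature robust to platform and
batch effects without explicit normalization.

Pairs whose indicator is (almost) constant across the training cohort carry no
discriminative information; ``filter_informative`` removes pairs whose
frequency of 1s falls outside [0.2, 0.8] (bounds inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GenePair = tuple[str, str]


def canonical_pair(gene_a: str, gene_b: str) -> GenePair:
    """Orient a pair lexicographically (reproducible across runs/platforms)."""
    if gene_a == gene_b:
        raise ValueError(f"degenerate pair: {gene_a!r} with itself")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def pair_label(pair: GenePair) -> str:
    return f"{pair[0]}|{pair[1]}"


def parse_pair_label(label: str) -> GenePair:
    a, sep, b = label.partition("|")
    if not sep or not a or not b:
        raise ValueError(f"malformed pair label {label!r}")
    return (a, b)


@dataclass
class PairFeatureMatrix:
    """Binary pair indicators, pairs x samples.

    ``indicators`` is a DataFrame whose index holds "A|B" labels in pair
    order and whose values are 0/1.  ``frequencies`` is the per-pair fraction
    of samples with indicator 1.
    """

    pairs: list[GenePair]
    indicators: pd.DataFrame
    n_deleted: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != self.indicators.shape[0]:
            raise ValueError("pair list and indicator rows disagree")
        vals = self.indicators.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("indicators must be binary")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def frequencies(self) -> pd.Series:
        return self.indicators.mean(axis=1)

    def subset(self, pairs: list[GenePair]) -> "PairFeatureMatrix":
        labels = [pair_label(p) for p in pairs]
        missing = [l for l in labels if l not in self.indicators.index]
        if missing:
            raise KeyError(f"pairs absent from feature matrix: {missing}")
        return PairFeatureMatrix(pairs=list(pairs), indicators=self.indicators.loc[labels])


def enumerate_pairs(gene_ids: list[str]) -> list[GenePair]:
    """All unordered pairs of distinct genes, once each, canonically oriented.

    ``n`` genes yield ``n(n-1)/2`` pairs; 66 genes yield 2,145.
    """
    genes = list(gene_ids)
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dups}")
    if len(genes) < 2:
        raise ValueError("need at least 2 unique genes to form pairs")
    return [canonical_pair(a, b) for a, b in combinations(genes, 2)]


def encode_pairs(expr: pd.DataFrame, pairs: list[GenePair]) -> PairFeatureMatrix:
    """Binarize expression into pair-order indicators.

    ``indicator(A|B, s) = 1`` iff ``expr.loc[A, s] > expr.loc[B, s]``; equality
    gives 0.  Raises ``KeyError`` naming any pair gene absent from ``expr``.
    """
    needed = {g for p in pairs for g in p}
    missing = sorted(needed - set(expr.index))
    if missing:
        raise KeyError(f"pair genes absent from expression matrix: {missing}")
    vals = expr.to_numpy()
    gene_idx = {g: i for i, g in enumerate(expr.index)}
    ia = np.fromiter((gene_idx[a] for a, _ in pairs), dtype=int, count=len(pairs))
    ib = np.fromiter((gene_idx[b] for _, b in pairs), dtype=int, count=len(pairs))
    ind = (vals[ia, :] > vals[ib, :]).astype(np.int8)
    df = pd.DataFrame(ind, index=[pair_label(p) for p in pairs], columns=expr.columns)
    return PairFeatureMatrix(pairs=list(pairs), indicators=df)


def filter_informative(
    pfm: PairFeatureMatrix, low: float = 0.2, high: float = 0.8
) -> PairFeatureMatrix:
    """Keep pairs whose frequency of 1s lies in [low, high], bounds inclusive.

    Near-constant indicators carry no classification information.  Pair order
    is preserved; the number of deleted pairs is recorded on the result.  An
    empty result is allowed (flagged in the log, not an error).
    """
    if not (0 <= low < high <= 1):
        raise ValueError(f"invalid frequency bounds [{low}, {high}]")
    freq = pfm.frequencies.to_numpy()
    keep = (freq >= low) & (freq <= high)
    kept_pairs = [p for p, k in zip(pfm.pairs, keep) if k]
    n_deleted = int((~keep).sum())
    if not kept_pairs:
        logger.warning("informative-frequency filter removed every pair")
    return PairFeatureMatrix(
        pairs=kept_pairs,
        indicators=pfm.indicators.loc[np.asarray(keep, bool)],
        n_deleted=n_deleted,
    )
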
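"""Encode gene-pair order indicators and apply the informative filter.

Builds the deterministic 12-sample, 8-gene micro-cohort, enumerates all 28
gene pairs, binarizes them into within-sample order indicators (ties -> 0),
and removes pairs whose indicator frequency falls outside [0.2, 0.8].
"""

from pairsurv import encode_pairs, enumerate_pairs, filter_informative
from pairsurv.simulate import make_worked_fixture

cohort = make_worked_fixture()
pairs = enumerate_pairs(list(cohort.expression.index))
print(f"{len(pairs)} pairs from {cohort.expression.shape[0]} genes")

pfm = encode_pairs(cohort.expression, pairs)
print("\nFirst rows of the indicator matrix (1 = first gene out-expresses the second):")
print(pfm.indicators.head())
print("\nNote G1|G2 in sample s01: both genes sit at 5.0, so the tie gives 0.")

kept = filter_informative(pfm, low=0.2, high=0.8)
print(f"\n{len(kept.pairs)} informative pairs kept, {kept.n_deleted} removed")
print("Per-pair frequency of 1s (kept pairs must lie in [0.2, 0.8]):")
print(kept.frequencies.round(3).head())
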
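"""Select risk-related genes: moderated-t DEGs, then L1 x random forest.

Constructs a two-group cohort in which 5 of 60 genes both differ between
risk groups and drive a continuous risk score, runs the empirical-Bayes
moderated t test with BH adjustment (DEG at adjusted p < 0.01), and
intersects lasso (1-SE rule) and random-forest (smallest-CV-RMSE prefix)
selections against the continuous risk target.
"""

import numpy as np
import pandas as pd

from pairsurv import differential_expression, select_rrg

rng = np.random.default_rng(12)
n_per_group = 50
n_genes = 60
X = rng.normal(0, 1, size=(n_genes, 2 * n_per_group))
X[:5, :n_per_group] += 1.5  # 5 genes shifted in the high-risk group
expr = pd.DataFrame(
    X, index=[f"GENE{i:02d}" for i in range(n_genes)],
    columns=[f"hi{i}" for i in range(n_per_group)] + [f"lo{i}" for i in range(n_per_group)],
)
risk_group = pd.Series(["high"] * n_per_group + ["low"] * n_per_group, index=expr.columns)
# continuous risk target driven by the same 5 genes
target = pd.Series(X[:5].T @ np.array([2.0, -2.0, 2.0, 2.0, -2.0])
                   + rng.normal(0, 0.5, 2 * n_per_group), index=expr.columns)

de = differential_expression(expr, risk_group, adj_p_threshold=0.01)
degs = de.index[de["deg"]].tolist()
print(f"{len(degs)} DEGs at adjusted p < 0.01 (5 genes were shifted): {degs}")

result = select_rrg(expr.loc[degs] if len(degs) >= 2 else expr, target, seed=7)
print(f"\nlasso arm selected {sorted(result.lasso_selected)}")
print(f"forest arm selected {sorted(result.rf_selected)}")
print(f"final risk-related genes (intersection): {sorted(result.final)}")
print("\nRF subset-size CV RMSE (the kept prefix minimizes this):")
print({m: round(v, 3) for m, v in result.rf_subset_rmse.items()})
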
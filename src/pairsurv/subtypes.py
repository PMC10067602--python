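"""Subtype discovery and classification over the signature genes.

Discovery uses consensus clustering: many subsampled runs of
partitioning-around-medoids (PAM, Euclidean distance), aggregated into a
consensus matrix of co-clustering frequencies per candidate k; the number of
clusters is chosen from the consensus CDF area (relative delta-area rule) and
final labels come from a hierarchical cut of 1 - consensus.

Two classifiers then port the discovered subtypes to new cohorts: a
nearest-medoid rule using the per-cluster PAM centres, and a multilayer
perceptron (hidden layers of 16, 64 and 64 units) tuned by an exhaustive
4 activations x 5 L2 penalties x 3 solvers grid search with stratified
cross-validated accuracy.  Both operate on per-gene z-scaled expression with
scaling constants frozen from the training cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .surveval import logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "pam_cluster",
    "consensus_cluster",
    "ConsensusResult",
    "SubtypeClassifier",
    "medoid_classifier_train",
    "medoid_classify",
    "mlp_grid_search",
    "mlp_classify",
    "compare_classifiers",
    "save_classifier",
    "load_classifier",
    "MLP_PARAM_GRID",
]

MLP_HIDDEN_LAYERS = (16, 64, 64)

MLP_PARAM_GRID = {
    "activation": ["identity", "logistic", "tanh", "relu"],
    "alpha": [0.00001, 0.0001, 0.001, 0.01, 0.1],
    "solver": ["lbfgs", "sgd", "adam"],
}


def pam_cluster(
    dist: np.ndarray, k: int, rng: np.random.Generator | None = None, max_iter: int = 50
) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD initialization (first medoid minimizes total distance, each
    further medoid maximizes the drop in assignment cost) followed by
    alternate assignment/update sweeps (each medoid replaced by the cluster
    member minimizing the summed within-cluster distance) until the medoid
    set is stable.  Deterministic; ``rng`` is accepted for interface
    symmetry but unused.
    """
    n = dist.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    medoids = np.empty(k, dtype=int)
    medoids[0] = int(np.argmin(dist.sum(axis=1)))
    nearest = dist[:, medoids[0]].copy()
    for c in range(1, k):
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids[:c]] = -np.inf
        medoids[c] = int(np.argmax(gains))
        nearest = np.minimum(nearest, dist[:, medoids[c]])
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if len(members) == 0:
                # re-seed an emptied cluster at the point farthest from its medoid
                far = int(np.argmax(np.min(dist[:, new_medoids], axis=1)))
                new_medoids[c] = far
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]  # k -> symmetric matrix in [0,1], diag 1
    labels: dict[int, pd.Series]  # k -> sample labels "C1".."Ck"
    cdf_area: dict[int, float]
    chosen_k: int
    sample_ids: list[str] = field(default_factory=list)


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    if len(vals) == 0:
        return 0.0
    # A = sum over sorted values of CDF * step width, over [0, 1]
    grid = np.concatenate([vals, [1.0]])
    cdf = np.arange(1, len(vals) + 1) / len(vals)
    widths = np.diff(grid)
    return float(np.sum(cdf * widths))


def consensus_cluster(
    expr: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples (columns of ``expr``) by subsampled PAM.

    For each k, ``reps`` runs each draw ``subsample`` of the samples without
    replacement, cluster them with PAM on Euclidean distances, and increment
    co-cluster counts; consensus(i,j) = co-clustered / co-sampled.  Final
    labels per k cut an average-linkage tree of 1 - consensus.

    ``chosen_k`` comes from the incremental CDF-area series Delta(k): Delta
    at the smallest k is the area itself, Delta(k) = (A(k) - A(k-1)) / A(k-1)
    beyond it, and Delta past the top of ``k_range`` is taken as 0.  The
    consensus CDF gains area rapidly up to the true cluster number and only
    marginally after, so the knee — the k with the largest drop
    Delta(k) - Delta(k+1) — marks the chosen k.  Ties break toward smaller k.
    """
    ks = sorted(k_range)
    n = expr.shape[1]
    if max(ks) + 1 > n:
        raise ValueError(f"k_range up to {max(ks)} needs more than {max(ks)} samples, have {n}")
    if min(ks) < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    X = expr.to_numpy().T  # samples x genes
    dist_full = squareform(pdist(X, metric="euclidean"))
    m = max(2, int(round(subsample * n)))

    consensus, labels, areas = {}, {}, {}
    for k in ks:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
            sub = dist_full[np.ix_(idx, idx)]
            lab = pam_cluster(sub, k, rng)
            tog[np.ix_(idx, idx)] += 1
            same = lab[:, None] == lab[None, :]
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = 0.5 * (cons + cons.T)
        consensus[k] = cons
        hc = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average")
        lab_final = hc.fit_predict(1.0 - cons)
        labels[k] = pd.Series(
            [f"C{c + 1}" for c in lab_final], index=expr.columns, name="subtype", dtype=object
        )
        areas[k] = _cdf_area(cons)

    deltas = {}
    prev_area = None
    for k in ks:
        if prev_area is None:
            deltas[k] = areas[k]
        else:
            deltas[k] = (areas[k] - prev_area) / max(prev_area, 1e-12)
        prev_area = areas[k]
    drops = {
        k: deltas[k] - (deltas[ks[i + 1]] if i + 1 < len(ks) else 0.0)
        for i, k in enumerate(ks)
    }
    chosen = max(ks, key=lambda k: (drops[k], -k))
    return ConsensusResult(
        k_range=ks, consensus=consensus, labels=labels, cdf_area=areas,
        chosen_k=chosen, sample_ids=list(expr.columns),
    )


@dataclass
class SubtypeClassifier:
    """A trained subtype classifier over a frozen signature-gene panel.

    ``kind`` is "medoid" (per-cluster PAM centres + nearest-centre rule) or
    "mlp".  ``scale_mean``/``scale_sd`` are the per-gene z-scaling constants
    frozen from training and applied to any new cohort before classification.
    """

    kind: str
    genes: list[str]
    classes: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    medoids: np.ndarray | None = None  # (n_classes, n_genes), z-scaled
    mlp: MLPClassifier | None = None
    best_params: dict | None = None
    cv_accuracy: float | None = None
    n_grid_evaluated: int | None = None
    cv_table: pd.DataFrame | None = None


def _zscale_train(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = expr.to_numpy().T  # samples x genes
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd, mean, sd


def _zscale_apply(clf: SubtypeClassifier, expr: pd.DataFrame) -> np.ndarray:
    missing = sorted(set(clf.genes) - set(expr.index))
    if missing:
        raise KeyError(f"signature genes missing from new cohort: {missing}")
    X = expr.loc[clf.genes].to_numpy().T
    return (X - clf.scale_mean) / clf.scale_sd


def medoid_classifier_train(expr: pd.DataFrame, labels: pd.Series) -> SubtypeClassifier:
    """Per-cluster medoids on z-scaled training expression.

    The medoid of a cluster is the member sample minimizing the summed
    Euclidean distance to the rest of the cluster (PAM-consistent).
    """
    labels = labels.loc[expr.columns]
    classes = sorted(labels.unique())
    if any((labels == c).sum() == 0 for c in classes):
        raise ValueError("every class must be non-empty")
    Xz, mean, sd = _zscale_train(expr)
    medoids = np.zeros((len(classes), Xz.shape[1]))
    for i, c in enumerate(classes):
        members = np.where((labels == c).to_numpy())[0]
        sub = Xz[members]
        within = cdist(sub, sub).sum(axis=1)
        medoids[i] = sub[int(np.argmin(within))]
    return SubtypeClassifier(
        kind="medoid", genes=list(expr.index), classes=list(classes),
        scale_mean=mean, scale_sd=sd, medoids=medoids,
    )


def medoid_classify(clf: SubtypeClassifier, new_expr: pd.DataFrame) -> pd.Series:
    """Label new samples by the nearest training medoid (Euclidean, z-scaled).

    Distance ties break toward the lowest cluster index.
    """
    if clf.kind != "medoid":
        raise ValueError("classifier is not a medoid classifier")
    Xz = _zscale_apply(clf, new_expr)
    d = cdist(Xz, clf.medoids)
    idx = np.argmin(d, axis=1)  # argmin returns the first minimum: lowest index wins ties
    return pd.Series(
        [clf.classes[i] for i in idx], index=new_expr.columns, name="subtype", dtype=object
    )


def _make_mlp(params: dict, seed: int, max_iter: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=MLP_HIDDEN_LAYERS,
        activation=params["activation"],
        alpha=params["alpha"],
        solver=params["solver"],
        max_iter=max_iter,
        random_state=seed,
    )


def mlp_grid_search(
    expr: pd.DataFrame,
    labels: pd.Series,
    folds: int = 10,
    seed: int = 0,
    max_iter: int = 400,
) -> SubtypeClassifier:
    """Exhaustive 4x5x3 grid search for the three-hidden-layer MLP.

    Every combination of activation, L2 penalty and solver is scored by
    stratified ``folds``-fold cross-validated accuracy
    (N correct / N total); the best combination is refit on all data.
    Deterministic for a fixed seed (fold split and weight init both derive
    from it).  Classes with fewer than 2 members are warned about.
    """
    labels = labels.loc[expr.columns]
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    if (counts < 2).any():
        logger.warning("classes with <2 samples: %s", counts[counts < 2].index.tolist())
    Xz, mean, sd = _zscale_train(expr)
    y = labels.to_numpy()

    grid = list(ParameterGrid(MLP_PARAM_GRID))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xz, y))
    rows = []
    for params in grid:
        correct = 0
        total = 0
        for tr, te in splits:
            clf = _make_mlp(params, seed, max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xz[tr], y[tr])
            pred = clf.predict(Xz[te])
            correct += int((pred == y[te]).sum())
            total += len(te)
        rows.append({**params, "cv_accuracy": correct / total})
    table = pd.DataFrame(rows)
    best_idx = int(table["cv_accuracy"].to_numpy().argmax())
    best = grid[best_idx]

    final = _make_mlp(best, seed, max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xz, y)
    return SubtypeClassifier(
        kind="mlp", genes=list(expr.index), classes=list(classes),
        scale_mean=mean, scale_sd=sd, mlp=final, best_params=dict(best),
        cv_accuracy=float(table["cv_accuracy"].iloc[best_idx]),
        n_grid_evaluated=len(grid), cv_table=table,
    )


def mlp_classify(clf: SubtypeClassifier, new_expr: pd.DataFrame) -> pd.Series:
    if clf.kind != "mlp" or clf.mlp is None:
        raise ValueError("classifier is not a fitted MLP")
    Xz = _zscale_apply(clf, new_expr)
    return pd.Series(clf.mlp.predict(Xz), index=new_expr.columns, name="subtype", dtype=object)


def classify(clf: SubtypeClassifier, new_expr: pd.DataFrame) -> pd.Series:
    return medoid_classify(clf, new_expr) if clf.kind == "medoid" else mlp_classify(clf, new_expr)


def save_classifier(clf: SubtypeClassifier, path) -> None:
    """Serialize a trained classifier to JSON (weights stored as lists)."""
    import json

    payload = {
        "kind": clf.kind,
        "genes": clf.genes,
        "classes": clf.classes,
        "scale_mean": clf.scale_mean.tolist(),
        "scale_sd": clf.scale_sd.tolist(),
    }
    if clf.kind == "medoid":
        payload["medoids"] = clf.medoids.tolist()
    else:
        payload["best_params"] = clf.best_params
        payload["cv_accuracy"] = clf.cv_accuracy
        payload["coefs"] = [w.tolist() for w in clf.mlp.coefs_]
        payload["intercepts"] = [b.tolist() for b in clf.mlp.intercepts_]
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_classifier(path) -> SubtypeClassifier:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    clf = SubtypeClassifier(
        kind=payload["kind"],
        genes=payload["genes"],
        classes=payload["classes"],
        scale_mean=np.asarray(payload["scale_mean"], float),
        scale_sd=np.asarray(payload["scale_sd"], float),
    )
    if clf.kind == "medoid":
        clf.medoids = np.asarray(payload["medoids"], float)
        return clf
    clf.best_params = payload["best_params"]
    clf.cv_accuracy = payload.get("cv_accuracy")
    mlp = _make_mlp(payload["best_params"], seed=0, max_iter=1)
    # rebuild the fitted estimator: shape the internals, then restore weights
    n_features = len(clf.genes)
    X0 = np.zeros((len(clf.classes), n_features))
    y0 = np.array(clf.classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mlp.fit(X0, y0)
    mlp.coefs_ = [np.asarray(w, float) for w in payload["coefs"]]
    mlp.intercepts_ = [np.asarray(b, float) for b in payload["intercepts"]]
    clf.mlp = mlp
    return clf


def compare_classifiers(
    clf_medoid: SubtypeClassifier,
    clf_mlp: SubtypeClassifier,
    test_expr: pd.DataFrame,
    test_survival: pd.DataFrame,
) -> dict:
    """Pick the classifier whose predicted subtypes separate survival better.

    Each classifier labels the test cohort; a log-rank test across the
    predicted labels gives one p-value per classifier, and the smaller p wins
    (ties go to the first listed, the medoid rule).  A classifier that
    predicts a single class is reported as "not evaluable" rather than
    crashing.
    """
    report: dict = {}
    for name, clf in (("medoid", clf_medoid), ("mlp", clf_mlp)):
        pred = classify(clf, test_expr)
        common = pred.index.intersection(test_survival.index)
        groups = {
            c: test_survival.loc[common[pred.loc[common] == c]]
            for c in sorted(pred.loc[common].unique())
        }
        if len(groups) < 2:
            report[name] = {"p": None, "note": "not evaluable (single predicted class)"}
        else:
            chi2, p = logrank_test(groups)
            report[name] = {"p": p, "chi_square": chi2}
        report[f"{name}_labels"] = pred
    ps = [(name, report[name]["p"]) for name in ("medoid", "mlp")]
    evaluable = [(n, p) for n, p in ps if p is not None]
    if not evaluable:
        report["winner"] = None
    else:
        best = min(evaluable, key=lambda t: t[1])
        # ties (and single-evaluable cases) resolve in listed order
        report["winner"] = next(n for n, p in evaluable if p == best[1])
    return report
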
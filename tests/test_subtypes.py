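from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from pairsurv.simulate import SimulationConfig, simulate_cohort
from pairsurv.subtypes import (
    compare_classifiers,
    consensus_cluster,
    medoid_classifier_train,
    medoid_classify,
    mlp_classify,
    mlp_grid_search,
    pam_cluster,
)


def blob_frame(seed=0, n=60, centers=((0, 0), (6, 6), (0, 8)), sd=0.8):
    rng = np.random.default_rng(seed)
    k = len(centers)
    labels = np.repeat(np.arange(k), n // k)
    pts = np.array([centers[l] for l in labels]) + rng.normal(0, sd, size=(len(labels), 2))
    df = pd.DataFrame(
        pts.T, index=["gA", "gB"], columns=[f"s{i:03d}" for i in range(len(labels))]
    )
    return df, labels


class TestPam:
    def test_medoids_match_brute_force_on_small_instance(self):
        """PAM labels induce medoids equal to brute-force within-cluster minimizers."""
        df, truth = blob_frame(seed=4, n=45)
        X = df.to_numpy().T
        dist = squareform(pdist(X))
        labels = pam_cluster(dist, 3, np.random.default_rng(0))
        assert adjusted_rand_score(truth, labels) == 1.0
        for c in range(3):
            members = np.where(labels == c)[0]
            sums = dist[np.ix_(members, members)].sum(axis=1)
            med = members[np.argmin(sums)]
            # the brute-force medoid must not beat any other member
            assert dist[np.ix_([med], members)].sum() == pytest.approx(sums.min())

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            pam_cluster(np.zeros((3, 3)), 5, np.random.default_rng(0))


class TestConsensusCluster:
    @pytest.fixture(scope="class")
    def separated(self):
        cfg = SimulationConfig(
            n_samples=120, n_genes=60, n_signature_genes=40, subtype_separation=1.5,
            subtype_proportions=(1 / 3, 1 / 3, 1 / 3), seed=14,
        )
        c = simulate_cohort(cfg)
        return c, np.log(c.expression.loc[c.signature_genes])

    def test_matrix_symmetric_with_unit_diagonal(self, separated):
        _, expr = separated
        res = consensus_cluster(expr, k_range=(2, 3, 4), reps=30, seed=1)
        for k, m in res.consensus.items():
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 1.0)
            assert m.min() >= 0 and m.max() <= 1

    def test_recovers_planted_subtypes(self, separated):
        c, expr = separated
        res = consensus_cluster(expr, k_range=(2, 3, 4, 5, 6), reps=100, seed=2)
        assert res.chosen_k == 3
        assert adjusted_rand_score(c.true_subtype, res.labels[3]) >= 0.9

    def test_single_rep_consensus_is_binary_where_defined(self, separated):
        _, expr = separated
        res = consensus_cluster(expr, k_range=(3,), reps=1, subsample=1.0, seed=3)
        m = res.consensus[3]
        assert np.isin(m, (0.0, 1.0)).all()

    def test_duplicated_samples_get_identical_labels(self):
        df, _ = blob_frame(seed=8, n=30)
        dup = pd.concat([df, df.add_suffix("_dup", axis=1)], axis=1)
        res = consensus_cluster(dup, k_range=(3,), reps=60, seed=5)
        lab = res.labels[3]
        for s in df.columns:
            assert lab[s] == lab[s + "_dup"]

    def test_k_range_exceeding_samples_rejected(self):
        df, _ = blob_frame(n=6)
        with pytest.raises(ValueError):
            consensus_cluster(df.iloc[:, :5], k_range=(2, 6), reps=5, seed=0)


class TestMedoidClassifier:
    def test_training_medoids_classify_to_their_own_labels(self):
        df, truth = blob_frame(seed=2, n=45)
        labels = pd.Series([f"C{t+1}" for t in truth], index=df.columns, dtype=object)
        clf = medoid_classifier_train(df, labels)
        # the stored medoids are z-scaled training samples: classifying the
        # training cohort must reproduce the training labels on clean blobs
        pred = medoid_classify(clf, df)
        assert (pred == labels).all()

    def test_one_gene_toy_nearest_centre(self):
        expr = pd.DataFrame([[0.0, 0, 10, 10]], index=["g"], columns=list("abcd"))
        labels = pd.Series(["lo", "lo", "hi", "hi"], index=list("abcd"), dtype=object)
        clf = medoid_classifier_train(expr, labels)
        new = pd.DataFrame([[2.0]], index=["g"], columns=["x"])
        assert medoid_classify(clf, new)["x"] == "lo"

    def test_missing_signature_gene_rejected(self):
        df, truth = blob_frame(n=30)
        labels = pd.Series([f"C{t+1}" for t in truth], index=df.columns, dtype=object)
        clf = medoid_classifier_train(df, labels)
        with pytest.raises(KeyError, match="gB"):
            medoid_classify(clf, df.loc[["gA"]])

    def test_held_out_accuracy_exceeds_chance(self):
        cfg = SimulationConfig(
            n_samples=150, n_genes=50, n_signature_genes=30, subtype_separation=1.5,
            subtype_proportions=(1 / 3, 1 / 3, 1 / 3), seed=6, population_seed=606,
        )
        train = simulate_cohort(cfg)
        test = simulate_cohort(replace(cfg, seed=7))
        clf = medoid_classifier_train(
            np.log(train.expression.loc[train.signature_genes]), train.true_subtype
        )
        pred = medoid_classify(clf, np.log(test.expression.loc[test.signature_genes]))
        acc = (pred.to_numpy() == test.true_subtype.to_numpy()).mean()
        assert acc >= 0.8


class TestMlpGridSearch:
    @pytest.fixture(scope="class")
    def blobs(self):
        df, truth = blob_frame(seed=10, n=60)
        labels = pd.Series([f"C{t+1}" for t in truth], index=df.columns, dtype=object)
        return df, labels

    def test_grid_evaluates_exactly_sixty_combinations(self, blobs):
        df, labels = blobs
        clf = mlp_grid_search(df, labels, folds=2, seed=1, max_iter=40)
        assert clf.n_grid_evaluated == 60
        assert len(clf.cv_table) == 60

    def test_separable_blobs_reach_high_cv_accuracy(self, blobs):
        df, labels = blobs
        clf = mlp_grid_search(df, labels, folds=3, seed=2, max_iter=200)
        assert clf.cv_accuracy >= 0.95
        pred = mlp_classify(clf, df)
        assert (pred == labels).mean() >= 0.95

    def test_same_seed_reproduces_choice_and_weights(self, blobs):
        df, labels = blobs
        a = mlp_grid_search(df, labels, folds=2, seed=5, max_iter=40)
        b = mlp_grid_search(df, labels, folds=2, seed=5, max_iter=40)
        assert a.best_params == b.best_params
        pd.testing.assert_frame_equal(a.cv_table, b.cv_table)
        for wa, wb in zip(a.mlp.coefs_, b.mlp.coefs_):
            assert np.array_equal(wa, wb)


class TestCompareClassifiers:
    def test_identical_classifiers_tie_to_first_listed(self):
        df, truth = blob_frame(seed=12, n=45)
        labels = pd.Series([f"C{t+1}" for t in truth], index=df.columns, dtype=object)
        clf = medoid_classifier_train(df, labels)
        rng = np.random.default_rng(0)
        surv = pd.DataFrame(
            {"time": rng.exponential(10, 45), "event": 1}, index=df.columns
        )
        report = compare_classifiers(clf, clf, df, surv)
        assert report["medoid"]["p"] == report["mlp"]["p"]
        assert report["winner"] == "medoid"

    def test_single_class_prediction_is_not_evaluable(self):
        df, truth = blob_frame(seed=13, n=45)
        labels = pd.Series(["C1"] * 45, index=df.columns, dtype=object)
        labels.iloc[0] = "C2"  # two classes in training, but C2 unreachable
        clf = medoid_classifier_train(df.iloc[:, :], labels)
        far = df + 1000.0  # all samples land on the same side
        rng = np.random.default_rng(1)
        surv = pd.DataFrame({"time": rng.exponential(10, 45), "event": 1}, index=df.columns)
        report = compare_classifiers(clf, clf, far, surv)
        assert report["medoid"]["note"].startswith("not evaluable")
        assert report["winner"] is None


class TestClassifierSerialization:
    def test_medoid_round_trip_predictions_identical(self, tmp_path):
        df, truth = blob_frame(seed=21, n=45)
        labels = pd.Series([f"C{t+1}" for t in truth], index=df.columns, dtype=object)
        clf = medoid_classifier_train(df, labels)
        from pairsurv.subtypes import load_classifier, save_classifier

        save_classifier(clf, tmp_path / "clf.json")
        back = load_classifier(tmp_path / "clf.json")
        pd.testing.assert_series_equal(medoid_classify(clf, df), medoid_classify(back, df))

    def test_mlp_round_trip_predictions_identical(self, tmp_path):
        df, truth = blob_frame(seed=22, n=45)
        labels = pd.Series([f"C{t+1}" for t in truth], index=df.columns, dtype=object)
        clf = mlp_grid_search(df, labels, folds=2, seed=0, max_iter=60)
        from pairsurv.subtypes import load_classifier, save_classifier

        save_classifier(clf, tmp_path / "clf.json")
        back = load_classifier(tmp_path / "clf.json")
        pd.testing.assert_series_equal(mlp_classify(clf, df), mlp_classify(back, df))
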
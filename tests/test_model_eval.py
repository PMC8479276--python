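import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmda.features import FeatureTable
from tsmda.model_eval import (
    AssociationClassifier,
    ModelArtifact,
    blind_test,
    compute_metrics,
    cross_validate,
    rank_candidates,
    train_classifier,
)

FAST_XGB = {"n_estimators": 20, "max_depth": 3}


def brute_force_auc(labels, scores):
    """All positive-negative pair enumeration: wins + half ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _separable_table(rng, n=120):
    # the signal feature is exactly class-valued, so any split inside the
    # unit gap separates train and test alike
    y = rng.integers(0, 2, n)
    X = np.column_stack([y.astype(float), rng.random(n)])
    return FeatureTable(
        [(f"m{i}", "d0") for i in range(n)], X, ["signal", "noise"], y
    )


class TestComputeMetrics:
    def test_perfect_separation(self):
        rep = compute_metrics([1, 1, 0, 0], [1.0, 1.0, 0.0, 0.0])
        assert (rep.auc, rep.mcc, rep.bacc, rep.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_perfect_inversion(self):
        rep = compute_metrics([1, 1, 0, 0], [0.0, 0.0, 1.0, 1.0])
        assert rep.auc == 0.0
        assert rep.mcc == -1.0

    def test_four_sample_worked_example(self):
        rep = compute_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert rep.auc == pytest.approx(0.75)
        assert rep.mcc == pytest.approx(0.0)
        assert rep.bacc == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics([1, 1, 1], [0.5, 0.6, 0.7])

    def test_auc_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            rep = compute_metrics(labels, scores)
            assert rep.auc == pytest.approx(brute_force_auc(labels, scores))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(
            # scores on a 1/64 grid so the reflection 1-s is exact and
            # tie structure is preserved; 32/64 = 0.5 sits on the threshold
            # and is excluded
            st.tuples(st.integers(0, 1), st.integers(1, 63).filter(lambda k: k != 32)),
            min_size=4,
            max_size=30,
        )
    )
    def test_mcc_label_score_swap_symmetry(self, pairs):
        labels = np.array([l for l, _ in pairs])
        scores = np.array([k / 64 for _, k in pairs])
        if len(np.unique(labels)) < 2:
            return
        a = compute_metrics(labels, scores)
        b = compute_metrics(1 - labels, 1 - scores, threshold=0.5)
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)


class TestClassifier:
    def test_separable_training_auc_one(self, rng):
        table = _separable_table(rng)
        art = train_classifier(table, FAST_XGB, seed=0)
        scores = art.classifier.score_pairs(table)
        assert compute_metrics(table.labels, scores).auc == 1.0

    def test_same_seed_identical_predictions(self, rng):
        table = _separable_table(rng)
        s1 = train_classifier(table, FAST_XGB, seed=5).classifier.score_pairs(table)
        s2 = train_classifier(table, FAST_XGB, seed=5).classifier.score_pairs(table)
        np.testing.assert_array_equal(s1, s2)

    def test_feature_name_contract(self, rng):
        table = _separable_table(rng)
        art = train_classifier(table, FAST_XGB, seed=0)
        permuted = table.select_columns(["noise", "signal"])
        with pytest.raises(ValueError, match="feature names"):
            art.classifier.predict_proba(permuted.matrix, permuted.feature_names)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError):
            AssociationClassifier().fit(X, np.ones(10))

    def test_artifact_round_trip(self, rng, tmp_path):
        table = _separable_table(rng)
        art = train_classifier(table, FAST_XGB, seed=0)
        art.save(tmp_path / "model")
        loaded = ModelArtifact.load(tmp_path / "model")
        np.testing.assert_allclose(
            loaded.classifier.score_pairs(table), art.classifier.score_pairs(table)
        )
        assert loaded.feature_names == art.feature_names


class TestCrossValidate:
    def test_separable_mean_auc_one_sd_zero(self, rng):
        rep = cross_validate(_separable_table(rng), k=5, seed=0, params=FAST_XGB)
        mean, sd = rep.metrics.mean_sd["auc"]
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)
        assert rep.scheme == "cv5"

    def test_confusion_counts_cover_all_samples(self, rng):
        table = _separable_table(rng)
        rep = cross_validate(table, k=5, seed=0, params=FAST_XGB)
        assert sum(rep.confusion.values()) == len(table)

    def test_permuted_labels_auc_near_half(self, rng):
        table = _separable_table(rng, n=150)
        aucs = []
        for rep_i in range(10):
            permuted = table.with_labels(
                np.random.default_rng(rep_i).permutation(table.labels)
            )
            rep = cross_validate(permuted, k=5, seed=rep_i, params=FAST_XGB)
            aucs.append(rep.metrics.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_k_exceeding_class_count_errors(self, rng):
        table = _separable_table(rng, n=8)
        with pytest.raises(ValueError, match="k="):
            cross_validate(table, k=20, seed=0)


class TestBlindTest:
    def test_separable_holdout_auc_one(self, rng):
        rep = blind_test(_separable_table(rng), 0.2, seed=0, params=FAST_XGB)
        assert rep.metrics.auc == pytest.approx(1.0)
        assert rep.scheme == "blind"
        assert rep.n_samples == 24

    def test_same_seed_identical_report(self, rng):
        table = _separable_table(rng)
        a = blind_test(table, 0.2, seed=3, params=FAST_XGB)
        b = blind_test(table, 0.2, seed=3, params=FAST_XGB)
        assert a.to_frame().equals(b.to_frame())

    def test_bad_fraction(self, rng):
        with pytest.raises(ValueError):
            blind_test(_separable_table(rng), 1.5, seed=0)


class TestRankCandidates:
    def _model_and_candidates(self, rng):
        table = _separable_table(rng)
        art = train_classifier(table, FAST_XGB, seed=0)
        n = 6
        X = np.column_stack([np.linspace(1, 0, n), rng.random(n)])
        cands = FeatureTable(
            [(f"c{i}", "dX") for i in range(n)], X, ["signal", "noise"]
        )
        return art, cands

    def test_top_k_sorted_and_ranked(self, rng):
        art, cands = self._model_and_candidates(rng)
        table = rank_candidates(art, "dX", cands, k=3)
        assert [r[3] for r in table.rows] == [1, 2, 3]
        scores = [r[2] for r in table.rows]
        assert scores == sorted(scores, reverse=True)

    def test_k_larger_than_pool_warns_and_returns_all(self, rng, caplog):
        art, cands = self._model_and_candidates(rng)
        with caplog.at_level("WARNING"):
            table = rank_candidates(art, "dX", cands, k=100)
        assert len(table.rows) == 6
        assert any("returning all" in r.message for r in caplog.records)

    def test_unknown_disease_errors(self, rng):
        art, cands = self._model_and_candidates(rng)
        with pytest.raises(ValueError, match="dZ"):
            rank_candidates(art, "dZ", cands, k=3)
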
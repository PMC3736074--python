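from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

from healthtopics import synth
from healthtopics.evaluation import (
    compute_metrics,
    confusion_matrix,
    cross_validate,
    paired_t_test,
    repeated_cv,
    sweep_frequency_threshold,
)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        assert cm.counts.tolist() == [[2, 0], [0, 1]]

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([], [], ["a", "b"])
        assert cm.counts.sum() == 0

    def test_hand_tallied_pairs(self):
        pairs = [
            ("t", "t"), ("t", "t"), ("t", "e"), ("t", "s"), ("t", "t"),
            ("e", "e"), ("e", "e"), ("e", "t"), ("e", "e"), ("e", "s"),
            ("s", "s"), ("s", "s"), ("s", "s"), ("s", "t"), ("s", "s"),
            ("s", "s"), ("t", "t"), ("e", "e"), ("s", "e"), ("t", "t"),
        ]
        true, pred = zip(*pairs)
        cm = confusion_matrix(true, pred, ["t", "e", "s"])
        # manual tally: rows true t/e/s, cols predicted t/e/s
        assert cm.counts.tolist() == [[5, 1, 1], [1, 4, 1], [1, 1, 5]]
        assert cm.total == 20

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in class order"):
            confusion_matrix(["a"], ["z"], ["a", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["a", "b"], ["a", "b"])


class TestMetrics:
    def test_diagonal_matrix_gives_all_ones(self):
        cm = confusion_matrix(["a"] * 3 + ["b"] * 2, ["a"] * 3 + ["b"] * 2, ["a", "b"])
        m = compute_metrics(cm)
        assert m["accuracy"] == 1.0
        assert m["macro"] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_three_class_hand_computed_oracle(self):
        """Counts [[5,1,0],[1,3,2],[0,1,7]]: metrics computed by hand with
        exact fractions."""
        cm = confusion_matrix(
            ["a"] * 6 + ["b"] * 6 + ["c"] * 8,
            ["a"] * 5 + ["b"] + ["a"] + ["b"] * 3 + ["c"] * 2 + ["b"] + ["c"] * 7,
            ["a", "b", "c"],
        )
        assert cm.counts.tolist() == [[5, 1, 0], [1, 3, 2], [0, 1, 7]]
        m = compute_metrics(cm)
        assert m["accuracy"] == pytest.approx(15 / 20)
        assert m["per_class"]["a"]["precision"] == pytest.approx(float(Fraction(5, 6)))
        assert m["per_class"]["a"]["recall"] == pytest.approx(float(Fraction(5, 6)))
        assert m["per_class"]["a"]["f1"] == pytest.approx(float(Fraction(5, 6)))
        assert m["per_class"]["b"]["precision"] == pytest.approx(float(Fraction(3, 5)))
        assert m["per_class"]["b"]["recall"] == pytest.approx(float(Fraction(1, 2)))
        assert m["per_class"]["b"]["f1"] == pytest.approx(float(Fraction(6, 11)))
        assert m["per_class"]["c"]["precision"] == pytest.approx(float(Fraction(7, 9)))
        assert m["per_class"]["c"]["recall"] == pytest.approx(float(Fraction(7, 8)))
        assert m["per_class"]["c"]["f1"] == pytest.approx(float(Fraction(98, 119)))
        assert m["macro"]["precision"] == pytest.approx(
            float((Fraction(5, 6) + Fraction(3, 5) + Fraction(7, 9)) / 3)
        )

    def test_class_never_predicted_nor_true_gets_zeros(self):
        cm = confusion_matrix(["a", "a"], ["a", "a"], ["a", "ghost"])
        m = compute_metrics(cm)
        assert m["per_class"]["ghost"] == {"precision": 0.0, "recall": 0.0, "f1": 0.0}

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(confusion_matrix([], [], ["a"]))

    def test_micro_identity_on_random_matrices(self, rng):
        """Pooled accuracy equals the class-size-weighted mean of per-class
        recall."""
        for _ in range(50):
            m = int(rng.integers(2, 5))
            counts = rng.integers(0, 20, size=(m, m))
            if counts.sum() == 0:
                continue
            classes = [f"c{i}" for i in range(m)]
            true, pred = [], []
            for i in range(m):
                for j in range(m):
                    true += [classes[i]] * counts[i, j]
                    pred += [classes[j]] * counts[i, j]
            metrics = compute_metrics(confusion_matrix(true, pred, classes))
            weights = counts.sum(axis=1) / counts.sum()
            weighted_recall = sum(
                w * metrics["per_class"][c]["recall"] for w, c in zip(weights, classes)
            )
            assert metrics["accuracy"] == pytest.approx(weighted_recall, abs=1e-12)
            # per-class F is the harmonic mean of its P and R
            for c in classes:
                p, r = metrics["per_class"][c]["precision"], metrics["per_class"][c]["recall"]
                expect = 2 * p * r / (p + r) if p + r else 0.0
                assert metrics["per_class"][c]["f1"] == pytest.approx(expect, abs=1e-12)


class TestPairedTTest:
    def test_identical_vectors_degenerate_convention(self):
        assert paired_t_test([0.8, 0.9], [0.8, 0.9]) == (0.0, 0.5)

    def test_hand_computed_example(self):
        """d = [.04,.03,.05]: t = .04/(.01/sqrt(3)) = 4 sqrt(3)."""
        t, p = paired_t_test([0.80, 0.82, 0.81], [0.84, 0.85, 0.86])
        assert t == pytest.approx(4 * np.sqrt(3), abs=1e-12)
        assert p == pytest.approx(float(scipy.stats.t.sf(4 * np.sqrt(3), df=2)), abs=1e-12)

    def test_antisymmetry(self):
        a, b = [0.1, 0.3, 0.2, 0.5], [0.2, 0.4, 0.25, 0.55]
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(1 - p1)

    def test_zero_spread_nonzero_mean_sentinel(self):
        # binary-exact values so the differences are exactly equal
        t, p = paired_t_test([0.25, 0.5], [0.5, 0.75])
        assert t == float("inf") and p == 0.0
        t, p = paired_t_test([0.5, 0.75], [0.25, 0.5])
        assert t == float("-inf") and p == 1.0

    def test_agrees_with_reference_implementation(self, rng):
        """50 random vector pairs vs scipy's paired t-test to 1e-9."""
        for _ in range(50):
            n = int(rng.integers(3, 15))
            a = rng.random(n)
            b = a + rng.normal(0, 0.05, size=n)
            t, p = paired_t_test(a, b)
            ref = scipy.stats.ttest_rel(b, a, alternative="greater")
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [1.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])


@pytest.fixture(scope="module")
def small_corpus():
    cfg = synth.strong_signature_config(n_messages=300, seed=42)
    corpus, _ = synth.generate_corpus(cfg)
    return cfg, corpus


class TestCrossValidate:
    def test_folds_partition_the_corpus(self, small_corpus):
        _, corpus = small_corpus
        report = cross_validate(corpus, recipe="FS1", classifier_kind="naive_bayes", k=10, seed=1)
        seen = sorted(i for fold in report.per_fold for i in fold["test_indices"])
        assert seen == list(range(len(corpus)))

    def test_stratified_per_class_fold_counts_differ_by_at_most_one(self, small_corpus):
        _, corpus = small_corpus
        report = cross_validate(corpus, recipe="FS1", classifier_kind="naive_bayes", k=10, seed=1)
        labels = corpus.labels
        for lab in corpus.label_set:
            per_fold = [
                sum(1 for i in fold["test_indices"] if labels[i] == lab)
                for fold in report.per_fold
            ]
            assert max(per_fold) - min(per_fold) <= 1

    def test_same_seed_identical_report_different_seed_different_folds(self, small_corpus):
        _, corpus = small_corpus
        r1 = cross_validate(corpus, recipe="FS1", classifier_kind="naive_bayes", k=10, seed=5)
        r2 = cross_validate(corpus, recipe="FS1", classifier_kind="naive_bayes", k=10, seed=5)
        r3 = cross_validate(corpus, recipe="FS1", classifier_kind="naive_bayes", k=10, seed=6)
        assert r1.to_dict() == r2.to_dict()
        assert r1.per_fold[0]["test_indices"] != r3.per_fold[0]["test_indices"]

    def test_class_smaller_than_k_rejected_naming_the_class(self, small_corpus):
        _, corpus = small_corpus
        tiny = corpus.subset(range(12))
        with pytest.raises(ValueError, match="fewer than k"):
            cross_validate(tiny, recipe="FS1", classifier_kind="naive_bayes", k=10)

    def test_unlabeled_corpus_rejected(self):
        from healthtopics.corpus import LabeledCorpus, Message

        corpus = LabeledCorpus.from_messages(
            [Message(f"m{i}", "x y z", None) for i in range(20)]
        )
        with pytest.raises(ValueError, match="labeled"):
            cross_validate(corpus, recipe="FS1", classifier_kind="naive_bayes", k=2)

    def test_accuracy_tracks_bayes_optimal_on_strong_signal(self, small_corpus):
        cfg, corpus = small_corpus
        report = cross_validate(corpus, recipe="FS1", classifier_kind="naive_bayes", k=10, seed=1)
        bayes, se = synth.bayes_optimal_accuracy(cfg, n_mc=500, seed=9)
        assert abs(report.accuracy - bayes) <= 0.03 + 3 * se


class TestRepeatedCVAndSweep:
    def test_identical_configs_give_identical_vectors(self, small_corpus):
        _, corpus = small_corpus
        cfg = {"recipe": "FS1", "classifier_kind": "naive_bayes"}
        res = repeated_cv(corpus, [cfg, dict(cfg)], repetitions=3, seed=2)
        assert res["results"][0]["accuracy"] == res["results"][1]["accuracy"]
        assert res["results"][0]["macro_f"] == res["results"][1]["macro_f"]
        assert len(res["results"][0]["accuracy"]) == 3

    def test_domain_features_beat_ngrams_when_they_carry_the_signal(self):
        cfg = synth.domain_signal_config(n_messages=400, seed=3)
        corpus, _ = synth.generate_corpus(cfg)
        dom, _ = synth.generate_lexicons(cfg)
        res = repeated_cv(
            corpus,
            [
                {"recipe": "FS1", "classifier_kind": "naive_bayes"},
                {"recipe": "FS2", "classifier_kind": "naive_bayes"},
            ],
            repetitions=3,
            seed=4,
            domain_lexicon=dom,
        )
        assert np.mean(res["results"][1]["accuracy"]) > np.mean(res["results"][0]["accuracy"])

    def test_sweep_output_shape_and_degenerate_threshold(self, small_corpus):
        _, corpus = small_corpus
        rows = sweep_frequency_threshold(
            corpus, [5, 10**9], classifier_kind="naive_bayes", k=10, seed=1
        )
        assert [r["threshold"] for r in rows] == [5, 10**9]
        # astronomically large threshold empties FS1: majority-class behaviour
        from collections import Counter

        majority_share = max(Counter(corpus.labels).values()) / len(corpus)
        assert rows[1]["accuracy"] == pytest.approx(majority_share, abs=0.02)
        assert rows[0]["accuracy"] >= rows[1]["accuracy"]

    def test_sweep_requires_thresholds(self, small_corpus):
        _, corpus = small_corpus
        with pytest.raises(ValueError):
            sweep_frequency_threshold(corpus, [], classifier_kind="naive_bayes")
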
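"""Bags, tf-idf weighting, histogram distances, and the four classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

import symhar as sh
from symhar.classifiers import (
    make_bigrams,
    train_linear_classifier,
    weasel_featurize,
    weasel_transform,
)
from symhar.data_model import Histogram, SymbolicWord, WordSequence


def _seq(letter_list, tag="x"):
    return WordSequence([SymbolicWord(lt, i, tag) for i, lt in enumerate(letter_list)])


class TestClassBags:
    def test_counts_are_conserved_per_class(self):
        bags = sh.build_class_bags(
            [(_seq(["aa", "ab", "aa"]), "walk"), (_seq(["ba", "bb"]), "run")], reduce=False
        )
        assert bags["walk"].total() == 3 and bags["run"].total() == 2

    def test_doubling_input_doubles_counts(self):
        seqs = [(_seq(["aa", "ab"]), "walk")]
        once = sh.build_class_bags(seqs, reduce=False)
        twice = sh.build_class_bags(seqs * 2, reduce=False)
        assert {w: 2 * n for w, n in once["walk"].counts.items()} == twice["walk"].counts

    def test_reduction_collapses_runs_first(self):
        bags = sh.build_class_bags([(_seq(["aa", "aa", "ab"]), "walk")], reduce=True)
        assert bags["walk"].counts == {"x:aa": 1, "x:ab": 1}


class TestTfIdf:
    def test_tf_zero_branch(self):
        assert sh.tf_weight(0) == 0.0

    def test_tf_base10_value(self):
        assert sh.tf_weight(9) == pytest.approx(1.0)

    def test_tf_monotone(self):
        values = [sh.tf_weight(f) for f in range(0, 20)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_idf_word_everywhere_is_zero(self):
        bags = {c: Histogram({"x:aa": 1}) for c in range(4)}
        assert sh.idf_weight("x:aa", bags) == 0.0

    def test_idf_rare_word(self):
        bags = {0: Histogram({"x:aa": 1})}
        bags.update({c: Histogram({"x:bb": 1}) for c in range(1, 10)})
        assert sh.idf_weight("x:aa", bags) == pytest.approx(1.0)

    def test_absent_word_has_weight_exactly_zero(self):
        bags = {
            "Activity 1": Histogram({"x:accbb": 2, "x:cdaaa": 9}),
            "Activity 2": Histogram({"x:ddbca": 1}),
        }
        wm = sh.tfidf_matrix(bags)
        j = wm.vocabulary.index("x:accbb")
        assert wm.row("Activity 2")[j] == 0.0
        assert wm.row("Activity 1")[j] > 0.0

    def test_word_in_every_class_zeroes_its_column(self):
        bags = {
            "a": Histogram({"x:aa": 3, "x:ab": 1}),
            "b": Histogram({"x:aa": 5, "x:ba": 2}),
        }
        wm = sh.tfidf_matrix(bags)
        np.testing.assert_array_equal(wm.weights[:, wm.vocabulary.index("x:aa")], 0.0)

    def test_disjoint_vocabularies_give_block_pattern(self):
        bags = {"a": Histogram({"x:aa": 1, "x:ab": 1}), "b": Histogram({"x:ba": 1, "x:bb": 1})}
        wm = sh.tfidf_matrix(bags)
        for j, word in enumerate(wm.vocabulary):
            owner = "a" if word in ("x:aa", "x:ab") else "b"
            assert wm.row(owner)[j] > 0
            other = "b" if owner == "a" else "a"
            assert wm.row(other)[j] == 0.0


class TestCosine:
    def test_identical_nonzero_vectors(self):
        assert sh.cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert sh.cosine_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_closed_form(self):
        assert sh.cosine_similarity([1.0, 1.0], [1.0, 0.0]) == pytest.approx(0.7071068)

    def test_both_zero_raises(self):
        with pytest.raises(sh.NoEvidenceError):
            sh.cosine_similarity([0.0], [0.0])


def _vsm_from_bags(bags):
    wm = sh.tfidf_matrix(bags)
    idf = {w: sh.idf_weight(w, bags) for w in wm.vocabulary}
    from symhar.classifiers import VSMModel

    return VSMModel(weight_matrix=wm, idf_table=idf, class_priors={c: 1 for c in bags})


class TestClassifyVSM:
    def test_query_equal_to_training_bag(self):
        bags = {"A": Histogram({"x:ab": 3}), "B": Histogram({"x:cd": 3})}
        model = _vsm_from_bags(bags)
        assert sh.classify_vsm([SymbolicWord("ab", 0)], model) == "A"

    def test_unseen_words_signal_no_evidence(self):
        model = _vsm_from_bags({"A": Histogram({"x:ab": 3}), "B": Histogram({"x:cd": 3})})
        with pytest.raises(sh.NoEvidenceError):
            sh.classify_vsm([SymbolicWord("zz", 0)], model)

    def test_fallback_returns_most_frequent_class(self):
        model = _vsm_from_bags({"A": Histogram({"x:ab": 3}), "B": Histogram({"x:cd": 3})})
        model.class_priors = {"A": 1, "B": 5}
        label = sh.classify_vsm([SymbolicWord("zz", 0)], model, on_no_evidence="fallback")
        assert label == "B"


class TestBossDistance:
    def test_equal_histograms(self):
        h = Histogram({"a": 2, "b": 1})
        assert sh.boss_distance(h, h) == 0.0

    def test_missing_word_squared(self):
        assert sh.boss_distance(Histogram({"a": 2}), Histogram()) == 4.0

    def test_asymmetry_is_formula_forced(self):
        h1, h2 = Histogram({"a": 1, "b": 2}), Histogram({"b": 2, "c": 5})
        assert sh.boss_distance(h1, h2) == 1.0
        assert sh.boss_distance(h2, h1) == 25.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32))
    def test_matches_exhaustive_per_word_loop(self, seed):
        rng = np.random.default_rng(seed)
        words = [f"w{i}" for i in range(12)]
        h1 = Histogram({w: int(n) for w, n in zip(words, rng.integers(0, 6, 12)) if n > 0})
        h2 = Histogram({w: int(n) for w, n in zip(words, rng.integers(0, 6, 12)) if n > 0})
        oracle = 0.0
        for w in words:
            if h1.get(w) > 0:
                oracle += (h1.get(w) - h2.get(w)) ** 2
        assert sh.boss_distance(h1, h2) == pytest.approx(oracle)


class TestBoss1NN:
    def test_exact_match_wins(self):
        from symhar.classifiers import BOSSModel

        hists = [Histogram({"a": 1}), Histogram({"b": 4})]
        model = BOSSModel(histograms=hists, labels=["walk", "run"])
        assert sh.classify_boss_1nn(Histogram({"b": 4}), model) == "run"

    def test_single_class_model(self):
        from symhar.classifiers import BOSSModel

        model = BOSSModel(histograms=[Histogram({"a": 1})], labels=["sit"])
        assert sh.classify_boss_1nn(Histogram({"zz": 9}), model) == "sit"

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32))
    def test_matches_brute_force_search(self, seed):
        from symhar.classifiers import BOSSModel

        rng = np.random.default_rng(seed)
        words = [f"w{i}" for i in range(6)]
        hists = [
            Histogram({w: int(n) for w, n in zip(words, rng.integers(0, 5, 6)) if n > 0} or {"w0": 1})
            for _ in range(10)
        ]
        labels = [f"c{i % 3}" for i in range(10)]
        model = BOSSModel(histograms=hists, labels=labels)
        query = Histogram({w: int(n) for w, n in zip(words, rng.integers(0, 5, 6)) if n > 0} or {"w1": 1})
        dists = [sh.boss_distance(query, h) for h in hists]
        assert sh.classify_boss_1nn(query, model) == labels[int(np.argmin(dists))]


class TestWeaselFeatures:
    def test_bigrams_pair_nonoverlapping_neighbors(self):
        assert make_bigrams(["aab", "abc", "acc", "aaa"]) == ["aab abc", "acc aaa"]

    def test_odd_trailing_word_is_dropped(self):
        assert make_bigrams(["aa", "bb", "cc"]) == ["aa bb"]

    def test_uninformative_feature_is_masked(self):
        words = [{(8, "x"): ["aa", "bb"]} for _ in range(20)]
        for i, w in enumerate(words):
            if i % 2:  # class-specific word plus the shared ones
                w[(8, "x")] = w[(8, "x")] + ["zz"]
        labels = ["A", "B"] * 10
        features, _ = weasel_featurize(words, labels, chi2_threshold=0.5)
        kept = features.kept_vocabulary
        assert all("aa" not in k and "bb" not in k for k in kept)
        assert any(":zz" in k for k in kept)

    def test_class_exclusive_feature_statistic_matches_hand_value(self):
        # 50 balanced instances; one count of the word in every class-A instance.
        # Observed per-class counts (25, 0) vs expected (12.5, 12.5) -> chi2 = 25.
        words = []
        labels = []
        for i in range(50):
            label = "A" if i < 25 else "B"
            toks = ["mm"] + (["ww"] if label == "A" else [])
            words.append({(8, "x"): toks})
            labels.append(label)
        features, _ = weasel_featurize(words, labels, chi2_threshold=2.0)
        j = features.vocabulary.index("u:8:x:ww")
        assert features.chi2_scores[j] == pytest.approx(25.0)
        assert features.keep_mask[j]

    def test_transform_applies_fitted_mask(self):
        words = [{(8, "x"): ["aa", "zz"] if i % 2 else ["aa"]} for i in range(20)]
        labels = ["A", "B"] * 10
        features, train = weasel_featurize(words, labels, chi2_threshold=0.5)
        test = weasel_transform(words[:2], features)
        assert test.shape[1] == train.shape[1] == len(features.kept_vocabulary)


class TestLinearClassifier:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X = sparse.csr_matrix(np.array([[0.0], [0.0], [5.0], [6.0]]))
        y = ["A", "A", "B", "B"]
        model = train_linear_classifier(X, y, seed=0)
        assert list(model.predict(X)) == y

    def test_same_seed_is_deterministic(self, rng):
        X = sparse.csr_matrix(rng.normal(size=(30, 5)))
        y = list(rng.choice(["A", "B"], size=30))
        p1 = train_linear_classifier(X, y, seed=3).predict(X)
        p2 = train_linear_classifier(X, y, seed=3).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_informative_feature_dominates_weights(self, rng):
        y = np.array(["A"] * 20 + ["B"] * 20)
        informative = np.where(y == "A", -1.0, 1.0) + rng.normal(0, 0.1, 40)
        X = sparse.csr_matrix(np.column_stack([rng.normal(size=(40, 3)), informative]))
        model = train_linear_classifier(X, list(y), seed=0)
        weights = np.abs(model.coef_).ravel()
        assert weights[3] == weights.max()

    def test_single_class_rejected(self):
        with pytest.raises(sh.ParameterError):
            train_linear_classifier(sparse.csr_matrix(np.zeros((3, 1))), ["A"] * 3)


class TestEndToEndToys:
    def _toy_instances(self, rng, phase_consistent=False):
        # two classes with disjoint spectral content -> disjoint vocabularies
        t = np.arange(200)
        instances, labels = [], []
        for i in range(12):
            f = 2 if i % 2 == 0 else 7
            phase = np.pi / 4 + rng.normal(0, 0.2) if phase_consistent else rng.uniform(0, 6.28)
            sig = np.sin(2 * np.pi * f * t / 50 + phase)
            instances.append({"x": sig + rng.normal(0, 0.02, 200)})
            labels.append("lo" if f == 2 else "hi")
        return instances, labels

    @pytest.mark.parametrize("cls", [sh.SAXVSM, sh.BOSS, sh.BOSSVS])
    def test_training_set_accuracy_is_perfect(self, cls, rng):
        instances, labels = self._toy_instances(rng)
        clf = cls(window_samples=50)
        clf.fit(instances, labels)
        assert clf.predict(instances) == labels

    def test_weasel_learns_the_toy(self, rng):
        # phase-consistent so the mean-based ANOVA column selection applies
        instances, labels = self._toy_instances(rng, phase_consistent=True)
        clf = sh.WEASEL(window_sizes=(50,), word_length=6, seed=0)
        clf.fit(instances, labels)
        assert clf.predict(instances) == labels
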
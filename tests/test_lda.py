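import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from forumtopics.corpus import ForumCorpus, ForumDocument
from forumtopics.lda import (FileFeatureSet, LdaConfig, TopicModelState,
                             corpus_log_likelihood, export_top_pairs,
                             extract_file_feature_set, extract_topic_keys,
                             fit_lda, minka_fixed_point, optimize_alpha)
from forumtopics.preprocess import (BagOfWordsCorpus, Vocabulary,
                                    vectorize_corpus)
from forumtopics.synthetic import (align_topic_words, assignment_purity,
                                   match_topics)


def _bow(docs, terms):
    vocab = Vocabulary.from_terms(terms)
    return BagOfWordsCorpus(vocabulary=vocab,
                            docs=tuple(tuple(d) for d in docs),
                            doc_ids=tuple(f"F{i}" for i in range(len(docs))))


def _state_from_counts(n_wk, n_dk, alpha, beta, terms):
    """Build a consistent state directly from count matrices (tokens laid
    out deterministically)."""
    n_wk = np.asarray(n_wk, dtype=np.int64)
    n_dk = np.asarray(n_dk, dtype=np.int64)
    token_doc, token_word, z = [], [], []
    remaining = n_wk.copy()
    for d in range(n_dk.shape[0]):
        for k in range(n_dk.shape[1]):
            need = n_dk[d, k]
            w = 0
            while need > 0:
                take = min(need, remaining[w, k])
                for _ in range(take):
                    token_doc.append(d)
                    token_word.append(w)
                    z.append(k)
                remaining[w, k] -= take
                need -= take
                w += 1
    return TopicModelState(
        token_doc=np.array(token_doc, dtype=np.int32),
        token_word=np.array(token_word, dtype=np.int32),
        assignments=np.array(z, dtype=np.int32),
        n_wk=n_wk, n_dk=n_dk, n_k=n_wk.sum(axis=0),
        alpha=np.asarray(alpha, dtype=np.float64), beta=beta,
        vocabulary=Vocabulary.from_terms(terms),
        doc_ids=tuple(f"F{i}" for i in range(n_dk.shape[0])))


class TestSampler:
    def test_single_word_vocabulary_runs_and_rows_sum_to_one(self):
        bow = _bow([[0, 0, 0], [0, 0]], ["only"])
        state = fit_lda(bow, LdaConfig(K=2, n_iterations=20, seed=5,
                                       optimize_alpha_every=0))
        feats = extract_file_feature_set(state)
        assert np.allclose(feats.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert state.counts_consistent()

    def test_same_seed_gives_identical_assignments(self, two_topic_setup):
        _, _, _, bow, state = two_topic_setup
        again = fit_lda(bow, LdaConfig(K=2, n_iterations=500,
                                       optimize_alpha_every=50, burn_in=100,
                                       seed=11))
        assert np.array_equal(state.assignments, again.assignments)
        assert np.allclose(state.alpha, again.alpha)

    def test_different_seed_changes_assignments(self, two_topic_setup):
        _, _, _, bow, state = two_topic_setup
        other = fit_lda(bow, LdaConfig(K=2, n_iterations=50, seed=99))
        assert not np.array_equal(state.assignments, other.assignments)

    def test_counts_consistent_after_fit(self, two_topic_setup):
        _, _, _, _, state = two_topic_setup
        assert state.counts_consistent()
        assert state.n_k.sum() == state.assignments.size

    def test_two_topic_recovery_purity_and_tv(self, two_topic_setup):
        cfg, corpus, truth, bow, state = two_topic_setup
        phi = align_topic_words(state.topic_word_distributions(),
                                state.vocabulary, cfg.V)
        mapping, tv = match_topics(phi, truth.topic_word)
        assert tv.max() <= 0.15
        est_z = []
        pos = 0
        for doc in bow.docs:
            est_z.append(state.assignments[pos:pos + len(doc)])
            pos += len(doc)
        purity = assignment_purity(est_z, truth.token_topics, mapping)
        assert purity >= 0.95

    def test_k_larger_than_token_count_rejected(self):
        bow = _bow([[0], [1]], ["aa", "bb"])
        with pytest.raises(ValueError):
            fit_lda(bow, LdaConfig(K=3, n_iterations=5, seed=0))

    def test_log_likelihood_trend_non_decreasing_moving_average(
            self, two_topic_setup):
        _, _, _, bow, _ = two_topic_setup
        state = fit_lda(bow, LdaConfig(K=2, n_iterations=120, seed=3,
                                       optimize_alpha_every=0),
                        log_likelihood_every=2)
        ll = np.array([v for _, v in state.log_likelihood_history])
        w = 25  # sweeps 50..100 vs first 50: burn-in average must rise
        assert ll[-w:].mean() >= ll[:w].mean()


class TestAlphaOptimization:
    def test_symmetric_counts_give_equal_alpha(self):
        n_dk = np.full((6, 3), 7)
        alpha = minka_fixed_point(n_dk, np.array([0.5, 0.5, 0.5]))
        assert np.max(np.abs(alpha - alpha[0])) < 1e-9

    def test_concentrated_counts_grow_first_component(self):
        n_dk = np.zeros((8, 3), dtype=int)
        n_dk[:, 0] = 20
        a0 = np.array([1.0, 1.0, 1.0])
        a1 = minka_fixed_point(n_dk, a0, max_iter=1)
        a2 = minka_fixed_point(n_dk, a1, max_iter=1)
        assert a1[0] > a0[0] and a2[0] > a1[0]
        assert a2[1] <= a1[1] < a0[1]
        final = minka_fixed_point(n_dk, a0)
        assert final[1] == pytest.approx(1e-6)   # unused topics hit floor

    def test_fixed_point_matches_numeric_mle(self, rng):
        # brute-force oracle: maximize the Dirichlet-multinomial
        # log-likelihood numerically over log(alpha)
        n_dk = rng.integers(0, 12, size=(5, 3)).astype(float)
        n_dk[0, 0] += 3  # ensure some asymmetry
        lengths = n_dk.sum(axis=1)

        def negll(log_a):
            a = np.exp(log_a)
            a0 = a.sum()
            return -(len(n_dk) * gammaln(a0) - gammaln(lengths + a0).sum()
                     + gammaln(n_dk + a).sum() - len(n_dk) * gammaln(a).sum())

        res = minimize(negll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        oracle = np.exp(res.x)
        fitted = minka_fixed_point(n_dk, np.ones(3))
        assert np.max(np.abs(fitted - oracle)) < 1e-4

    def test_optimize_alpha_leaves_counts_untouched(self, two_topic_setup):
        _, _, _, _, state = two_topic_setup
        before = state.n_dk.copy()
        alpha = optimize_alpha(state)
        assert np.array_equal(state.n_dk, before)
        assert np.all(alpha > 0)


class TestTopicKeys:
    def test_dominant_word_is_first_keyword(self):
        state = _state_from_counts(
            n_wk=[[9, 0], [1, 5]], n_dk=[[10, 5]], alpha=[1.0, 1.0],
            beta=0.01, terms=["chemo", "rads"])
        keys = extract_topic_keys(state, top_words=2)
        assert keys[0].keywords[0] == "chemo"
        assert keys[0].topic_id == 1

    def test_tied_counts_break_lexicographically(self):
        state = _state_from_counts(
            n_wk=[[3, 0], [3, 0]], n_dk=[[6, 0]], alpha=[1.0, 1.0],
            beta=0.01, terms=["zebra", "apple"])
        keys = extract_topic_keys(state, top_words=2)
        # vocabulary order is (apple, zebra); equal counts -> apple first
        assert keys[0].keywords == ("apple", "zebra")

    def test_strength_is_alpha(self):
        state = _state_from_counts(
            n_wk=[[2, 1]], n_dk=[[2, 1]], alpha=[1.4, 0.2], beta=0.01,
            terms=["aa"])
        keys = extract_topic_keys(state, top_words=1)
        assert keys[0].strength == pytest.approx(1.4)
        assert keys[1].strength == pytest.approx(0.2)

    def test_top_words_beyond_vocabulary_returns_all(self):
        state = _state_from_counts(
            n_wk=[[2, 1], [0, 3]], n_dk=[[2, 4]], alpha=[1.0, 1.0],
            beta=0.01, terms=["aa", "bb"])
        keys = extract_topic_keys(state, top_words=10)
        assert all(len(k.keywords) == 2 for k in keys)

    def test_keywords_match_full_sort_oracle(self, rng):
        V, K = 12, 3
        n_wk = rng.integers(0, 20, size=(V, K))
        n_dk = n_wk.sum(axis=0, keepdims=True)
        terms = [f"t{i:02d}" for i in range(V)]
        state = _state_from_counts(n_wk, n_dk, np.ones(K), 0.01, terms)
        keys = extract_topic_keys(state, top_words=5)
        beta, Vb = 0.01, 0.01 * V
        for k in range(K):
            probs = (n_wk[:, k] + beta) / (n_wk[:, k].sum() + Vb)
            oracle = [t for _, t in
                      sorted(zip(-probs, terms))][:5]
            assert list(keys[k].keywords) == oracle


class TestFileFeatureSet:
    def test_rows_are_smoothed_proportions(self):
        state = _state_from_counts(
            n_wk=[[3, 1]], n_dk=[[3, 1]], alpha=[0.5, 0.5], beta=0.01,
            terms=["aa"])
        feats = extract_file_feature_set(state)
        assert feats.matrix[0] == pytest.approx([3.5 / 5, 1.5 / 5])

    def test_empty_document_gets_normalized_prior(self):
        state = _state_from_counts(
            n_wk=[[2, 0]], n_dk=[[2, 0], [0, 0]], alpha=[0.9, 0.1],
            beta=0.01, terms=["aa"])
        feats = extract_file_feature_set(state)
        assert feats.matrix[1] == pytest.approx([0.9, 0.1])

    def test_rows_sum_to_one_and_bounded(self, two_topic_setup):
        _, _, _, _, state = two_topic_setup
        m = extract_file_feature_set(state).matrix
        assert np.max(np.abs(m.sum(axis=1) - 1.0)) < 1e-9
        assert m.max() <= 1.0 and m.min() >= 0.0

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            FileFeatureSet(matrix=np.array([[0.6, 0.6]]), doc_ids=("F1",))


class TestTopPairs:
    def test_basic_ordering(self):
        feats = FileFeatureSet(matrix=np.array([[0.5, 0.3, 0.2]]),
                               doc_ids=("F1",))
        assert export_top_pairs(feats, n_top=2)["F1"] == [(1, 0.5), (2, 0.3)]

    def test_ties_break_by_topic_id(self):
        feats = FileFeatureSet(matrix=np.array([[0.5, 0.5, 0.0]]),
                               doc_ids=("F1",))
        assert [t for t, _ in export_top_pairs(feats, n_top=3)["F1"]] \
            == [1, 2, 3]

    def test_matches_full_sort_oracle(self, rng):
        m = rng.dirichlet(np.ones(6), size=4)
        feats = FileFeatureSet(matrix=m, doc_ids=("A", "B", "C", "D"))
        pairs = export_top_pairs(feats, n_top=6)
        for i, doc in enumerate(("A", "B", "C", "D")):
            oracle = sorted(((m[i, k], -k) for k in range(6)), reverse=True)
            assert [t for t, _ in pairs[doc]] == [-k + 1 for _, k in oracle]


class TestLogLikelihood:
    def test_single_token_closed_form(self):
        # one token assigned topic k: p(w, z) = alpha_k/sum(alpha) * 1/V
        state = _state_from_counts(
            n_wk=[[1, 0], [0, 0]], n_dk=[[1, 0]], alpha=[0.3, 0.7],
            beta=0.01, terms=["aa", "bb"])
        expected = math.log((0.3 / 1.0) * (1.0 / 2.0))
        assert corpus_log_likelihood(state) == pytest.approx(expected)

    def test_invariant_under_topic_relabeling_with_symmetric_alpha(self):
        n_wk = np.array([[4, 1], [0, 3]])
        n_dk = np.array([[2, 2], [2, 2]])
        s1 = _state_from_counts(n_wk, n_dk, [0.5, 0.5], 0.01, ["aa", "bb"])
        s2 = _state_from_counts(n_wk[:, ::-1].copy(), n_dk[:, ::-1].copy(),
                                [0.5, 0.5], 0.01, ["aa", "bb"])
        assert corpus_log_likelihood(s1) == pytest.approx(
            corpus_log_likelihood(s2))


def test_fit_requires_nonempty_corpus():
    corpus = ForumCorpus(documents=[
        ForumDocument(forum_id="F1", text="chemo rads", post_count=1)])
    bow = vectorize_corpus(corpus)
    empty = BagOfWordsCorpus(vocabulary=bow.vocabulary, docs=((),),
                             doc_ids=("F1",))
    with pytest.raises(ValueError):
        fit_lda(empty, LdaConfig(K=2, n_iterations=5, seed=0))
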
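import numpy as np
import pytest

from topicphewas import align_topics, fit_lda, top_codes, topic_scores
from topicphewas.topic_model import TopicModelFit, load_fit, save_fit

from conftest import make_counts


def two_block_corpus(n_per_block=40, tokens=30, seed=0):
    """Subjects use codes only from block A (0-4) or only block B (5-9)."""
    rng = np.random.default_rng(seed)
    dense = np.zeros((2 * n_per_block, 10), dtype=int)
    for i in range(n_per_block):
        for w in rng.integers(0, 5, tokens):
            dense[i, w] += 1
        for w in rng.integers(5, 10, tokens):
            dense[n_per_block + i, w] += 1
    return make_counts(dense)


@pytest.fixture(scope="module")
def small_fit(small_counts):
    counts, _ = small_counts
    return fit_lda(counts, n_topics=5, n_iterations=400, burn_in=150,
                   thin=10, seed=202)


class TestFitLda:
    def test_rows_are_probability_vectors(self, small_fit):
        np.testing.assert_allclose(small_fit.theta.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(small_fit.phi.sum(axis=1), 1.0, atol=1e-8)
        assert small_fit.theta.min() >= 0 and small_fit.phi.min() >= 0

    def test_zero_code_subject_scores_equal_prior_mean(self):
        dense = np.array([[5, 3, 2], [0, 0, 0], [1, 4, 0]])
        fit = fit_lda(make_counts(dense), n_topics=50, n_iterations=20,
                      burn_in=10, thin=2, seed=1)
        np.testing.assert_array_equal(fit.theta[1], np.full(50, 1.0 / 50))

    def test_two_block_corpus_is_separated(self):
        counts = two_block_corpus()
        fit = fit_lda(counts, n_topics=2, n_iterations=200, burn_in=100,
                      thin=5, seed=3)
        dominant = fit.theta.argmax(axis=1)
        block = np.array([0] * 40 + [1] * 40)
        accuracy = max(
            (dominant == block).mean(), (dominant == 1 - block).mean()
        )
        assert accuracy >= 0.95

    def test_planted_phi_recovered(self, small_counts, small_fit):
        _, truth = small_counts
        _, cosines = align_topics(truth.phi, small_fit.phi)
        assert cosines.mean() >= 0.9

    def test_agrees_with_variational_reference(self):
        # independent cross-check: sklearn's variational LDA on the same
        # separable corpus should find essentially the same two topics
        from sklearn.decomposition import LatentDirichletAllocation

        counts = two_block_corpus()
        fit = fit_lda(counts, n_topics=2, n_iterations=200, burn_in=100,
                      thin=5, seed=3)
        ref = LatentDirichletAllocation(
            n_components=2, random_state=0, max_iter=50
        ).fit(counts.counts)
        phi_ref = ref.components_ / ref.components_.sum(axis=1, keepdims=True)
        _, cosines = align_topics(phi_ref, fit.phi)
        assert cosines.mean() >= 0.95

    def test_fixed_seed_bit_identical(self, small_counts):
        counts, _ = small_counts
        kw = dict(n_topics=4, n_iterations=60, burn_in=30, thin=5, seed=77)
        f1 = fit_lda(counts, **kw)
        f2 = fit_lda(counts, **kw)
        np.testing.assert_array_equal(f1.theta, f2.theta)
        np.testing.assert_array_equal(f1.phi, f2.phi)
        np.testing.assert_array_equal(
            f1.log_likelihood_trace, f2.log_likelihood_trace
        )

    def test_log_likelihood_improves_in_trend(self, small_fit):
        trace = small_fit.log_likelihood_trace
        assert trace[-50:].mean() > trace[:10].mean()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(make_counts(np.zeros((3, 4), dtype=int)), n_topics=2)

    def test_k_below_two_rejected(self, small_counts):
        with pytest.raises(ValueError):
            fit_lda(small_counts[0], n_topics=1)


class TestTopicScores:
    def test_returns_copy_of_theta(self, small_fit):
        scores = topic_scores(small_fit)
        np.testing.assert_array_equal(scores, small_fit.theta)
        scores[0, 0] = 99.0
        assert small_fit.theta[0, 0] != 99.0


class TestTopCodes:
    def _fit_with_phi(self, phi, vocab=None):
        phi = np.asarray(phi, float)
        K, V = phi.shape
        return TopicModelFit(
            n_topics=K, phi=phi, theta=np.full((2, K), 1.0 / K),
            alpha=1.0, beta=0.1, n_iterations=1, burn_in=0, thin=1, seed=0,
            log_likelihood_trace=np.zeros(1),
            code_vocab=vocab or [f"c{j}" for j in range(V)],
        )

    def test_threshold_count_on_constructed_row(self):
        row = [0.5, 0.3, 0.15, 0.04, 0.01]
        fit = self._fit_with_phi([row])
        assert len(top_codes(fit, 0, min_weight=0.2)) == 2

    def test_zero_threshold_returns_all_weights_summing_to_one(self):
        fit = self._fit_with_phi([[0.6, 0.3, 0.1]])
        out = top_codes(fit, 0, min_weight=0.0)
        assert len(out) == 3
        assert sum(w for _, w in out) == pytest.approx(1.0)

    def test_impossible_threshold_returns_empty(self):
        fit = self._fit_with_phi([[0.6, 0.3, 0.1]])
        assert top_codes(fit, 0, min_weight=1.0) == []

    def test_ties_broken_by_code_string(self):
        fit = self._fit_with_phi([[0.4, 0.4, 0.2]], vocab=["b", "a", "c"])
        assert [c for c, _ in top_codes(fit, 0, 0.1)] == ["a", "b", "c"]

    def test_strict_comparison_option(self):
        fit = self._fit_with_phi([[0.5, 0.3, 0.2]])
        assert len(top_codes(fit, 0, 0.3, comparison=">")) == 1
        assert len(top_codes(fit, 0, 0.3, comparison=">=")) == 2

    def test_invalid_topic_index(self, small_fit):
        with pytest.raises(ValueError):
            top_codes(small_fit, 99)


class TestSerialization:
    def test_save_load_round_trip(self, small_fit, tmp_path):
        save_fit(small_fit, tmp_path / "fit")
        loaded = load_fit(tmp_path / "fit")
        np.testing.assert_array_equal(loaded.phi, small_fit.phi)
        np.testing.assert_array_equal(loaded.theta, small_fit.theta)
        assert loaded.subject_ids == small_fit.subject_ids
        assert loaded.code_vocab == small_fit.code_vocab
        assert loaded.alpha == small_fit.alpha
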
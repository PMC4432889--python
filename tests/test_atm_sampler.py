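import numpy as np
import pytest

from atmbiblio import (
    Hyperparameters,
    conditional_distribution,
    enumerate_exact_posterior,
    estimate_phi,
    estimate_theta,
    fit,
    gibbs_sweep,
    init_state,
    joint_log_likelihood,
    load_model,
    save_model,
)
from atmbiblio.atm_sampler import GibbsState, _flatten

from conftest import build_corpus


@pytest.fixture
def h2():
    return Hyperparameters(T=2, alpha=0.5, beta=0.5)


class TestInitState:
    def test_t1_forces_all_assignments(self, tiny_corpus):
        h = Hyperparameters(T=1, alpha=1.0, beta=1.0)
        state = init_state(tiny_corpus, h, seed=0)
        assert (state.z == 0).all()
        word_counts = np.bincount(state.token_word, minlength=tiny_corpus.W)
        assert np.array_equal(state.n_wt[:, 0], word_counts)

    def test_seed_determinism(self, tiny_corpus, h2):
        s1 = init_state(tiny_corpus, h2, seed=9)
        s2 = init_state(tiny_corpus, h2, seed=9)
        assert np.array_equal(s1.z, s2.z) and np.array_equal(s1.y, s2.y)

    def test_counts_match_independent_recount(self, h2):
        rng = np.random.default_rng(4)
        docs = [(rng.integers(0, 10, size=10).tolist(), [0, 1, 2]) for _ in range(10)]
        corpus = build_corpus(docs, n_words=10)
        state = init_state(corpus, Hyperparameters(T=4, alpha=0.1, beta=0.1), seed=2)
        n_wt, n_ta = state.recount()
        assert np.array_equal(n_wt, state.n_wt)
        assert np.array_equal(n_ta, state.n_ta)

    def test_author_assignments_within_document_sets(self, tiny_corpus, h2):
        state = init_state(tiny_corpus, h2, seed=1)
        for d, doc in enumerate(tiny_corpus.documents):
            lo, hi = state.doc_offsets[d], state.doc_offsets[d + 1]
            assert set(state.y[lo:hi]) <= set(doc.authors.tolist())

    def test_empty_corpus_rejected(self, h2):
        from atmbiblio import AuthorIndex, Corpus, Vocabulary

        with pytest.raises(ValueError):
            init_state(Corpus([], Vocabulary(), AuthorIndex()), h2, seed=0)


class TestConditional:
    def test_degenerate_support_is_point_mass(self):
        corpus = build_corpus([([0, 0], [0])], n_words=2, n_authors=1)
        h = Hyperparameters(T=1, alpha=1.0, beta=1.0)
        state = init_state(corpus, h, seed=0)
        state.n_wt[state.token_word[0], 0] -= 1
        state.n_ta[0, 0] -= 1
        table = conditional_distribution(state, corpus, doc=0, pos=0, hyper=h)
        assert table.shape == (1, 1) and table[0, 0] == pytest.approx(1.0)

    def test_fresh_counts_give_uniform(self, h2):
        corpus = build_corpus([([0, 1], [0, 1])], n_words=3)
        state = init_state(corpus, h2, seed=0)
        state.n_wt[:] = 0
        state.n_ta[:] = 0
        table = conditional_distribution(state, corpus, 0, 0, h2)
        assert np.allclose(table, 1.0 / table.size)

    def test_printed_equation_arithmetic(self):
        # W=2, T=2, one author; decremented N_WT=[[2,0],[0,2]], N_TA column [2,2]
        corpus = build_corpus([([0, 0, 0, 1, 1], [0])], n_words=2, n_authors=1)
        h = Hyperparameters(T=2, alpha=1.0, beta=1.0)
        state = init_state(corpus, h, seed=0)
        state.n_wt = np.array([[2, 0], [0, 2]], dtype=np.int64)
        state.n_ta = np.array([[2], [2]], dtype=np.int64)
        table = conditional_distribution(state, corpus, 0, 0, h)  # word 0
        # weights t0: (3/4)(3/6), t1: (1/4)(3/6) -> normalized (0.75, 0.25)
        assert table[:, 0] == pytest.approx([0.75, 0.25])

    def test_table_sums_to_one(self, tiny_corpus, h2):
        state = init_state(tiny_corpus, h2, seed=3)
        i = int(state.doc_offsets[2])
        state.n_wt[state.token_word[i], state.z[i]] -= 1
        state.n_ta[state.z[i], state.y[i]] -= 1
        table = conditional_distribution(state, tiny_corpus, 2, 0, h2)
        assert table.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_count_detected(self, tiny_corpus, h2):
        state = init_state(tiny_corpus, h2, seed=3)
        state.n_wt[0, 0] = -1
        with pytest.raises(RuntimeError, match="corrupted"):
            conditional_distribution(state, tiny_corpus, 0, 0, h2)


class TestSweep:
    def test_count_conservation_and_consistency(self, tiny_corpus, h2):
        state = init_state(tiny_corpus, h2, seed=5)
        total = tiny_corpus.n_tokens
        for _ in range(5):
            gibbs_sweep(state, tiny_corpus, h2)
            assert state.n_wt.sum() == total == state.n_ta.sum()
            state.check_consistency()

    def test_t1_leaves_assignments_fixed(self, tiny_corpus):
        h = Hyperparameters(T=1, alpha=1.0, beta=1.0)
        state = init_state(tiny_corpus, h, seed=5)
        z0, y_before = state.z.copy(), state.y.copy()
        gibbs_sweep(state, tiny_corpus, h)
        assert (state.z == z0).all()  # single topic: z can never move

    def test_loglik_invariant_under_topic_relabeling(self, tiny_corpus, h2):
        state = init_state(tiny_corpus, h2, seed=6)
        ll = joint_log_likelihood(state, h2)
        permuted = GibbsState(
            z=1 - state.z, y=state.y.copy(),
            n_wt=state.n_wt[:, ::-1].copy(), n_ta=state.n_ta[::-1].copy(),
            token_word=state.token_word, token_doc=state.token_doc,
            doc_offsets=state.doc_offsets, auth_flat=state.auth_flat,
            auth_offsets=state.auth_offsets, rng_seed=0,
        )
        permuted.check_consistency()
        assert joint_log_likelihood(permuted, h2) == pytest.approx(ll, rel=1e-12)


class TestEstimators:
    def test_zero_token_author_gets_uniform_prior_mean(self):
        corpus = build_corpus([([0, 1], [0])], n_words=2, n_authors=2)
        h = Hyperparameters(T=4, alpha=0.5, beta=0.5)
        state = init_state(corpus, h, seed=0)
        theta = estimate_theta(state, h)
        assert np.allclose(theta[:, 1], 0.25)  # author 1 never assigned

    def test_direct_arithmetic(self, tiny_corpus):
        h = Hyperparameters(T=2, alpha=0.5, beta=1.0)
        state = init_state(tiny_corpus, h, seed=0)
        state.n_ta = np.array([[3, 0], [1, 0]], dtype=np.int64)
        theta = estimate_theta(state, h)
        assert theta[:, 0] == pytest.approx([0.7, 0.3])
        state.n_wt = np.zeros((tiny_corpus.W, 2), dtype=np.int64)
        state.n_wt[0, 0] = 4
        phi = estimate_phi(state, h)
        # column [4,0,0,0], beta=1, W=4 -> (5/8, 1/8, 1/8, 1/8)
        assert phi[:, 0] == pytest.approx([5 / 8, 1 / 8, 1 / 8, 1 / 8])

    def test_columns_normalized(self, tiny_corpus, h2):
        state = init_state(tiny_corpus, h2, seed=8)
        assert np.allclose(estimate_theta(state, h2).sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(estimate_phi(state, h2).sum(axis=0), 1.0, atol=1e-9)


class TestFit:
    def test_single_word_corpus_is_point_mass(self):
        corpus = build_corpus([([0] * 6, [0]), ([0] * 4, [0])], n_words=1)
        h = Hyperparameters(T=1, alpha=1.0, beta=0.01)
        model = fit(corpus, h, n_sweeps=10, seed=0)
        assert model.phi[0, 0] > 0.99

    def test_seed_determinism_bitwise(self, tiny_corpus, h2):
        m1 = fit(tiny_corpus, h2, n_sweeps=20, seed=13)
        m2 = fit(tiny_corpus, h2, n_sweeps=20, seed=13)
        assert np.array_equal(m1.theta, m2.theta)
        assert np.array_equal(m1.phi, m2.phi)
        assert np.array_equal(m1.log_likelihood, m2.log_likelihood)

    def test_loglik_finite_and_columns_normalized(self, tiny_corpus, h2):
        model = fit(tiny_corpus, h2, n_sweeps=30, seed=1)
        assert np.isfinite(model.log_likelihood).all()
        assert np.allclose(model.theta.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(model.phi.sum(axis=0), 1.0, atol=1e-9)
        assert (model.theta > 0).all() and (model.phi > 0).all()

    def test_oversized_T_warns_not_raises(self, tiny_corpus, caplog):
        h = Hyperparameters(T=100, alpha=0.5, beta=0.5)
        fit(tiny_corpus, h, n_sweeps=4, seed=0)  # must not raise


class TestExactPosterior:
    def test_enumeration_matches_closed_form_single_token(self):
        # One token, one author: P(z=t) ∝ β/(Wβ) · α/(Tα) is uniform over T.
        corpus = build_corpus([([0], [0])], n_words=2, n_authors=1)
        h = Hyperparameters(T=2, alpha=0.3, beta=0.7)
        marg = enumerate_exact_posterior(corpus, h)
        assert np.allclose(marg[0, :, 0], 0.5)

    def test_enumeration_marginals_sum_to_one(self, tiny_corpus, h2):
        marg = enumerate_exact_posterior(tiny_corpus, h2)
        assert np.allclose(marg.sum(axis=(1, 2)), 1.0)

    def test_enumeration_guards_against_blowup(self, h2):
        corpus = build_corpus([(list(range(10)) * 3, [0, 1])], n_words=10)
        with pytest.raises(ValueError, match="too large"):
            enumerate_exact_posterior(corpus, h2)


def test_model_bundle_roundtrip(tmp_path, tiny_corpus, h2):
    model = fit(tiny_corpus, h2, n_sweeps=10, seed=2)
    save_model(model, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    assert np.array_equal(loaded.theta, model.theta)
    assert np.array_equal(loaded.phi, model.phi)
    assert loaded.hyper == model.hyper
    assert loaded.vocabulary == model.vocabulary
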
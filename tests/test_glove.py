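import numpy as np
import pytest
from hypothesis import given, strategies as st

import radstroke as rs
from radstroke.preprocess import TokenDoc


def _doc(sentences, rid="d"):
    return TokenDoc(report_id=rid, sentences=[list(s) for s in sentences])


def _brute_force_mass(sentences, window):
    """Total co-occurrence mass by direct enumeration of ordered pairs."""
    total = 0.0
    for sent in sentences:
        n = len(sent)
        for i in range(n):
            for j in range(n):
                if i == j or sent[i] == sent[j]:
                    continue
                d = abs(i - j)
                if d <= window:
                    total += 1.0 / d
    return total


class TestCooccurrence:
    def test_adjacent_pair_weight_one(self):
        docs = [_doc([["a", "b"]])]
        vocab = rs.fit_vocabulary(docs)
        cooc = rs.build_cooccurrence(docs, vocab, window=10)
        X = cooc.X.toarray()
        a, b = vocab.index["a"], vocab.index["b"]
        assert X[a, b] == X[b, a] == 1.0

    def test_distance_weighting_by_hand(self):
        docs = [_doc([["a", "b", "c"]])]
        vocab = rs.fit_vocabulary(docs)
        X = rs.build_cooccurrence(docs, vocab, window=10).X.toarray()
        idx = vocab.index
        assert X[idx["a"], idx["b"]] == 1.0
        assert X[idx["b"], idx["c"]] == 1.0
        assert X[idx["a"], idx["c"]] == 0.5

    def test_empty_corpus_gives_zero_matrix(self):
        docs = [_doc([["a", "b"]])]
        vocab = rs.fit_vocabulary(docs)
        cooc = rs.build_cooccurrence([TokenDoc("e", [])], vocab)
        assert cooc.nnz == 0

    def test_sentence_boundaries_block_cooccurrence(self):
        docs = [_doc([["a"], ["b"]])]
        vocab = rs.fit_vocabulary(docs)
        assert rs.build_cooccurrence(docs, vocab, window=10).nnz == 0
        spanning = rs.build_cooccurrence(docs, vocab, window=10, cross_sentence=True)
        assert spanning.X.toarray()[vocab.index["a"], vocab.index["b"]] == 1.0

    def test_diagonal_is_zero_for_repeated_tokens(self):
        docs = [_doc([["a", "b", "a"]])]
        vocab = rs.fit_vocabulary(docs)
        X = rs.build_cooccurrence(docs, vocab, window=10).X.toarray()
        assert np.all(np.diag(X) == 0)

    @given(
        st.lists(
            st.lists(st.sampled_from("abcdef"), min_size=1, max_size=20),
            min_size=1,
            max_size=6,
        ),
        st.integers(min_value=1, max_value=8),
    )
    def test_total_mass_matches_brute_force(self, sentences, window):
        docs = [_doc(sentences)]
        vocab = rs.fit_vocabulary(docs)
        cooc = rs.build_cooccurrence(docs, vocab, window=window)
        assert cooc.X.sum() == pytest.approx(_brute_force_mass(sentences, window))
        # symmetry
        assert (cooc.X - cooc.X.T).nnz == 0


@pytest.fixture(scope="module")
def planted_corpus():
    spec = rs.SyntheticCorpusSpec(n_docs=200, seed=5)
    texts = rs.generate_embedding_corpus(spec)
    docs = [rs.preprocess_report(t, report_id=f"D{i}") for i, t in enumerate(texts)]
    vocab = rs.fit_vocabulary(docs)
    cooc = rs.build_cooccurrence(docs, vocab, window=10)
    return spec, vocab, cooc


class TestTraining:
    def test_zero_iters_returns_seeded_initialization(self, planted_corpus):
        _, vocab, cooc = planted_corpus
        cfg = rs.GloveConfig(d=8, iters=0, seed=3)
        model = rs.train_glove(cooc, cfg)
        rng = np.random.default_rng(3)
        expected = rng.uniform(-0.5 / 8, 0.5 / 8, size=(len(vocab), 8))
        np.testing.assert_array_equal(model.W, expected)
        assert model.loss_history == []

    def test_all_zero_cooccurrence_errors(self):
        docs = [_doc([["a", "b"]])]
        vocab = rs.fit_vocabulary(docs)
        empty = rs.build_cooccurrence([TokenDoc("e", [])], vocab)
        with pytest.raises(ValueError, match="no co-occurrence mass"):
            rs.train_glove(empty, rs.GloveConfig(d=4, iters=1))

    def test_loss_decreases_over_training(self, planted_corpus):
        _, _, cooc = planted_corpus
        model = rs.train_glove(cooc, rs.GloveConfig(d=16, iters=10, seed=2))
        assert len(model.loss_history) == 10
        assert model.loss_history[-1] < model.loss_history[0]

    def test_same_seed_same_loss_history(self, planted_corpus):
        _, _, cooc = planted_corpus
        cfg = rs.GloveConfig(d=8, iters=4, seed=9)
        h1 = rs.train_glove(cooc, cfg).loss_history
        h2 = rs.train_glove(cooc, cfg).loss_history
        assert h1 == h2

    def test_planted_synonyms_closer_than_controls(self, planted_corpus):
        spec, vocab, cooc = planted_corpus
        model = rs.train_glove(cooc, rs.GloveConfig(d=50, iters=30, seed=1))
        emb = rs.export_embeddings(model, vocab)

        def cos(a, b):
            va, vb = emb.vector(a), emb.vector(b)
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        within = np.mean([cos(a, b) for a, b in spec.synonym_pairs])
        firsts = [p[0] for p in spec.synonym_pairs]
        across = np.mean(
            [cos(firsts[i], firsts[j]) for i in range(len(firsts)) for j in range(i + 1, len(firsts))]
        )
        assert within > across + 0.2


class TestExportAndNeighbors:
    def test_export_sums_main_and_context(self, planted_corpus):
        _, vocab, cooc = planted_corpus
        model = rs.train_glove(cooc, rs.GloveConfig(d=6, iters=1, seed=0))
        emb = rs.export_embeddings(model, vocab)
        np.testing.assert_allclose(emb.vectors, model.W + model.W_context)
        assert emb.d == 6

    def test_neighbors_match_brute_force(self):
        rng = np.random.default_rng(0)
        tokens = [f"t{i}" for i in range(12)]
        emb = rs.EmbeddingFile(tokens=tokens, vectors=rng.normal(size=(12, 4)))
        got = rs.nearest_neighbors(emb, "t3", 5)
        q = emb.vector("t3")
        sims = sorted(
            (
                (-(emb.vector(t) @ q) / (np.linalg.norm(emb.vector(t)) * np.linalg.norm(q)), t)
                for t in tokens
                if t != "t3"
            )
        )
        assert [t for _, t in sims[:5]] == [t for t, _ in got]

    def test_k_equals_v_minus_one_returns_all_others(self, small_embedding):
        got = rs.nearest_neighbors(small_embedding, "acute", len(small_embedding) - 1)
        assert len(got) == len(small_embedding) - 1
        assert "acute" not in [t for t, _ in got]

    def test_unknown_token_errors(self, small_embedding):
        with pytest.raises(KeyError):
            rs.nearest_neighbors(small_embedding, "nope", 2)
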
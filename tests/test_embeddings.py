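"""Embedding store, retrofitting, and the word semantic score."""

from __future__ import annotations

import math

import numpy as np
import pytest

from kias.embeddings import (
    EmbeddingStore,
    RetrofitConfig,
    build_lexicon_graph,
    cosine,
    read_word2vec,
    retrofit,
    write_word2vec,
    wss,
)
from kias.lexicon import DepressionLexicon


class TestCosine:
    def test_identity(self):
        v = np.array([0.3, -1.2, 2.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(
            1 / math.sqrt(2)
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(3), np.ones(3))


class TestStore:
    def test_absent_word_is_distinguishable_miss(self):
        store = EmbeddingStore({"a": np.ones(3)})
        assert store.get("b") is None
        with pytest.raises(KeyError):
            store["b"]

    def test_word2vec_text_round_trip(self, tmp_path):
        store = EmbeddingStore(
            {"a": np.array([1.0, 2.5]), "b": np.array([-0.125, 3.0])}
        )
        path = tmp_path / "emb.txt"
        write_word2vec(store, path)
        back = read_word2vec(path)
        for w in ("a", "b"):
            np.testing.assert_array_equal(store[w], back[w])

    def test_headerless_file_detected(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("a 1.0 0.0\nb 0.0 1.0\n", encoding="utf-8")
        assert len(read_word2vec(path)) == 2


class TestLexiconGraph:
    def test_same_phrase_words_are_linked(self):
        lex = DepressionLexicon({"S3": {"trouble sleeping"}})
        graph = build_lexicon_graph(lex)
        assert graph.has_edge("trouble", "sleeping")

    def test_single_one_word_phrase_has_no_edges(self):
        lex = DepressionLexicon({"S3": {"insomnia"}})
        graph = build_lexicon_graph(lex)
        assert graph.number_of_nodes() == 1
        assert graph.number_of_edges() == 0

    def test_shared_word_connects_phrase_partners(self):
        lex = DepressionLexicon({"S2": {"feeling down", "feeling hopeless"}})
        graph = build_lexicon_graph(lex)
        assert graph.has_edge("feeling", "down")
        assert graph.has_edge("feeling", "hopeless")
        assert not graph.has_edge("down", "hopeless")


class TestRetrofit:
    def test_one_jacobi_step_two_word_fixture(self):
        store = EmbeddingStore(
            {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        )
        lex = DepressionLexicon({"S2": {"a b"}})
        graph = build_lexicon_graph(lex)
        out = retrofit(store, graph, RetrofitConfig(alpha=1.0, iterations=1))
        np.testing.assert_allclose(out["a"], [0.5, 0.5])
        np.testing.assert_allclose(out["b"], [0.5, 0.5])
        assert cosine(out["a"], out["b"]) == pytest.approx(1.0)

    def test_zero_iterations_forbidden(self):
        with pytest.raises(ValueError):
            RetrofitConfig(iterations=0)

    def test_off_graph_word_keeps_exact_vector(self):
        store = EmbeddingStore(
            {
                "a": np.array([1.0, 0.0]),
                "b": np.array([0.0, 1.0]),
                "zebra": np.array([0.25, -0.75]),
            }
        )
        graph = build_lexicon_graph(DepressionLexicon({"S2": {"a b"}}))
        out = retrofit(store, graph)
        np.testing.assert_array_equal(out["zebra"], store["zebra"])

    def test_empty_graph_returns_input_unchanged(self):
        import networkx as nx

        store = EmbeddingStore({"a": np.array([1.0, 2.0])})
        out = retrofit(store, nx.Graph())
        np.testing.assert_array_equal(out["a"], store["a"])

    def test_one_step_star_update_is_known_convex_combination(self):
        """On a star graph a single synchronous round must give
        (alpha * center + (1/k) * sum(neighbors)) / (alpha + 1): a convex
        combination of the original vector and the neighbor mean."""
        rng = np.random.default_rng(11)
        import networkx as nx

        center, spokes = "hub", [f"n{i}" for i in range(4)]
        vecs = {w: rng.standard_normal(3) for w in [center, *spokes]}
        store = EmbeddingStore(vecs)
        graph = nx.Graph([(center, s) for s in spokes])
        alpha = 0.7
        out = retrofit(store, graph, RetrofitConfig(alpha=alpha, iterations=1))
        k = len(spokes)
        expected = (alpha * vecs[center] + np.mean([vecs[s] for s in spokes], axis=0)) / (
            alpha + 1.0
        )
        np.testing.assert_allclose(out[center], expected, atol=1e-12)

    def test_linked_pair_cosine_nondecreasing_over_iterations(self):
        rng = np.random.default_rng(3)
        words = [f"w{i}" for i in range(8)]
        vecs = {w: rng.standard_normal(16) for w in words}
        vecs = {w: v / np.linalg.norm(v) for w, v in vecs.items()}
        lex = DepressionLexicon(
            {"S1": {f"{a} {b}" for a, b in zip(words[:-1], words[1:])}}
        )
        graph = build_lexicon_graph(lex)
        store = EmbeddingStore(vecs)
        initial = float(
            np.mean([cosine(store[a], store[b]) for a, b in graph.edges])
        )
        means = []
        for iters in (1, 3, 6, 10):
            out = retrofit(store, graph, RetrofitConfig(iterations=iters))
            sims = [cosine(out[a], out[b]) for a, b in graph.edges]
            means.append(float(np.mean(sims)))
        # every retrofit depth leaves linked pairs more similar than the
        # raw embeddings (synchronous rounds oscillate slightly on the way
        # to the fixed point, so per-round monotonicity is not asserted)
        assert all(m > initial for m in means)
        # and the iteration settles: late rounds change almost nothing
        assert abs(means[-1] - means[-2]) < 1e-3


class TestWss:
    def test_lexicon_word_scores_one(self, unit_embeddings, mini_lexicon):
        assert wss("insomnia", unit_embeddings, mini_lexicon) == pytest.approx(1.0)

    def test_orthogonal_word_clamped_to_zero(self, mini_lexicon):
        store = EmbeddingStore(
            {
                "trouble": np.array([1.0, 0.0]),
                "sleeping": np.array([1.0, 0.0]),
                "insomnia": np.array([1.0, 0.0]),
                "feeling": np.array([1.0, 0.0]),
                "down": np.array([1.0, 0.0]),
                "nobody": np.array([1.0, 0.0]),
                "likes": np.array([1.0, 0.0]),
                "me": np.array([1.0, 0.0]),
                "granite": np.array([0.0, 1.0]),
                "opposite": np.array([-1.0, 0.0]),
            }
        )
        assert wss("granite", store, mini_lexicon) == 0.0
        assert wss("opposite", store, mini_lexicon) == 0.0  # negative max clamped

    def test_oov_word_scores_zero(self, unit_embeddings, mini_lexicon):
        assert wss("xylophone", unit_embeddings, mini_lexicon) == 0.0

    def test_retrofitting_raises_wss_of_graph_linked_word(self):
        """Domain relatedness is learned: after retrofitting, 'feeling'
        moves toward 'lethargic' and its semantic score strictly rises."""
        import networkx as nx

        rng = np.random.default_rng(5)
        v1, v2 = rng.standard_normal(12), rng.standard_normal(12)
        store = EmbeddingStore(
            {"feeling": v1 / np.linalg.norm(v1), "lethargic": v2 / np.linalg.norm(v2)}
        )
        lex = DepressionLexicon({"S4": {"lethargic"}})  # 'feeling' not in lexicon
        graph = nx.Graph([("feeling", "lethargic")])
        before = wss("feeling", store, lex)
        after = wss("feeling", retrofit(store, graph), lex)
        assert after > before
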
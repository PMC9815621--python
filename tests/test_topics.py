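"""Embedding training, lexicon expansion, k selection, topic incidence."""

import numpy as np
import pytest

from counselhelp.embedding import Embedding, EmbeddingParams, cosine, \
    train_embedding
from counselhelp.topics import (doc_vector, expand_lexicon,
                                select_k_and_cluster, topic_incidence)


def _embedding_from(vectors: dict[str, list[float]]) -> Embedding:
    vocab = {w: i for i, w in enumerate(vectors)}
    mat = np.array([vectors[w] for w in vectors], dtype=float)
    return Embedding(vocabulary=vocab, vectors=mat,
                     params=EmbeddingParams(dimension=mat.shape[1],
                                            min_count=1))


class TestTrainEmbedding:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_cooccurrence_drives_similarity(self, seed):
        """Words that always co-occur end up closer than words that
        never do."""
        rng = np.random.default_rng(seed)
        docs = []
        for _ in range(120):
            if rng.random() < 0.5:
                docs.append(["alpha", "beta"] * 3 + ["pad1"])
            else:
                docs.append(["gamma", "delta"] * 3 + ["pad2"])
        emb = train_embedding(docs, EmbeddingParams(dimension=2, min_count=1,
                                                    seed=seed))
        assert emb.similarity("alpha", "beta") > emb.similarity("alpha",
                                                                "gamma")

    def test_min_count_filters_vocabulary(self):
        docs = [["a", "a", "b"]]
        emb = train_embedding(docs, EmbeddingParams(dimension=2, min_count=2))
        assert "a" in emb and "b" not in emb

    def test_min_count_too_large_raises(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            train_embedding([["a", "b"]],
                            EmbeddingParams(dimension=2, min_count=10))

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError, match="empty corpus"):
            train_embedding([[]], EmbeddingParams(dimension=2, min_count=1))

    def test_deterministic_under_seed(self):
        docs = [["a", "b", "c", "a"], ["b", "c", "d"], ["a", "d", "b"]]
        p = EmbeddingParams(dimension=3, min_count=1, seed=9)
        e1 = train_embedding(docs, p)
        e2 = train_embedding(docs, p)
        assert e1.vocabulary == e2.vocabulary
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_stopwords_removed_before_training(self):
        docs = [["stop", "a", "b"]] * 5
        emb = train_embedding(docs, EmbeddingParams(dimension=2, min_count=1),
                              stopwords={"stop"})
        assert "stop" not in emb


class TestExpandLexicon:
    def test_threshold_one_keeps_seeds_and_exact_duplicates(self):
        emb = _embedding_from({"seed": [1, 0], "dup": [2, 0],
                               "other": [0, 1]})
        assert expand_lexicon(["seed"], emb, 1.0) == {"seed", "dup"}

    def test_threshold_minus_one_returns_whole_vocabulary(self):
        emb = _embedding_from({"seed": [1, 0], "x": [0, 1], "y": [-1, 0]})
        assert expand_lexicon(["seed"], emb, -1.0) == {"seed", "x", "y"}

    def test_planted_synonym_in_distractor_out(self):
        emb = _embedding_from({
            "seed": [1.0, 0.0],
            "synonym": [0.9, np.sqrt(1 - 0.81)],
            "distractor": [0.1, np.sqrt(1 - 0.01)],
        })
        out = expand_lexicon(["seed"], emb, 0.5)
        assert out == {"seed", "synonym"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        emb = _embedding_from({f"w{i}": rng.normal(size=4).tolist()
                               for i in range(30)})
        lo = expand_lexicon(["w0"], emb, 0.2)
        hi = expand_lexicon(["w0"], emb, 0.6)
        assert hi <= lo

    def test_no_seed_in_vocab_warns_and_returns_seeds(self):
        emb = _embedding_from({"a": [1, 0]})
        with pytest.warns(UserWarning, match="no seed"):
            out = expand_lexicon(["missing"], emb, 0.5)
        assert out == {"missing"}

    def test_bad_threshold_rejected(self):
        emb = _embedding_from({"a": [1, 0]})
        with pytest.raises(ValueError):
            expand_lexicon(["a"], emb, 1.5)


class TestDocVector:
    def test_single_word_document(self):
        emb = _embedding_from({"a": [3.0, 4.0]})
        v, flag = doc_vector(["a"], emb)
        np.testing.assert_array_equal(v, [3.0, 4.0])
        assert not flag

    def test_opposite_vectors_cancel(self):
        emb = _embedding_from({"p": [1.0, 2.0], "n": [-1.0, -2.0]})
        v, _ = doc_vector(["p", "n"], emb)
        np.testing.assert_allclose(v, [0.0, 0.0])

    def test_hand_mean(self):
        emb = _embedding_from({"a": [1, 0], "b": [0, 1], "c": [1, 1]})
        v, _ = doc_vector(["a", "b", "c"], emb)
        np.testing.assert_allclose(v, [2 / 3, 2 / 3])

    def test_out_of_vocabulary_document_flagged(self):
        emb = _embedding_from({"a": [1, 0]})
        v, flag = doc_vector(["zzz"], emb)
        assert flag
        np.testing.assert_array_equal(v, [0.0, 0.0])


class TestSelectK:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (40, 3)),
                         rng.normal(12, 1, (40, 3))])
        sel = select_k_and_cluster(pts, range(2, 7), seed=4)
        assert sel.chosen_k == 2
        assert all(-1.0 <= v <= 1.0 for v in sel.silhouette_trace.values())

    def test_k_range_out_of_bounds_rejected(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError, match="k_range"):
            select_k_and_cluster(pts, range(2, 10))

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 1, (30, 2)),
                         rng.normal(8, 1, (30, 2))])
        s1 = select_k_and_cluster(pts, range(2, 5), seed=3)
        s2 = select_k_and_cluster(pts, range(2, 5), seed=3)
        assert s1.chosen_k == s2.chosen_k
        np.testing.assert_array_equal(s1.assignments, s2.assignments)


class TestTopicIncidence:
    LEX = {f"t{j}": {f"t{j}word{k}" for k in range(3)} for j in range(7)}

    def test_no_topic_words_zero_vector(self):
        inc = topic_incidence(["plain", "words"], self.LEX)
        assert inc.vector.tolist() == [0] * 7

    def test_single_topic_unit_vector(self):
        inc = topic_incidence(["t2word0", "plain"], self.LEX)
        assert inc.vector.tolist() == [0, 0, 1, 0, 0, 0, 0]

    def test_all_topics_saturate(self):
        toks = [f"t{j}word1" for j in range(7)]
        assert topic_incidence(toks, self.LEX).vector.tolist() == [1] * 7

    def test_invariant_to_order_and_multiplicity(self):
        a = topic_incidence(["t1word0", "t3word1"], self.LEX)
        b = topic_incidence(["t3word1"] * 5 + ["t1word0"] * 2, self.LEX)
        np.testing.assert_array_equal(a.vector, b.vector)
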
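"""Dyadic synchrony formulas: Jaccard, LSM, emotion cosine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from counselhelp.synchrony import (composite_lsm, emotional_similarity,
                                   jaccard_topic_consistency, lsm_category,
                                   append_synchrony, score_pair)
from counselhelp import vocab


class TestJaccard:
    def test_identical_vectors(self):
        assert jaccard_topic_consistency((1, 1, 0, 0, 0, 0, 0),
                                         (1, 1, 0, 0, 0, 0, 0)) == 1.0

    def test_disjoint_vectors(self):
        assert jaccard_topic_consistency((1, 0, 0, 0, 0, 0, 0),
                                         (0, 1, 0, 0, 0, 0, 0)) == 0.0

    def test_enumerated_overlap(self):
        # intersection 2, union 4
        r = (1, 1, 1, 0, 0, 0, 0)
        m = (1, 1, 0, 1, 0, 0, 0)
        assert jaccard_topic_consistency(r, m) == 0.5

    def test_empty_union_scores_zero(self):
        assert jaccard_topic_consistency((0,) * 7, (0,) * 7) == 0.0

    def test_symmetric(self):
        r, m = (1, 0, 1, 0, 1, 0, 0), (1, 1, 0, 0, 1, 0, 1)
        assert jaccard_topic_consistency(r, m) == \
            jaccard_topic_consistency(m, r)

    def test_partition_mismatch_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            jaccard_topic_consistency((1, 0), (1, 0), "symptom", "factor")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard_topic_consistency((1, 0), (1, 0, 1))


class TestLsmCategory:
    def test_equal_rates_score_one(self):
        assert lsm_category(5.0, 5.0) == 1.0

    def test_both_zero_forced_to_one_by_smoothing(self):
        assert lsm_category(0.0, 0.0) == 1.0

    def test_one_sided_use_near_zero(self):
        # 1 - 10/10.0001
        assert lsm_category(10.0, 0.0) == pytest.approx(1 - 10.0 / 10.0001)
        assert lsm_category(10.0, 0.0) == pytest.approx(1.0e-5, rel=1e-3)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            lsm_category(-1.0, 2.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_bounded_and_symmetric(self, p1, p2):
        s = lsm_category(p1, p2)
        assert 0.0 <= s <= 1.0
        assert s == lsm_category(p2, p1)

    @given(st.floats(1, 100), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_gap_at_fixed_sum(self, total, f1, f2):
        """At a fixed rate sum, a wider gap never scores higher."""
        d1, d2 = sorted([f1 * total, f2 * total])
        s_small = lsm_category((total + d1) / 2, (total - d1) / 2)
        s_large = lsm_category((total + d2) / 2, (total - d2) / 2)
        assert s_small >= s_large - 1e-12


class TestCompositeLsm:
    def test_all_categories_equal_scores_one(self):
        props = {c: 4.0 for c in vocab.LSM_CATEGORIES}
        scores, mean = composite_lsm(props, dict(props))
        assert mean == 1.0
        assert len(scores) == 9

    def test_two_category_toy_group(self):
        p1 = {"A": 5.0, "B": 10.0}
        p2 = {"A": 5.0, "B": 10.0 / 3}
        scores, mean = composite_lsm(p1, p2, ["A", "B"])
        assert scores["A"] == 1.0
        assert scores["B"] == pytest.approx(0.5, abs=1e-5)
        assert mean == pytest.approx(0.75, abs=1e-5)

    def test_declared_absence_uses_eight_categories(self):
        group = [c for c in vocab.LSM_CATEGORIES if c != "Article"]
        props = {c: 2.0 for c in group}
        scores, mean = composite_lsm(props, dict(props), group)
        assert len(scores) == 8
        assert mean == 1.0

    def test_missing_category_named_in_error(self):
        p = {c: 1.0 for c in vocab.LSM_CATEGORIES if c != "Quant"}
        with pytest.raises(KeyError, match="Quant"):
            composite_lsm(p, p)


class TestEmotionalSimilarity:
    def test_scale_invariance(self):
        e = np.array([1.0, 2.0, 0.5, 0, 0, 1, 0])
        assert emotional_similarity(e, 2 * e) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert emotional_similarity((1, 0, 0, 0, 0, 0, 0),
                                    (0, 1, 0, 0, 0, 0, 0)) == 0.0

    def test_hand_cosine(self):
        s = emotional_similarity((1, 1, 0, 0, 0, 0, 0),
                                 (1, 0, 0, 0, 0, 0, 0))
        assert s == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_scores_zero(self):
        assert emotional_similarity((0,) * 7, (1, 2, 3, 0, 0, 0, 0)) == 0.0

    def test_negative_element_rejected(self):
        with pytest.raises(ValueError):
            emotional_similarity((1, -1, 0, 0, 0, 0, 0), (1,) * 7)

    def test_symmetric(self):
        a = (1, 2, 3, 0, 1, 0, 2)
        b = (2, 0, 1, 1, 0, 3, 1)
        assert emotional_similarity(a, b) == emotional_similarity(b, a)


class TestAppendSynchrony:
    def test_columns_match_standalone_operations(self, tiny_corpus):
        from tests.conftest import featurize
        table = featurize(tiny_corpus)
        row = table.data.iloc[0]
        q = {c: row[f"counselee:{c}"] for c in
             set(vocab.LSM_CATEGORIES) | set(vocab.EMOTION_CATEGORIES)}
        r = {c: row[f"counselor:{c}"] for c in
             set(vocab.LSM_CATEGORIES) | set(vocab.EMOTION_CATEGORIES)}
        _, lsm_mean = composite_lsm(q, r)
        assert row["sync:LSM_mean"] == pytest.approx(lsm_mean)
        e1 = [q[c] for c in vocab.EMOTION_CATEGORIES]
        e2 = [r[c] for c in vocab.EMOTION_CATEGORIES]
        assert row["sync:AffectSIM"] == pytest.approx(
            emotional_similarity(e1, e2))
        # p0: question hits symptom topic 1 only; response hits topic 1 too
        assert row["sync:SymptomsSIM"] == 1.0
        # p0: question has no factor word, response hits factor topic 1
        assert row["sync:FactorsSIM"] == 0.0
        tags = {table.tags[c][0] for c in table.data.columns
                if c.startswith("sync:")}
        assert tags == {"synchrony"}

    def test_identical_texts_score_one_everywhere(self):
        from counselhelp.corpus import QAPair
        from tests.conftest import featurize
        text = "preps01 i01 anx01 conj01 symp2w01 fact3w01 adverb01 ."
        pair = QAPair.from_raw("t", text, text, 2)
        table = featurize([pair])
        row = table.data.iloc[0]
        assert row["sync:LSM_mean"] == 1.0
        assert row["sync:AffectSIM"] == pytest.approx(1.0)
        assert row["sync:SymptomsSIM"] == 1.0
        assert row["sync:FactorsSIM"] == 1.0

    def test_empty_response_flagged_zeros(self):
        from counselhelp.corpus import QAPair
        from tests.conftest import featurize
        pair = QAPair.from_raw("t", "anx01 symp1w01 preps01 .", "", 1)
        table = featurize([pair])
        row = table.data.iloc[0]
        assert row["sync:AffectSIM"] == 0.0
        assert row["sync:SymptomsSIM"] == 0.0
        assert table.n_degenerate_pairs == 1

    def test_alignment_mismatch_rejected(self, tiny_corpus):
        from tests.conftest import featurize
        table = featurize(tiny_corpus)
        with pytest.raises(ValueError, match="rows"):
            append_synchrony(table, tiny_corpus[:1],
                             vocab.topic_lexicons("symptom"),
                             vocab.topic_lexicons("factor"))
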
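"""Synthetic corpus generator: determinism, IO, calibration, recovery."""

import numpy as np
import pytest
from scipy import stats

from counselhelp.corpus import (ConfigError, CorpusFormatError,
                                GeneratorConfig, OutcomeModel,
                                SynchronyControls, generate_corpus,
                                read_corpus, write_corpus)
from counselhelp.features import category_proportions
from counselhelp.lexicon import tokenize
from counselhelp.vocab import (DICTIONARY_LAYOUT, FUNCTION_WORD_LEAVES,
                               LEAF_CATEGORIES, default_lexicon)


class TestGenerateCorpus:
    def test_empty_corpus(self):
        corpus, truth = generate_corpus(GeneratorConfig(n_pairs=0))
        assert corpus == []
        assert len(truth) == 0

    def test_fixed_seed_reproduces_exactly(self):
        cfg = GeneratorConfig(n_pairs=20, seed=42)
        c1, t1 = generate_corpus(cfg)
        c2, t2 = generate_corpus(cfg)
        assert [p.question_raw for p in c1] == [p.question_raw for p in c2]
        assert [p.response_raw for p in c1] == [p.response_raw for p in c2]
        assert [p.helpful_votes for p in c1] == [p.helpful_votes for p in c2]
        assert t1.features.equals(t2.features)

    def test_votes_support_starts_at_one(self):
        corpus, _ = generate_corpus(GeneratorConfig(n_pairs=100, seed=1))
        assert min(p.helpful_votes for p in corpus) >= 1

    def test_tokens_match_tokenizer_output(self):
        corpus, _ = generate_corpus(GeneratorConfig(n_pairs=5, seed=2))
        for p in corpus:
            assert p.question_tokens == tokenize(p.question_raw).tokens
            assert p.response_tokens == tokenize(p.response_raw).tokens

    def test_document_lengths_near_targets(self):
        corpus, _ = generate_corpus(GeneratorConfig(n_pairs=200, seed=3))
        q = np.mean([len(p.question_tokens) for p in corpus])
        r = np.mean([len(p.response_tokens) for p in corpus])
        assert abs(q - 185) < 10
        assert abs(r - 388) < 15

    def test_planted_lsm_effect_raises_votes(self):
        """A positive style-matching coefficient (0.8) must surface as a
        positive rank correlation between the latent LSM score and votes."""
        ranges = {k: r for k, (_, r) in LEAF_CATEGORIES.items()}
        for leaf, (lo, hi) in ranges.items():
            if leaf in FUNCTION_WORD_LEAVES:
                ranges[leaf] = (0.5 * lo, min(1.4 * hi, 0.12))
            else:
                ranges[leaf] = (0.5 * lo, 0.6 * hi)
        cfg = GeneratorConfig(
            n_pairs=500, seed=7, category_rate_ranges=ranges,
            synchrony_controls=SynchronyControls(lsm_strength=0.0),
            outcome_model=OutcomeModel(coefficients={"lsm_mean": 0.8},
                                       centers={"lsm_mean": 0.85}))
        corpus, truth = generate_corpus(cfg)
        votes = [p.helpful_votes for p in corpus]
        rho, _ = stats.spearmanr(truth.synchrony["lsm_mean"], votes)
        assert rho > 0

    def test_outcome_calibration_zero_effects(self):
        """With all coefficients zero, mean(votes - 1) estimates
        exp(intercept) = 3.362 within 3 standard errors."""
        cfg = GeneratorConfig(n_pairs=4000, seed=3,
                              outcome_model=OutcomeModel())
        corpus, _ = generate_corpus(cfg)
        excess = np.array([p.helpful_votes - 1 for p in corpus], float)
        se = excess.std(ddof=1) / np.sqrt(len(excess))
        assert abs(excess.mean() - 3.362) < 3 * se

    def test_category_proportions_converge_to_truth(self):
        """Empirical category proportions on 2000-token documents deviate
        from the latent rates by < 2 percentage points on average."""
        lex = default_lexicon()
        matcher = lex.matcher()
        leaf_cols = {col: leaves[0] for col, leaves in
                     DICTIONARY_LAYOUT.items() if len(leaves) == 1}
        devs = []
        for seed in range(1, 6):
            cfg = GeneratorConfig(n_pairs=6, seed=seed,
                                  question_length_mean=2000,
                                  response_length_mean=2000)
            corpus, truth = generate_corpus(cfg)
            for i, p in enumerate(corpus):
                props, _ = category_proportions(p.response_tokens, lex,
                                                matcher)
                for col, leaf in leaf_cols.items():
                    true_pct = 100.0 * truth.response_rates.iloc[i][leaf]
                    devs.append(abs(props[col] - true_pct))
        assert np.mean(devs) < 2.0


class TestConfigValidation:
    def test_negative_n_pairs_names_field(self):
        with pytest.raises(ConfigError, match="n_pairs"):
            generate_corpus(GeneratorConfig(n_pairs=-1))

    def test_bad_probability_names_field(self):
        cfg = GeneratorConfig(
            synchrony_controls=SynchronyControls(topic_overlap=1.5))
        with pytest.raises(ConfigError, match="topic_overlap"):
            generate_corpus(cfg)

    def test_bad_rate_range_names_leaf(self):
        ranges = {k: r for k, (_, r) in LEAF_CATEGORIES.items()}
        ranges["anx"] = (0.5, 0.2)
        with pytest.raises(ConfigError, match="anx"):
            generate_corpus(GeneratorConfig(category_rate_ranges=ranges))

    def test_unknown_outcome_feature_rejected(self):
        cfg = GeneratorConfig(
            outcome_model=OutcomeModel(coefficients={"nonsense": 1.0}))
        with pytest.raises(ConfigError, match="nonsense"):
            generate_corpus(cfg)

    def test_negative_length_rejected(self):
        with pytest.raises(ConfigError, match="question_length_mean"):
            generate_corpus(GeneratorConfig(question_length_mean=-5))


class TestCorpusIO:
    def test_roundtrip_identity(self, tmp_path, tiny_corpus):
        path = tmp_path / "c.jsonl"
        n = write_corpus(tiny_corpus, path)
        assert n == 2
        back = read_corpus(path)
        for a, b in zip(tiny_corpus, back):
            assert a.pair_id == b.pair_id
            assert a.question_raw == b.question_raw
            assert a.response_raw == b.response_raw
            assert a.helpful_votes == b.helpful_votes
            assert a.question_tokens == b.question_tokens

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_corpus(path) == []

    def test_missing_votes_cites_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"pair_id": "a", "question_raw": "x", "response_raw": "y",'
            ' "helpful_votes": 2}\n'
            '{"pair_id": "b", "question_raw": "x", "response_raw": "y"}\n')
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_corpus(path)

    def test_invalid_json_cites_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text("not json at all\n")
        with pytest.raises(CorpusFormatError, match="line 1"):
            read_corpus(path)

    def test_negative_votes_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"pair_id": "a", "question_raw": "x",'
                        ' "response_raw": "y", "helpful_votes": -2}\n')
        with pytest.raises(CorpusFormatError):
            read_corpus(path)
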
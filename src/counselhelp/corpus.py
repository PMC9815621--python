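"""Seeded synthetic Q&A corpora with known psycholinguistic structure.

Each generated pair couples a counselee question with a counselor response.
Documents are token streams over a synthetic pseudo-word vocabulary: every
leaf category (function words, emotion words, cognitive words, topic words,
filler, ...) has a per-document emission probability, so the latent
category rates — and hence every downstream feature — are known exactly.

Dyadic synchrony is controllable: the response's function-word and emotion
rates are convex mixtures of the question's rates and fresh draws
(``lsm_strength`` / ``emotion_corr``), and response topics inherit
question topics with probability ``topic_overlap``.

Helpful votes follow ``1 + Poisson(exp(eta))`` (optionally negative
binomial), where ``eta`` is a linear predictor over named latent
quantities; the observed support therefore starts at 1, matching vote
counts on real Q&A counseling platforms (range 1-39, mean 4.362 in the
data these conditions emulate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import vocab
from .lexicon import tokenize

__all__ = [
    "ConfigError", "CorpusFormatError", "OutcomeModel", "SynchronyControls",
    "GeneratorConfig", "QAPair", "GroundTruth", "generate_corpus",
    "write_corpus", "read_corpus", "default_outcome_model",
]


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class CorpusFormatError(ValueError):
    """Malformed corpus record; message cites the line number."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModel:
    """Log-link count model for helpful votes.

    ``eta = intercept + sum_f coef_f * (x_f - center_f)`` and votes are
    ``1 + Poisson(exp(eta))`` (or negative binomial with ``dispersion``,
    the NB2 size parameter; smaller = more overdispersed).

    Recognised feature names: ``lsm_mean``, ``affect_sim``,
    ``symptoms_sim``, ``factors_sim``, ``q_length100``, ``r_length100``
    (document length / 100), and ``q_rate:<leaf>`` / ``r_rate:<leaf>``
    (latent leaf-category rate on the percent scale).
    """

    intercept: float = math.log(3.362)   # mean votes 1 + 3.362 = 4.362
    coefficients: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    noise: str = "poisson"               # "poisson" | "negbin"
    dispersion: float | None = None      # required for negbin

    def validate(self) -> None:
        if self.noise not in ("poisson", "negbin"):
            raise ConfigError(f"outcome_model.noise: unknown value {self.noise!r}")
        if self.noise == "negbin" and (self.dispersion is None
                                       or self.dispersion <= 0):
            raise ConfigError("outcome_model.dispersion: must be > 0 for negbin")
        known_prefixes = ("q_rate:", "r_rate:")
        known = {"lsm_mean", "affect_sim", "symptoms_sim", "factors_sim",
                 "q_length100", "r_length100"}
        for name in self.coefficients:
            if name in known:
                continue
            if name.startswith(known_prefixes):
                leaf = name.split(":", 1)[1]
                if leaf not in vocab.LEAF_CATEGORIES:
                    raise ConfigError(
                        f"outcome_model.coefficients[{name!r}]: unknown leaf")
                continue
            raise ConfigError(
                f"outcome_model.coefficients[{name!r}]: unknown feature")


@dataclass(frozen=True)
class SynchronyControls:
    """Dyadic coupling strengths, all in [0, 1]."""

    topic_overlap: float = 0.7       # P(response keeps an active question topic)
    topic_background: float = 0.1    # P(response activates any topic anew)
    lsm_strength: float = 0.7        # function-word rate mixing weight
    emotion_corr: float = 0.6        # emotion-leaf rate mixing weight

    def validate(self) -> None:
        for f in ("topic_overlap", "topic_background", "lsm_strength",
                  "emotion_corr"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"synchrony_controls.{f}: {v} not in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full study conditions for one synthetic corpus."""

    n_pairs: int = 200
    question_length_mean: float = 185.0   # tokens
    response_length_mean: float = 388.0
    sentence_length_mean: float = 14.0
    extra_punct_rate: float = 0.15        # per-sentence chance of a colon etc.
    #: per-leaf uniform rate ranges; defaults from the vocabulary spec
    category_rate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: r for k, (_, r)
                                 in vocab.LEAF_CATEGORIES.items()})
    question_topic_rate: float = 0.35     # P(topic active in question)
    topic_rate_range: tuple[float, float] = (0.004, 0.012)
    synchrony_controls: SynchronyControls = field(
        default_factory=SynchronyControls)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise ConfigError(f"n_pairs: {self.n_pairs} must be >= 0")
        for f in ("question_length_mean", "response_length_mean",
                  "sentence_length_mean"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f}: must be positive")
        if not (0.0 <= self.extra_punct_rate <= 1.0):
            raise ConfigError("extra_punct_rate: not in [0, 1]")
        if not (0.0 <= self.question_topic_rate <= 1.0):
            raise ConfigError("question_topic_rate: not in [0, 1]")
        total_hi = 0.0
        for leaf, (lo, hi) in self.category_rate_ranges.items():
            if leaf not in vocab.LEAF_CATEGORIES:
                raise ConfigError(f"category_rate_ranges[{leaf!r}]: unknown leaf")
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(
                    f"category_rate_ranges[{leaf!r}]: ({lo}, {hi}) invalid")
            total_hi += hi
        lo, hi = self.topic_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"topic_rate_range: ({lo}, {hi}) invalid")
        total_hi += hi * 2 * vocab.N_TOPICS
        if total_hi > 0.98:
            raise ConfigError(
                f"category_rate_ranges: worst-case rate sum {total_hi:.3f} "
                "exceeds 0.98; no filler mass left")
        self.synchrony_controls.validate()
        self.outcome_model.validate()


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class QAPair:
    """One counselee question + counselor response + vote count."""

    pair_id: str
    question_raw: str
    response_raw: str
    helpful_votes: int
    question_tokens: list[str] = field(default_factory=list, repr=False)
    response_tokens: list[str] = field(default_factory=list, repr=False)

    @classmethod
    def from_raw(cls, pair_id: str, question_raw: str, response_raw: str,
                 helpful_votes: int) -> "QAPair":
        if helpful_votes < 0:
            raise CorpusFormatError(
                f"pair {pair_id}: helpful_votes must be >= 0")
        return cls(pair_id, question_raw, response_raw, int(helpful_votes),
                   tokenize(question_raw).tokens, tokenize(response_raw).tokens)


@dataclass
class GroundTruth:
    """Latent quantities behind a generated corpus.

    Rate-level fields store *expected* rates (not realized counts); topic
    incidence is the realized, token-backed incidence.  ``features`` holds
    every quantity the outcome model may reference, one row per pair.
    """

    question_rates: pd.DataFrame     # per-leaf expected rates (fractions)
    response_rates: pd.DataFrame
    question_symptom: np.ndarray     # (n, 7) binary, token-backed
    response_symptom: np.ndarray
    question_factor: np.ndarray
    response_factor: np.ndarray
    synchrony: pd.DataFrame          # lsm_mean, affect_sim, symptoms/factors_sim
    features: pd.DataFrame           # outcome-model feature values
    eta: np.ndarray                  # linear predictor
    expected_rate: np.ndarray        # exp(eta), the (votes - 1) mean
    coefficients: dict[str, float]

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_EXTRA_PUNCT = [":", '"', "(", ")", ";"]


def _draw_rates(rng: np.random.Generator,
                ranges: dict[str, tuple[float, float]]) -> dict[str, float]:
    return {leaf: float(rng.uniform(lo, hi))
            for leaf, (lo, hi) in ranges.items()}


def _mix_rates(rng: np.random.Generator, q_rates: dict[str, float],
               ranges: dict[str, tuple[float, float]],
               weights: dict[str, float]) -> dict[str, float]:
    """Response rates: per-leaf convex mixture of question rate + fresh draw."""
    out = {}
    for leaf, (lo, hi) in ranges.items():
        w = weights.get(leaf, 0.0)
        fresh = float(rng.uniform(lo, hi))
        out[leaf] = w * q_rates[leaf] + (1.0 - w) * fresh
    return out


def _emit_document(rng: np.random.Generator, length: int,
                   rates: dict[str, float],
                   topic_rates: dict[tuple[str, int], float],
                   cfg: GeneratorConfig) -> tuple[str, list[str]]:
    """Emit one document: returns (raw text, word tokens)."""
    names = list(rates) + [f"topic/{p}/{i}" for (p, i) in topic_rates]
    probs = list(rates.values()) + list(topic_rates.values())
    filler = 1.0 - sum(probs)
    probs.append(filler)
    counts = rng.multinomial(length, probs)
    words: list[str] = []
    pools = [vocab.leaf_pool(n) for n in rates]
    pools += [vocab.topic_pool(p, i) for (p, i) in topic_rates]
    pools.append(vocab.filler_pool())
    for pool, cnt in zip(pools, counts):
        if cnt:
            idx = rng.integers(0, len(pool), size=cnt)
            words.extend(pool[j] for j in idx)
    rng.shuffle(words)
    # sentence assembly: geometric sentence lengths, '.' terminators
    symbols: list[str] = []
    i = 0
    p_stop = 1.0 / cfg.sentence_length_mean
    while i < len(words):
        slen = int(rng.geometric(p_stop))
        sent = words[i:i + slen]
        i += slen
        symbols.extend(sent)
        if rng.random() < cfg.extra_punct_rate:
            symbols.append(_EXTRA_PUNCT[int(rng.integers(len(_EXTRA_PUNCT)))])
        symbols.append(".")
    return " ".join(symbols), words


def _incidence_from_tokens(words: Sequence[str], partition: str) -> np.ndarray:
    vec = np.zeros(vocab.N_TOPICS, dtype=np.int64)
    pools = [set(vocab.topic_pool(partition, i)) for i in range(vocab.N_TOPICS)]
    wset = set(words)
    for i, pool in enumerate(pools):
        if wset & pool:
            vec[i] = 1
    return vec


def _lsm_percentages(rates: dict[str, float]) -> dict[str, float]:
    """Expected function-word category percentages from leaf rates."""
    out = {}
    for cat in vocab.LSM_CATEGORIES:
        leaves = vocab.DICTIONARY_LAYOUT[cat]
        out[cat] = 100.0 * sum(rates[l] for l in leaves)
    return out


def _emotion_vector(rates: dict[str, float]) -> np.ndarray:
    vec = []
    for cat in vocab.EMOTION_CATEGORIES:
        leaves = vocab.DICTIONARY_LAYOUT[cat]
        vec.append(100.0 * sum(rates[l] for l in leaves))
    return np.asarray(vec)


def _true_synchrony(q_rates, r_rates, q_sym, r_sym, q_fac, r_fac):
    # local imports avoid a cycle: synchrony_metrics depends on nothing here
    from .synchrony import (composite_lsm, emotional_similarity,
                            jaccard_binary)
    lq = _lsm_percentages(q_rates)
    lr = _lsm_percentages(r_rates)
    _, lsm_mean = composite_lsm(lq, lr, vocab.LSM_CATEGORIES)
    affect = emotional_similarity(_emotion_vector(q_rates),
                                  _emotion_vector(r_rates))
    return {
        "lsm_mean": lsm_mean,
        "affect_sim": affect,
        "symptoms_sim": jaccard_binary(q_sym, r_sym),
        "factors_sim": jaccard_binary(q_fac, r_fac),
    }


def generate_corpus(config: GeneratorConfig) -> tuple[list[QAPair], GroundTruth]:
    """Generate ``config.n_pairs`` question/response pairs plus ground truth.

    Deterministic: a fixed config (including seed) yields byte-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    sc = config.synchrony_controls
    ranges = config.category_rate_ranges

    func_leaves = set(vocab.FUNCTION_WORD_LEAVES)
    emo_leaves = set(vocab.DICTIONARY_LAYOUT["Affect"])
    mix_w = {leaf: (sc.lsm_strength if leaf in func_leaves else
                    sc.emotion_corr if leaf in emo_leaves else 0.0)
             for leaf in ranges}

    pairs: list[QAPair] = []
    q_rate_rows, r_rate_rows = [], []
    q_sym, r_sym, q_fac, r_fac = [], [], [], []
    sync_rows, feat_rows = [], []

    tlo, thi = config.topic_rate_range
    for k in range(n):
        q_rates = _draw_rates(rng, ranges)
        r_rates = _mix_rates(rng, q_rates, ranges, mix_w)

        incid = {}
        topic_rates_q: dict[tuple[str, int], float] = {}
        topic_rates_r: dict[tuple[str, int], float] = {}
        for part in ("symptom", "factor"):
            qa = rng.random(vocab.N_TOPICS) < config.question_topic_rate
            keep = rng.random(vocab.N_TOPICS) < sc.topic_overlap
            new = rng.random(vocab.N_TOPICS) < sc.topic_background
            ra = (qa & keep) | new
            incid[part] = (qa, ra)
            for i in range(vocab.N_TOPICS):
                if qa[i]:
                    topic_rates_q[(part, i)] = float(rng.uniform(tlo, thi))
                if ra[i]:
                    topic_rates_r[(part, i)] = float(rng.uniform(tlo, thi))

        q_len = max(10, int(rng.poisson(config.question_length_mean)))
        r_len = max(10, int(rng.poisson(config.response_length_mean)))
        q_raw, q_words = _emit_document(rng, q_len, q_rates, topic_rates_q,
                                        config)
        r_raw, r_words = _emit_document(rng, r_len, r_rates, topic_rates_r,
                                        config)

        qs = _incidence_from_tokens(q_words, "symptom")
        rs = _incidence_from_tokens(r_words, "symptom")
        qf = _incidence_from_tokens(q_words, "factor")
        rf = _incidence_from_tokens(r_words, "factor")

        sync = _true_synchrony(q_rates, r_rates, qs, rs, qf, rf)

        feats = dict(sync)
        feats["q_length100"] = q_len / 100.0
        feats["r_length100"] = r_len / 100.0
        for leaf, v in q_rates.items():
            feats[f"q_rate:{leaf}"] = 100.0 * v
        for leaf, v in r_rates.items():
            feats[f"r_rate:{leaf}"] = 100.0 * v

        om = config.outcome_model
        eta = om.intercept
        for name, coef in om.coefficients.items():
            eta += coef * (feats[name] - om.centers.get(name, 0.0))
        mu = math.exp(eta)
        if om.noise == "poisson":
            votes = 1 + int(rng.poisson(mu))
        else:
            size = om.dispersion
            p = size / (size + mu)
            votes = 1 + int(rng.negative_binomial(size, p))

        pairs.append(QAPair(f"pair{k:06d}", q_raw, r_raw, votes,
                            q_words, r_words))
        q_rate_rows.append(q_rates)
        r_rate_rows.append(r_rates)
        q_sym.append(qs); r_sym.append(rs); q_fac.append(qf); r_fac.append(rf)
        sync_rows.append(sync)
        feats["eta"] = eta
        feat_rows.append(feats)

    feat_df = pd.DataFrame(feat_rows) if feat_rows else pd.DataFrame()
    eta_arr = (feat_df.pop("eta").to_numpy() if "eta" in feat_df
               else np.zeros(0))
    truth = GroundTruth(
        question_rates=pd.DataFrame(q_rate_rows),
        response_rates=pd.DataFrame(r_rate_rows),
        question_symptom=np.asarray(q_sym, dtype=np.int64).reshape(n, -1)
        if n else np.zeros((0, vocab.N_TOPICS), dtype=np.int64),
        response_symptom=np.asarray(r_sym, dtype=np.int64).reshape(n, -1)
        if n else np.zeros((0, vocab.N_TOPICS), dtype=np.int64),
        question_factor=np.asarray(q_fac, dtype=np.int64).reshape(n, -1)
        if n else np.zeros((0, vocab.N_TOPICS), dtype=np.int64),
        response_factor=np.asarray(r_fac, dtype=np.int64).reshape(n, -1)
        if n else np.zeros((0, vocab.N_TOPICS), dtype=np.int64),
        synchrony=pd.DataFrame(sync_rows),
        features=feat_df,
        eta=eta_arr,
        expected_rate=np.exp(eta_arr),
        coefficients=dict(config.outcome_model.coefficients),
    )
    return pairs, truth


def default_outcome_model() -> OutcomeModel:
    """Planted-effect outcome model used by the analysis pipeline.

    Effects load on counselor emotion/cognition rates, dyadic synchrony,
    and counselee verbosity; centers are rough expectations under the
    default rate ranges so mean votes stay near 4.36.
    """
    mid = {leaf: 100.0 * (lo + hi) / 2.0
           for leaf, (lo, hi) in
           ((k, r) for k, (_, r) in vocab.LEAF_CATEGORIES.items())}
    coefficients = {
        "lsm_mean": 1.0,
        "affect_sim": 0.6,
        "symptoms_sim": 0.5,
        "r_rate:posfeel": 0.15,
        "r_rate:insight": 0.20,
        "r_rate:i": 0.10,
        "q_length100": 0.08,
    }
    # centers = latent expectations under the default ranges (measured on a
    # large zero-effect reference run) so the intercept keeps its meaning
    centers = {
        "lsm_mean": 0.95,
        "affect_sim": 0.996,
        "symptoms_sim": 0.45,
        "r_rate:posfeel": mid["posfeel"],
        "r_rate:insight": mid["insight"],
        "r_rate:i": mid["i"],
        "q_length100": 1.85,
    }
    return OutcomeModel(coefficients=coefficients, centers=centers)


# ---------------------------------------------------------------------------
# Corpus IO: JSON Lines, one record per pair
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("pair_id", "question_raw", "response_raw", "helpful_votes")


def write_corpus(corpus: Iterable[QAPair], destination: str | Path) -> int:
    """Write pairs as JSON Lines; returns the record count."""
    path = Path(destination)
    count = 0
    with path.open("w", encoding="utf-8") as fh:
        for p in corpus:
            rec = {"pair_id": p.pair_id, "question_raw": p.question_raw,
                   "response_raw": p.response_raw,
                   "helpful_votes": p.helpful_votes}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            count += 1
    return count


def read_corpus(source: str | Path) -> list[QAPair]:
    """Read a JSON Lines corpus; inverse of :func:`write_corpus`."""
    pairs = []
    with Path(source).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"line {lineno}: invalid JSON ({exc.msg})") from None
            for f in _REQUIRED_FIELDS:
                if f not in rec:
                    raise CorpusFormatError(
                        f"line {lineno}: missing field {f!r}")
            if not isinstance(rec["helpful_votes"], int) \
                    or rec["helpful_votes"] < 0:
                raise CorpusFormatError(
                    f"line {lineno}: helpful_votes must be a non-negative "
                    "integer")
            pairs.append(QAPair.from_raw(rec["pair_id"], rec["question_raw"],
                                         rec["response_raw"],
                                         rec["helpful_votes"]))
    return pairs
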
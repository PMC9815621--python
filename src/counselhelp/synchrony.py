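"""Counselor-counselee synchrony statistics.

Three dyadic measures, each scored per question/response pair:

* **Topic consistency** — Jaccard similarity ``|R ∩ M| / |R ∪ M|`` between
  the binary topic-incidence vectors of the question (R) and response (M),
  computed separately over symptom topics and factor topics.
* **Language style matching (LSM)** — per function-word category
  ``1 - |p1 - p2| / (p1 + p2 + 0.0001)`` on the percentage scale, averaged
  over the nine function-word categories (prepositions, auxiliary verbs,
  adverbs, conjunctions, articles, quantifiers, negations, personal and
  impersonal pronouns).  The 0.0001 smoothing keeps the score defined (and
  equal to 1) when neither speaker uses a category.
* **Emotional similarity** — cosine similarity between the two speakers'
  7-dimension emotion-category rate vectors; a proxy for expressed empathy.

All three are symmetric and bounded in [0, 1].  Degenerate inputs (empty
topic union, all-zero emotion vector) score 0.0 and are flagged rather
than treated as perfect agreement: absence of signal is not evidence of
synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import vocab

__all__ = [
    "LSM_SMOOTHING", "SynchronyScores", "jaccard_binary",
    "jaccard_topic_consistency", "lsm_category", "composite_lsm",
    "emotional_similarity", "append_synchrony",
]

#: smoothing constant in the LSM denominator, applied on the percent scale.
LSM_SMOOTHING = 1e-4


@dataclass
class SynchronyScores:
    symptoms_sim: float
    factors_sim: float
    lsm_by_category: dict[str, float]
    lsm_mean: float
    affect_sim: float
    degenerate: bool = False


def jaccard_binary(r: Sequence[int] | np.ndarray,
                   m: Sequence[int] | np.ndarray) -> float:
    """Jaccard similarity of two equal-length binary vectors.

    Empty union (both all-zero) scores 0.0 — see module docstring.
    """
    r = np.asarray(r, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if r.shape != m.shape:
        raise ValueError(
            f"incidence length mismatch: {r.shape} vs {m.shape}")
    union = int(np.sum(r | m))
    if union == 0:
        return 0.0
    return float(np.sum(r & m)) / union


def jaccard_topic_consistency(r, m, partition_r: str | None = None,
                              partition_m: str | None = None) -> float:
    """Topic consistency between a question and response incidence vector.

    If partition tags are given they must match (symptom vs factor topics
    are never compared against each other).
    """
    if partition_r is not None or partition_m is not None:
        if partition_r != partition_m:
            raise ValueError(
                f"partition mismatch: {partition_r!r} vs {partition_m!r}")
    return jaccard_binary(r, m)


def lsm_category(p1: float, p2: float) -> float:
    """Style-matching score for one function-word category.

    Inputs are category percentages in [0, 100].  Equal rates score 1;
    fully one-sided use scores near 0.
    """
    if p1 < 0 or p2 < 0:
        raise ValueError(f"negative category percentage: ({p1}, {p2})")
    return 1.0 - abs(p1 - p2) / (p1 + p2 + LSM_SMOOTHING)


def composite_lsm(props1: Mapping[str, float], props2: Mapping[str, float],
                  category_group: Sequence[str] | None = None,
                  ) -> tuple[dict[str, float], float]:
    """Per-category LSM scores and their unweighted mean.

    ``category_group`` defaults to the nine standard function-word
    categories; a configuration that declares a category absent (e.g. no
    articles in a Chinese-style dictionary) passes a shorter group
    explicitly rather than having it silently skipped.
    """
    group = list(category_group) if category_group is not None \
        else list(vocab.LSM_CATEGORIES)
    if not group:
        raise ValueError("empty LSM category group")
    scores = {}
    for cat in group:
        if cat not in props1 or cat not in props2:
            raise KeyError(f"LSM category {cat!r} missing from proportions")
        scores[cat] = lsm_category(props1[cat], props2[cat])
    return scores, float(np.mean(list(scores.values())))


def emotional_similarity(e1: Sequence[float] | np.ndarray,
                         e2: Sequence[float] | np.ndarray) -> float:
    """Cosine similarity of two non-negative emotion-rate vectors.

    Either vector all-zero scores 0.0 (no expressed emotion, no measurable
    similarity).
    """
    a = np.asarray(e1, dtype=float)
    b = np.asarray(e2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"emotion vector shape mismatch: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("emotion vectors must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def score_pair(q_props: Mapping[str, float], r_props: Mapping[str, float],
               q_sym, r_sym, q_fac, r_fac,
               lsm_group: Sequence[str] | None = None) -> SynchronyScores:
    """All synchrony scores for one pair from category proportions and
    topic incidence vectors."""
    by_cat, mean = composite_lsm(q_props, r_props, lsm_group)
    e1 = np.array([q_props[c] for c in vocab.EMOTION_CATEGORIES])
    e2 = np.array([r_props[c] for c in vocab.EMOTION_CATEGORIES])
    sym = jaccard_topic_consistency(q_sym, r_sym)
    fac = jaccard_topic_consistency(q_fac, r_fac)
    degenerate = (int(np.sum(np.asarray(q_sym) | np.asarray(r_sym))) == 0
                  or int(np.sum(np.asarray(q_fac) | np.asarray(r_fac))) == 0
                  or np.linalg.norm(e1) == 0 or np.linalg.norm(e2) == 0)
    return SynchronyScores(sym, fac, by_cat, mean,
                           emotional_similarity(e1, e2), degenerate)


def append_synchrony(table, corpus, symptom_lexicons: Mapping[str, set],
                     factor_lexicons: Mapping[str, set],
                     lsm_group: Sequence[str] | None = None):
    """Append synchrony columns (source tag ``synchrony``) to a feature table.

    ``table`` is a :class:`~counselhelp.features.FeatureTable` whose rows
    align with ``corpus``; topic incidence is recomputed lexically from the
    given topic lexicons.
    """
    from .features import FeatureTable  # cycle guard
    from .topics import topic_incidence

    if len(table.data) != len(corpus):
        raise ValueError(
            f"feature table has {len(table.data)} rows but corpus has "
            f"{len(corpus)} pairs")
    group = list(lsm_group) if lsm_group is not None \
        else list(vocab.LSM_CATEGORIES)

    rows = []
    n_degenerate = 0
    for i, pair in enumerate(corpus):
        q_props = {c: table.data.iloc[i][f"counselee:{c}"]
                   for c in set(group) | set(vocab.EMOTION_CATEGORIES)}
        r_props = {c: table.data.iloc[i][f"counselor:{c}"]
                   for c in set(group) | set(vocab.EMOTION_CATEGORIES)}
        q_sym = topic_incidence(pair.question_tokens, symptom_lexicons).vector
        r_sym = topic_incidence(pair.response_tokens, symptom_lexicons).vector
        q_fac = topic_incidence(pair.question_tokens, factor_lexicons).vector
        r_fac = topic_incidence(pair.response_tokens, factor_lexicons).vector
        s = score_pair(q_props, r_props, q_sym, r_sym, q_fac, r_fac, group)
        if s.degenerate:
            n_degenerate += 1
        row = {"sync:SymptomsSIM": s.symptoms_sim,
               "sync:FactorsSIM": s.factors_sim,
               "sync:AffectSIM": s.affect_sim,
               "sync:LSM_mean": s.lsm_mean}
        for cat, v in s.lsm_by_category.items():
            row[f"sync:LSM_{cat}"] = v
        rows.append(row)

    sync_df = pd.DataFrame(rows, index=table.data.index)
    tags = dict(table.tags)
    for col in sync_df.columns:
        name = col.split(":", 1)[1]
        if name in ("SymptomsSIM", "FactorsSIM", "AffectSIM"):
            tags[col] = ("synchrony", name)
        else:
            tags[col] = ("synchrony", "LSM")
    out = FeatureTable(data=pd.concat([table.data, sync_df], axis=1),
                       tags=tags)
    out.n_degenerate_pairs = n_degenerate
    return out
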
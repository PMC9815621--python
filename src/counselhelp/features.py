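"""LIWC-style category proportions and stylistic counters.

A document's psycholinguistic profile is the percentage of its word
tokens falling in each dictionary category (a token may count toward
several categories), plus dictionary-free stylistic counters: word count,
sentence statistics, punctuation tallies, numeral rate, and the share of
long (>= 4 symbol) tokens.

Percentages use word tokens as the denominator — punctuation is excluded,
following LIWC convention — and are therefore invariant to duplicating
the document.  An empty document yields all-zero proportions with an
explicit flag rather than NaNs.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import CategoryLexicon, LexiconMatcher, TokenSequence, tokenize

__all__ = [
    "StylisticCounts", "FeatureTable", "category_proportions",
    "stylistic_features", "build_feature_table",
]

_NUMERAL_RE = re.compile(r"^\d+$")


# ---------------------------------------------------------------------------
# Per-document operations
# ---------------------------------------------------------------------------

def category_proportions(tokens: TokenSequence | Sequence[str],
                         lexicon: CategoryLexicon,
                         matcher: LexiconMatcher | None = None,
                         ) -> tuple[dict[str, float], bool]:
    """Percentage of word tokens matching each lexicon category.

    Returns ``(proportions, empty_flag)``; the flag marks an empty
    document (all proportions zero by convention).
    """
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    words = tokens.tokens if isinstance(tokens, TokenSequence) else list(tokens)
    props = {c: 0.0 for c in lexicon.names}
    if not words:
        return props, True
    m = matcher if matcher is not None else lexicon.matcher()
    counts = {c: 0 for c in lexicon.names}
    for w, k in Counter(words).items():
        for c in m.categories_of(w):
            counts[c] += k
    denom = len(words)
    for c in counts:
        props[c] = 100.0 * counts[c] / denom
    return props, False


@dataclass
class StylisticCounts:
    """Dictionary-free stylistic profile of one document."""

    word_count: int = 0
    sentence_count: int = 0
    words_per_sentence: float = 0.0
    periods: int = 0
    colons: int = 0
    quotes: int = 0
    parentheses: int = 0
    other_punct: int = 0
    rate_four_char: float = 0.0   # % of tokens with >= 4 symbols
    numerals: float = 0.0         # % of tokens that are pure digits

    def as_columns(self) -> dict[str, float]:
        return {
            "WordCount": float(self.word_count),
            "SentenceCount": float(self.sentence_count),
            "WordPerSentence": self.words_per_sentence,
            "Period": float(self.periods),
            "Colon": float(self.colons),
            "Quote": float(self.quotes),
            "Parenth": float(self.parentheses),
            "OtherP": float(self.other_punct),
            "RateFourCharWord": self.rate_four_char,
            "Numerals": self.numerals,
        }


def stylistic_features(raw: str, tokens: TokenSequence | None = None,
                       ) -> StylisticCounts:
    """Stylistic counters for one document.

    ``tokens`` must be the registered tokenizer's output for ``raw``; it
    is recomputed when omitted.  A non-empty document with no terminal
    punctuation counts as one sentence.
    """
    seq = tokens if tokens is not None else tokenize(raw)
    wc = seq.n_words
    sc = seq.n_sentences
    counts = StylisticCounts(word_count=wc, sentence_count=sc)
    counts.words_per_sentence = wc / max(sc, 1)
    for p in seq.punctuation_marks:
        if p == ".":
            counts.periods += 1
        elif p == ":":
            counts.colons += 1
        elif p in ('"', "'", "“", "”"):
            counts.quotes += 1
        elif p in ("(", ")"):
            counts.parentheses += 1
        else:
            counts.other_punct += 1
    if wc:
        counts.rate_four_char = 100.0 * sum(
            1 for t in seq.tokens if len(t) >= 4) / wc
        counts.numerals = 100.0 * sum(
            1 for t in seq.tokens if _NUMERAL_RE.match(t)) / wc
    return counts


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Per-pair numeric features with (source, type) column tags.

    ``data`` rows follow corpus order; ``tags`` maps every column to its
    ``(source, type)`` pair, source in {counselee, counselor, synchrony}.
    """

    data: pd.DataFrame
    tags: dict[str, tuple[str, str]]
    empty_documents: list[str] = field(default_factory=list)
    n_degenerate_pairs: int = 0

    def columns_for_source(self, sources: Iterable[str]) -> list[str]:
        wanted = set(sources)
        return [c for c in self.data.columns
                if self.tags[c][0] in wanted]

    def columns_for_type(self, type_name: str) -> list[str]:
        return [c for c in self.data.columns
                if self.tags[c][1] == type_name]

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` plus sidecar ``<prefix>.tags.csv``."""
        prefix = Path(prefix)
        data_path = prefix.with_suffix(".csv")
        tag_path = prefix.with_name(prefix.name + ".tags.csv")
        self.data.to_csv(data_path, index=False)
        pd.DataFrame(
            [{"column": c, "source": s, "type": t}
             for c, (s, t) in self.tags.items()]
        ).to_csv(tag_path, index=False)
        return data_path, tag_path

    @classmethod
    def read(cls, prefix: str | Path) -> "FeatureTable":
        prefix = Path(prefix)
        data = pd.read_csv(prefix.with_suffix(".csv"))
        tag_df = pd.read_csv(prefix.with_name(prefix.name + ".tags.csv"))
        tags = {r.column: (r.source, r.type) for r in tag_df.itertuples()}
        return cls(data=data, tags=tags)


def build_feature_table(corpus, lexicon: CategoryLexicon,
                        group_map: Mapping[str, tuple[str, str]],
                        ) -> FeatureTable:
    """Assemble the per-pair feature table for both speakers.

    Counselee columns come from the question, counselor columns from the
    response; synchrony columns are appended later by
    :func:`counselhelp.synchrony.append_synchrony`.  Every emitted column
    must be covered by ``group_map`` (source and type tags), otherwise an
    error names the missing feature.
    """
    matcher = lexicon.matcher()
    rows = []
    empty_docs: list[str] = []
    for pair in corpus:
        row: dict[str, float] = {}
        for prefix, raw in (("counselee", pair.question_raw),
                            ("counselor", pair.response_raw)):
            seq = tokenize(raw)
            props, is_empty = category_proportions(seq, lexicon, matcher)
            if is_empty:
                empty_docs.append(f"{pair.pair_id}:{prefix}")
            for cat, v in props.items():
                row[f"{prefix}:{cat}"] = v
            for col, v in stylistic_features(raw, seq).as_columns().items():
                row[f"{prefix}:{col}"] = v
        rows.append(row)

    data = pd.DataFrame(rows)
    if data.empty and len(list(corpus)) == 0:
        data = pd.DataFrame()
    tags = {}
    for col in data.columns:
        if col not in group_map:
            raise KeyError(
                f"feature {col!r} missing from group map")
        tags[col] = tuple(group_map[col])
    return FeatureTable(data=data, tags=tags, empty_documents=empty_docs)
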
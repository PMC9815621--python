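"""Deterministic word embeddings from co-occurrence statistics.

Words are embedded by factorizing a positive pointwise-mutual-information
(PPMI) co-occurrence matrix with truncated SVD — the classic spectral
route to distributional semantics.  It is count-based and fully
deterministic under a fixed seed (the SVD's randomized initialisation is
seeded), which the reproducibility contract here values over the
stochastic-gradient alternative.

``window`` counts neighbours on each side; ``window=0`` means whole-
document co-occurrence (LSA-style), which suits topic detection where
document-level association is the signal of interest.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import TruncatedSVD

__all__ = ["EmbeddingParams", "Embedding", "train_embedding", "cosine"]


@dataclass(frozen=True)
class EmbeddingParams:
    dimension: int = 50
    window: int = 0          # 0 = whole document
    min_count: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.dimension < 2:
            raise ValueError(f"dimension {self.dimension} must be >= 2")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class Embedding:
    """Vocabulary-indexed dense word vectors."""

    vocabulary: dict[str, int]
    vectors: np.ndarray          # (V, dimension)
    params: EmbeddingParams

    def __contains__(self, word: str) -> bool:
        return word in self.vocabulary

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocabulary[word]]

    @property
    def words(self) -> list[str]:
        inv = sorted(self.vocabulary, key=self.vocabulary.get)
        return inv

    def similarity(self, w1: str, w2: str) -> float:
        return cosine(self.vector(w1), self.vector(w2))


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _cooccurrence(docs: Sequence[Sequence[str]], vocab: dict[str, int],
                  window: int) -> sparse.csr_matrix:
    v = len(vocab)
    counts: Counter = Counter()
    for doc in docs:
        ids = [vocab[w] for w in doc if w in vocab]
        if window == 0:
            doc_counts = Counter(ids)
            items = list(doc_counts.items())
            for a, ca in items:
                for b, cb in items:
                    if a == b:
                        if ca > 1:
                            counts[(a, a)] += ca * (ca - 1)
                    else:
                        counts[(a, b)] += ca * cb
        else:
            for i, a in enumerate(ids):
                for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                    if j != i:
                        counts[(a, ids[j])] += 1
    if not counts:
        return sparse.csr_matrix((v, v))
    keys = np.array(list(counts.keys()), dtype=np.int64)
    vals = np.array(list(counts.values()), dtype=np.float64)
    return sparse.csr_matrix((vals, (keys[:, 0], keys[:, 1])), shape=(v, v))


def _ppmi(C: sparse.csr_matrix) -> sparse.csr_matrix:
    total = C.sum()
    if total == 0:
        return C
    row = np.asarray(C.sum(axis=1)).ravel()
    col = np.asarray(C.sum(axis=0)).ravel()
    C = C.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(C.data * total / (row[C.row] * col[C.col]))
    keep = pmi > 0
    return sparse.csr_matrix((pmi[keep], (C.row[keep], C.col[keep])),
                             shape=C.shape)


def train_embedding(docs: Iterable[Sequence[str]],
                    params: EmbeddingParams | None = None,
                    stopwords: set[str] | None = None) -> Embedding:
    """Train an embedding on tokenized documents.

    Vocabulary keeps words with corpus frequency >= ``min_count`` (after
    stop-word removal); raises if that leaves nothing.  Deterministic for
    a fixed corpus, params, and seed.
    """
    params = params or EmbeddingParams()
    params.validate()
    docs = [list(d) for d in docs]
    if stopwords:
        docs = [[w for w in d if w not in stopwords] for d in docs]
    if not any(docs):
        raise ValueError("empty corpus: nothing to train on")
    freq = Counter(w for d in docs for w in d)
    words = sorted((w for w, c in freq.items() if c >= params.min_count),
                   key=lambda w: (-freq[w], w))
    if not words:
        raise ValueError(
            f"min_count={params.min_count} leaves an empty vocabulary "
            f"(max frequency {max(freq.values())})")
    vocab = {w: i for i, w in enumerate(words)}
    if len(words) == 1:
        # degenerate but legal: a single word has no co-occurrence geometry
        return Embedding(vocabulary=vocab,
                         vectors=np.ones((1, params.dimension)),
                         params=params)

    C = _cooccurrence(docs, vocab, params.window)
    M = _ppmi(C)
    dim = min(params.dimension, len(words) - 1)
    svd = TruncatedSVD(n_components=dim, random_state=params.seed,
                       algorithm="randomized")
    vectors = svd.fit_transform(M)
    if dim < params.dimension:   # pad so the declared dimension holds
        vectors = np.hstack([vectors,
                             np.zeros((len(words), params.dimension - dim))])
    return Embedding(vocabulary=vocab, vectors=vectors, params=params)
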
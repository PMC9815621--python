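"""Embedding-based psychological topic detection.

The four-step pipeline: (1) seed word lists per topic partition (symptom
topics and factor topics, seven each in the default configuration);
(2) lexicon expansion — every vocabulary word whose maximum cosine
similarity to any seed reaches a threshold joins the partition's lexicon;
(3) dense vectors for the expanded words; (4) k-means over those vectors
with the number of clusters chosen by silhouette score.  The resulting
clusters define topic word lists; per-document topic *incidence* is then
plain lexical matching (a binary vector, one element per topic), not
nearest-centroid assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .embedding import Embedding, EmbeddingParams, train_embedding

__all__ = [
    "TopicIncidence", "ClusterSelection", "TopicModel", "expand_lexicon",
    "doc_vector", "select_k_and_cluster", "topic_incidence",
    "build_topic_model",
]


# ---------------------------------------------------------------------------
# Lexicon expansion and document vectors
# ---------------------------------------------------------------------------

def expand_lexicon(seeds: Sequence[str], embedding: Embedding,
                   threshold: float = 0.5) -> set[str]:
    """All vocabulary words with max cosine to any seed >= ``threshold``.

    Seeds present in the vocabulary are always included.  If no seed is
    in the vocabulary a warning is raised and the seed set is returned
    unchanged.
    """
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [-1, 1]")
    in_vocab = [s for s in seeds if s in embedding]
    if not in_vocab:
        warnings.warn("no seed word found in embedding vocabulary; "
                      "returning seeds unexpanded", stacklevel=2)
        return set(seeds)
    V = embedding.vectors
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    Vn = V / norms[:, None]
    S = np.stack([embedding.vector(s) for s in in_vocab])
    sn = np.linalg.norm(S, axis=1)
    sn[sn == 0] = 1.0
    Sn = S / sn[:, None]
    sims = Vn @ Sn.T                      # (V, n_seeds)
    best = sims.max(axis=1)
    out = {w for w, i in embedding.vocabulary.items() if best[i] >= threshold}
    out.update(in_vocab)
    return out


def doc_vector(tokens: Sequence[str], embedding: Embedding,
               ) -> tuple[np.ndarray, bool]:
    """Mean of in-vocabulary token vectors.

    Returns ``(vector, oov_flag)``; a document with no in-vocabulary
    token yields the zero vector, flagged.
    """
    vecs = [embedding.vector(t) for t in tokens if t in embedding]
    if not vecs:
        return np.zeros(embedding.vectors.shape[1]), True
    return np.mean(vecs, axis=0), False


# ---------------------------------------------------------------------------
# k selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterSelection:
    assignments: np.ndarray
    centers: np.ndarray
    silhouette_trace: dict[int, float]
    chosen_k: int


def select_k_and_cluster(vectors: np.ndarray, k_range: Sequence[int],
                         n_restarts: int = 10, seed: int = 0,
                         ) -> ClusterSelection:
    """k-means over ``vectors`` for every k in ``k_range``; keep the k
    maximising the silhouette score (ties -> smaller k).

    ``k_range`` must lie within [2, n_points - 1].
    """
    X = np.asarray(vectors, dtype=float)
    n = len(X)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(
            f"k_range [{ks[0]}, {ks[-1]}] outside [2, {n - 1}] for "
            f"{n} points")
    trace: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            raise ValueError(
                f"degenerate input: k={k} produced a single cluster")
        trace[k] = float(silhouette_score(X, labels))
        fits[k] = km
    chosen = min(ks, key=lambda k: (-trace[k], k))
    km = fits[chosen]
    return ClusterSelection(assignments=km.labels_.copy(),
                            centers=km.cluster_centers_.copy(),
                            silhouette_trace=trace, chosen_k=chosen)


# ---------------------------------------------------------------------------
# Topic model and incidence
# ---------------------------------------------------------------------------

@dataclass
class TopicIncidence:
    vector: np.ndarray           # binary, one element per topic
    partition: str = ""
    topic_names: list[str] = field(default_factory=list)


def topic_incidence(tokens: Sequence[str],
                    topic_lexicons: Mapping[str, set[str]],
                    partition: str = "") -> TopicIncidence:
    """Binary incidence: element j = 1 iff any token is in topic j's set.

    Invariant to token order and multiplicity.
    """
    names = list(topic_lexicons)
    tok = set(tokens)
    vec = np.array([1 if tok & set(topic_lexicons[nm]) else 0
                    for nm in names], dtype=np.int64)
    return TopicIncidence(vector=vec, partition=partition, topic_names=names)


@dataclass
class TopicModel:
    """Expanded topic lexicons plus the clustering evidence behind them."""

    embedding: Embedding
    partitions: dict[str, dict[str, set[str]]]       # partition -> topic -> words
    selections: dict[str, ClusterSelection]
    expanded: dict[str, set[str]]
    threshold: float

    def lexicons(self, partition: str) -> dict[str, set[str]]:
        return self.partitions[partition]

    def chosen_k(self, partition: str) -> int:
        return self.selections[partition].chosen_k


def _name_clusters(words: list[str], labels: np.ndarray,
                   seeds: Mapping[str, Sequence[str]]) -> dict[str, set[str]]:
    """Group words by cluster, naming each cluster after the seed topics it
    absorbed (falling back to a positional name)."""
    clusters: dict[int, set[str]] = {}
    for w, l in zip(words, labels):
        clusters.setdefault(int(l), set()).add(w)
    seed_of = {}
    for topic, ws in seeds.items():
        for w in ws:
            seed_of[w] = topic
    named: dict[str, set[str]] = {}
    for l in sorted(clusters):
        topics = sorted({seed_of[w] for w in clusters[l] if w in seed_of})
        name = "+".join(topics) if topics else f"cluster_{l}"
        if name in named:                       # two clusters, same seeds
            name = f"{name}#{l}"
        named[name] = clusters[l]
    return named


def build_topic_model(docs: Sequence[Sequence[str]],
                      seeds: Mapping[str, Mapping[str, Sequence[str]]],
                      params: EmbeddingParams | None = None,
                      threshold: float = 0.5,
                      k_range: Sequence[int] = range(2, 11),
                      k_override: int | None = None,
                      stopwords: set[str] | None = None,
                      seed: int = 0) -> TopicModel:
    """End-to-end topic detection over tokenized documents.

    ``seeds`` maps partition name ("symptom" / "factor") to per-topic seed
    word lists.  ``k_override`` pins the cluster count (e.g. at 7)
    regardless of the silhouette-chosen k; the trace is still reported.
    """
    params = params or EmbeddingParams(seed=seed)
    emb = train_embedding(docs, params, stopwords=stopwords)
    partitions: dict[str, dict[str, set[str]]] = {}
    selections: dict[str, ClusterSelection] = {}
    expanded_all: dict[str, set[str]] = {}
    for part, topic_seeds in seeds.items():
        all_seeds = [w for ws in topic_seeds.values() for w in ws]
        expanded = expand_lexicon(all_seeds, emb, threshold)
        expanded_in_vocab = sorted(w for w in expanded if w in emb)
        expanded_all[part] = set(expanded_in_vocab)
        vectors = np.stack([emb.vector(w) for w in expanded_in_vocab])
        ks = [k for k in k_range if 2 <= k <= len(expanded_in_vocab) - 1]
        if not ks:
            raise ValueError(
                f"partition {part!r}: expanded lexicon too small "
                f"({len(expanded_in_vocab)} words) for clustering")
        sel = select_k_and_cluster(vectors, ks, seed=seed)
        if k_override is not None and k_override != sel.chosen_k:
            km = KMeans(n_clusters=k_override, n_init=10, random_state=seed)
            labels = km.fit_predict(vectors)
            sel = ClusterSelection(assignments=labels,
                                   centers=km.cluster_centers_,
                                   silhouette_trace=sel.silhouette_trace,
                                   chosen_k=k_override)
        partitions[part] = _name_clusters(expanded_in_vocab, sel.assignments,
                                          topic_seeds)
        selections[part] = sel
    return TopicModel(embedding=emb, partitions=partitions,
                      selections=selections, expanded=expanded_all,
                      threshold=threshold)
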
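"""Embedding-based topic detection on the simulated corpus.

Trains the co-occurrence embedding (stop words removed first), expands
the per-topic seed lists by cosine threshold, clusters the expanded
vocabulary with k-means, and selects the cluster count by silhouette.
Writes the resulting topic lexicons and silhouette traces under
``results/topics/``.
"""

import json

import pandas as pd

from _config import RESULTS, SEED
from counselhelp import vocab
from counselhelp.corpus import read_corpus
from counselhelp.embedding import EmbeddingParams
from counselhelp.topics import build_topic_model


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl")
    docs = [p.question_tokens for p in corpus] + \
           [p.response_tokens for p in corpus]
    tm = build_topic_model(
        docs,
        seeds={"symptom": vocab.topic_seeds("symptom"),
               "factor": vocab.topic_seeds("factor")},
        params=EmbeddingParams(dimension=50, window=0, min_count=3,
                               seed=SEED),
        threshold=0.5, k_range=range(2, 11),
        stopwords=vocab.synthetic_stopwords(), seed=SEED)

    out = RESULTS / "topics"
    out.mkdir(exist_ok=True)
    for part in ("symptom", "factor"):
        sel = tm.selections[part]
        (out / f"{part}_lexicons.json").write_text(json.dumps(
            {nm: sorted(ws) for nm, ws in tm.lexicons(part).items()},
            indent=2, sort_keys=True))
        pd.DataFrame(sorted(sel.silhouette_trace.items()),
                     columns=["k", "silhouette"]).to_csv(
            out / f"{part}_silhouette.csv", index=False)
        print(f"{part}: expanded lexicon {len(tm.expanded[part])} words, "
              f"silhouette-chosen k = {sel.chosen_k} "
              f"(trace max {max(sel.silhouette_trace.values()):.3f})")
    print(f"topic lexicons and traces written to {out}")


if __name__ == "__main__":
    main()
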
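"""Psycholinguistic feature extraction for both speakers.

Computes LIWC-style category proportions (toy dictionary over the
synthetic vocabulary) and stylistic counters for every question and
response; writes the tagged feature table to ``results/features.csv``
with its column-tag sidecar.
"""

from _config import RESULTS
from counselhelp.corpus import read_corpus
from counselhelp.features import build_feature_table
from counselhelp.vocab import default_group_map, default_lexicon


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl")
    table = build_feature_table(corpus, default_lexicon(),
                                default_group_map())
    data_path, tag_path = table.write(RESULTS / "features")
    n_by_source = {
        s: len(table.columns_for_source([s]))
        for s in ("counselee", "counselor")}
    print(f"feature table: {len(table.data)} rows x "
          f"{table.data.shape[1]} columns -> {data_path}")
    print(f"columns per source: {n_by_source}; tags -> {tag_path}")
    if table.empty_documents:
        print(f"empty documents flagged: {len(table.empty_documents)}")


if __name__ == "__main__":
    main()
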
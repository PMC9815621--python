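import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from counselhelp.corpus import (GeneratorConfig, OutcomeModel,
                                default_outcome_model, generate_corpus)
from counselhelp.features import build_feature_table
from counselhelp.synchrony import append_synchrony
from counselhelp.vocab import (default_group_map, default_lexicon,
                               topic_lexicons)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def featurize(corpus):
    """Feature table (with synchrony columns) using the bundled toy
    dictionary and the generator's planted topic lexicons."""
    table = build_feature_table(corpus, default_lexicon(),
                                default_group_map())
    return append_synchrony(table, corpus, topic_lexicons("symptom"),
                            topic_lexicons("factor"))


@pytest.fixture(scope="session")
def study_run():
    """One 500-pair corpus under the default study conditions, fully
    featurized — shared by the heavier end-to-end checks."""
    cfg = GeneratorConfig(n_pairs=500, seed=101,
                          outcome_model=default_outcome_model())
    corpus, truth = generate_corpus(cfg)
    table = featurize(corpus)
    y = np.array([p.helpful_votes for p in corpus], dtype=float)
    return corpus, truth, table, y


@pytest.fixture(scope="session")
def tiny_corpus():
    """Two hand-readable pairs over the synthetic vocabulary."""
    from counselhelp.corpus import QAPair
    return [
        QAPair.from_raw(
            "p0",
            "preps01 anx01 symp1w01 filler001 . i01 sad01 .",
            "preps01 preps02 posfeel01 symp1w02 fact1w01 : filler002 .",
            3),
        QAPair.from_raw(
            "p1",
            "conj01 love01 fact2w01 w1 .",
            "conj01 love02 fact2w02 w2 w3 .",
            1),
    ]
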
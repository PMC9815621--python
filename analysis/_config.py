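"""Shared settings for the numbered analysis scripts.

One seed, one corpus size, one output root — every script imports from
here so the whole analysis is reproducible end to end.
"""

from pathlib import Path

from counselhelp.corpus import GeneratorConfig, default_outcome_model

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"

#: study conditions: vote counts with mean near 4.36 starting at 1,
#: questions near 185 tokens, responses near 388, planted effects on
#: counselor emotion/insight rates, style matching, and topic overlap
def study_conditions(n_pairs: int = 400) -> GeneratorConfig:
    return GeneratorConfig(n_pairs=n_pairs, seed=SEED,
                           outcome_model=default_outcome_model())
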
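# counselhelp

What makes a counselor's written answer *helpful*?  On asynchronous
question-and-answer counseling platforms, a counselee posts one question,
counselors post one response each, and readers vote responses as helpful.
`counselhelp` implements, as a tested and reusable pipeline, the analysis
of which psycholinguistic signals predict that helpful-vote count: LIWC-style
category proportions and stylistic counters for both speakers, three
counselor–counselee *synchrony* statistics, a five-regressor predictive
comparison under cross-validated MAE, and a signed cumulative-SHAP
explanation layer.  A seeded synthetic corpus generator with fully known
latent structure stands in for platform data, so every stage is testable
end to end.

## The measures

For a question with topic-incidence vector $R$ and its response with
vector $M$ (binary, one element per detected topic), **topic consistency**
is the Jaccard similarity

$$J(R, M) = \frac{|R \cap M|}{|R \cup M|},$$

computed separately over symptom topics and factor topics.  **Language
style matching** compares the two speakers' function-word rates: for a
category with usage percentages $p_1, p_2$,

$$\mathrm{LSM} = 1 - \frac{|p_1 - p_2|}{p_1 + p_2 + 0.0001},$$

averaged over nine function-word categories (prepositions, auxiliary
verbs, adverbs, conjunctions, articles, quantifiers, negations, personal
and impersonal pronouns).  **Emotional similarity** is the cosine of the
two speakers' 7-dimension emotion-rate vectors (overall emotion,
positive, negative, anxiety, anger, sadness, love) — a proxy for
expressed empathy.

Votes are predicted from counselee, counselor, and synchrony features by
linear regression, ridge, lasso, linear-kernel SVR, and a random forest,
compared by ten-fold cross-validated mean absolute error on a shared fold
partition.  The fitted model is then decomposed with Shapley values
$\mathrm{SHAP}_{ij}$ (authored in-package: exact path-dependent TreeSHAP
for tree ensembles, verified against an exhaustive-coalition oracle, plus
a kernel sampler for other models).  For a feature group $F$ the signed
cumulative decomposition reports

$$\mathrm{SHAP}_F^+ = \sum_{j \in F}\sum_{i}\mathrm{SHAP}_{ij}\,[\mathrm{SHAP}_{ij} > 0],$$

its negative counterpart, the total effect
$\mathrm{SHAP}_F^+ + |\mathrm{SHAP}_F^-|$, and each group's share of the
grand total.  On top of that sit a total-effect feature ranking,
SHAP-ranked incremental feature selection (CV-MAE versus top-$k$), a
five-way clustering of attribution profiles on $1 - r$ Pearson distance,
and per-response local decompositions.

Topic lexicons are built the embedding way: seed words per topic, a
deterministic PPMI + truncated-SVD word embedding, cosine-threshold
lexicon expansion, then k-means over the expanded vocabulary with the
cluster count chosen by silhouette score.

## Worked example

```python
import numpy as np
from counselhelp import (GeneratorConfig, default_outcome_model,
                         generate_corpus, build_feature_table,
                         append_synchrony, ModelSpec, fit_regressor,
                         compute_shap, grouped_decomposition, share_of_total)
from counselhelp.vocab import (default_lexicon, default_group_map,
                               topic_lexicons)

cfg = GeneratorConfig(n_pairs=200, seed=7,
                      outcome_model=default_outcome_model())
corpus, truth = generate_corpus(cfg)
print(np.mean([p.helpful_votes for p in corpus]))   # 4.67

table = build_feature_table(corpus, default_lexicon(), default_group_map())
table = append_synchrony(table, corpus, topic_lexicons("symptom"),
                         topic_lexicons("factor"))
y = np.array([p.helpful_votes for p in corpus], float)

model = fit_regressor(table.data.to_numpy(float), y,
                      ModelSpec("random_forest",
                                {"n_estimators": 200, "max_depth": 8},
                                seed=7))
shap = compute_shap(model, table.data, method="exact-tree")
decomp = grouped_decomposition(
    shap, {f: table.tags[f][0] for f in shap.feature_names})
print(share_of_total(decomp).round(2).to_dict())
# {'counselee': 44.49, 'counselor': 39.38, 'synchrony': 16.13}
```

The vote mean sits near the 4.36 the generator targets; the share
dictionary says how much of the total attribution magnitude each feature
source carries.  At this small sample the two speakers' shares are
close and synchrony carries the rest — on real platform data, where
counselor language dominates the outcome, the same decomposition
concentrates far more heavily on the counselor source.

## The analysis

Numbered scripts under `analysis/` run the study end to end on a
400-pair synthetic corpus, writing tables under `results/`:

| script | writes |
| --- | --- |
| `01_simulate_corpus.py` | `corpus.jsonl`, latent-truth tables, corpus summary |
| `02_detect_topics.py` | expanded topic lexicons, silhouette traces |
| `03_extract_features.py` | tagged per-speaker feature table |
| `04_compute_synchrony.py` | topic-consistency, LSM, emotion-cosine columns |
| `05_compare_models.py` | algorithm × feature-source CV-MAE grid |
| `06_explain_model.py` | signed cumulative decomposition, ranking, selection curve, style clusters, local decomposition |

Run them in order from the repository root
(`python analysis/01_simulate_corpus.py`, ...).  Each prints what it
found; for instance `05` reports the paired MAE grid and its best cell,
and `06` prints the source shares and the top-ranked features.

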
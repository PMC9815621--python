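"""Model comparison: five regressors x four feature-source sets.

Ten-fold cross-validated mean absolute error for linear regression,
ridge, lasso, linear-kernel SVR, and random forest, each fitted on
counselor-only, counselee-only, synchrony-only, and all-source feature
sets (shared fold partition, so the grid is paired).  Writes the grid
with row/column means to ``results/model_grid.csv``.
"""

import numpy as np

from _config import RESULTS, SEED
from counselhelp.corpus import read_corpus
from counselhelp.features import FeatureTable
from counselhelp.models import ModelSpec, compare_feature_sets

SOURCE_SETS = [("counselor",), ("counselee",), ("synchrony",),
               ("counselee", "counselor", "synchrony")]


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl")
    table = FeatureTable.read(RESULTS / "features_full")
    y = np.array([p.helpful_votes for p in corpus], float)
    specs = [ModelSpec(a, {"n_estimators": 200} if a == "random_forest"
                       else {}, seed=SEED)
             for a in ("linear_regression", "ridge", "lasso", "svr",
                       "random_forest")]
    grid, _ = compare_feature_sets(table, y, specs, SOURCE_SETS,
                                   n_folds=10, cv_seed=SEED)
    grid.round(4).to_csv(RESULTS / "model_grid.csv")
    grid.to_csv(RESULTS / "model_grid_full.csv", float_format="%.17g")

    cells = grid.drop(index="source_mean").drop(columns="algorithm_mean")
    best = cells.stack().idxmin()
    print(grid.round(4).to_string())
    print(f"\nbest cell: {best[0]} on {best[1]} "
          f"(CV MAE {cells.loc[best]:.4f})")
    print(f"grid written to {RESULTS / 'model_grid.csv'}")


if __name__ == "__main__":
    main()
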
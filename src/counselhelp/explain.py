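"""Signed cumulative SHAP decomposition and its derived reports.

Given a per-observation x per-feature attribution matrix
``SHAP_ij`` (with base value b such that ``b + sum_j SHAP_ij`` equals
the model prediction for observation i), this module produces the
explanation artifacts of the helpfulness analysis:

* grouped decomposition — per feature group F: the cumulative positive
  attribution ``SHAP_F+ = sum over i,j in F of SHAP_ij * [SHAP_ij > 0]``,
  its negative counterpart ``SHAP_F-``, and the *total effect*
  ``SHAP_F+ + |SHAP_F-|``; with share-of-grand-total percentages;
* feature ranking by total effect (cumulative-influence curve);
* SHAP-ranked incremental feature selection (CV-MAE vs top-k curve);
* feature clustering on 1 - Pearson correlation between attribution
  columns (average linkage);
* local per-observation decompositions.

Importance here is the total effect (matching the decomposition-table
arithmetic), not mean |SHAP|; both orderings are emitted by
:func:`rank_features`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._shapley import kernel_shap_values, tree_shap_values
from .models import ModelSpec, cross_validate_mae

__all__ = [
    "ShapMatrix", "GroupDecomposition", "FeatureClustering",
    "LocalExplanation", "compute_shap", "grouped_decomposition",
    "share_of_total", "rank_features", "incremental_selection",
    "cluster_features", "local_explanation",
]


# ---------------------------------------------------------------------------
# SHAP matrix
# ---------------------------------------------------------------------------

@dataclass
class ShapMatrix:
    """Signed attributions: rows = observations, columns = features."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("attribution matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")

    @property
    def predictions(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)

    def column(self, feature: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(feature)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def compute_shap(model, X, feature_names: Sequence[str] | None = None,
                 method: str = "exact-tree",
                 background: np.ndarray | None = None,
                 background_size: int = 100, seed: int = 0) -> ShapMatrix:
    """Attribution matrix for ``model`` over the rows of ``X``.

    ``exact-tree`` runs path-dependent TreeSHAP (tree models only;
    deterministic; additivity to float precision).  ``sampling-kernel``
    runs interventional kernel SHAP against a background sample — by
    default a seeded subsample of ``X`` of at most ``background_size``
    rows.
    """
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if method == "exact-tree":
        values, base = tree_shap_values(model, X)
    elif method == "sampling-kernel":
        if background is None:
            rng = np.random.default_rng(seed)
            take = min(background_size, len(X))
            idx = rng.choice(len(X), size=take, replace=False)
            background = X[idx]
        values, base = kernel_shap_values(model.predict, X, background,
                                          seed=seed)
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    return ShapMatrix(values=values, base_value=base,
                      feature_names=list(feature_names))


# ---------------------------------------------------------------------------
# Grouped signed decomposition
# ---------------------------------------------------------------------------

@dataclass
class GroupDecomposition:
    """Per-group signed cumulative attributions.

    ``table`` columns: ``negative`` (<= 0), ``positive`` (>= 0),
    ``total`` (= positive + |negative|), ``share_pct`` of the grand
    total.
    """

    table: pd.DataFrame
    grand_total: float
    grouping: dict[str, str]

    def merged(self, merge: Mapping[str, Sequence[str]]
               ) -> "GroupDecomposition":
        """Re-aggregate with the listed groups merged.

        Positive and negative sums add exactly; totals and shares are
        recomputed from the merged sums (grouping consistency).
        """
        target_of = {}
        for new, olds in merge.items():
            for g in olds:
                target_of[g] = new
        agg: dict[str, dict[str, float]] = {}
        for old_group in self.table.index:
            target = target_of.get(old_group, old_group)
            d = agg.setdefault(target, {"negative": 0.0, "positive": 0.0})
            d["negative"] += float(self.table.loc[old_group, "negative"])
            d["positive"] += float(self.table.loc[old_group, "positive"])
        out = pd.DataFrame(agg).T
        out["total"] = out["positive"] + out["negative"].abs()
        out["share_pct"] = 100.0 * out["total"] / self.grand_total
        out.index.name = self.table.index.name
        new_grouping = {f: target_of.get(g, g)
                        for f, g in self.grouping.items()}
        return GroupDecomposition(out, self.grand_total, new_grouping)


def grouped_decomposition(shap: ShapMatrix,
                          grouping: Mapping[str, str],
                          group_label: str = "group") -> GroupDecomposition:
    """Signed cumulative decomposition over a feature grouping.

    ``grouping`` maps every feature name to a group label; an uncovered
    feature raises.  Group order follows first appearance in
    ``shap.feature_names``.
    """
    for f in shap.feature_names:
        if f not in grouping:
            raise KeyError(f"feature {f!r} not covered by grouping")
    order: list[str] = []
    cols: dict[str, list[int]] = {}
    for j, f in enumerate(shap.feature_names):
        g = grouping[f]
        if g not in cols:
            cols[g] = []
            order.append(g)
        cols[g].append(j)
    rows = {}
    for g in order:
        block = shap.values[:, cols[g]]
        pos = float(block[block > 0].sum())
        neg = float(block[block < 0].sum())
        rows[g] = {"negative": neg, "positive": pos,
                   "total": pos + abs(neg)}
    table = pd.DataFrame(rows).T
    grand = float(table["total"].sum())
    table["share_pct"] = (100.0 * table["total"] / grand) if grand > 0 \
        else np.nan
    table.index.name = group_label
    return GroupDecomposition(table=table, grand_total=grand,
                              grouping={f: grouping[f]
                                        for f in shap.feature_names})


def share_of_total(decomp: GroupDecomposition) -> pd.Series:
    """Percent of the grand total per group (sums to 100 up to rounding)."""
    if decomp.grand_total == 0:
        raise ValueError("zero grand total: shares undefined")
    return 100.0 * decomp.table["total"] / decomp.grand_total


# ---------------------------------------------------------------------------
# Ranking and incremental selection
# ---------------------------------------------------------------------------

def rank_features(shap: ShapMatrix) -> pd.DataFrame:
    """Features ranked by total effect (positive sum + |negative sum|).

    Ties break on feature name so the ranking is column-order invariant.
    Also reports mean |SHAP| (the alternative ordering) and the
    cumulative share curve of the primary ordering.
    """
    if shap.values.size == 0:
        raise ValueError("empty attribution matrix")
    rows = []
    for j, f in enumerate(shap.feature_names):
        col = shap.values[:, j]
        pos = float(col[col > 0].sum())
        neg = float(col[col < 0].sum())
        rows.append({"feature": f, "positive": pos, "negative": neg,
                     "total_effect": pos + abs(neg),
                     "mean_abs": float(np.abs(col).mean())})
    df = pd.DataFrame(rows).sort_values(
        ["total_effect", "feature"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    grand = df["total_effect"].sum()
    df["cumulative_share_pct"] = (
        100.0 * df["total_effect"].cumsum() / grand if grand > 0 else np.nan)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def incremental_selection(table, y, ranking: Sequence[str], spec: ModelSpec,
                          n_folds: int = 10, cv_seed: int = 0,
                          max_k: int | None = None,
                          ) -> tuple[pd.DataFrame, int]:
    """CV MAE of the model restricted to the top-k ranked features,
    for k = 1..P (or ``max_k``); best k = argmin (ties -> smaller k).

    ``table`` may be a FeatureTable or a plain DataFrame; every ranked
    feature must be one of its columns.  The fold partition is shared
    across k.
    """
    data = table.data if hasattr(table, "data") else table
    ranking = list(ranking)
    if not ranking:
        raise ValueError("empty ranking")
    missing = [f for f in ranking if f not in data.columns]
    if missing:
        raise KeyError(f"ranked features not in table: {missing[:5]}")
    y = np.asarray(y, dtype=float)
    from sklearn.model_selection import KFold
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)
    folds = list(kf.split(np.zeros((len(y), 1))))
    P = len(ranking) if max_k is None else min(max_k, len(ranking))
    rows = []
    for k in range(1, P + 1):
        X = data[ranking[:k]].to_numpy(dtype=float)
        res = cross_validate_mae(X, y, spec, n_folds, cv_seed, folds=folds)
        rows.append({"k": k, "mae": res.mean_mae})
    curve = pd.DataFrame(rows)
    best_k = int(curve.loc[curve["mae"].idxmin(), "k"])
    return curve, best_k


# ---------------------------------------------------------------------------
# Attribution-profile clustering
# ---------------------------------------------------------------------------

@dataclass
class FeatureClustering:
    distance: pd.DataFrame            # 1 - Pearson r, symmetric, in [0, 2]
    linkage_matrix: np.ndarray
    assignments: dict[str, int]
    excluded: list[str]               # constant attribution columns


def cluster_features(shap: ShapMatrix, n_clusters: int = 5,
                     ) -> FeatureClustering:
    """Average-linkage hierarchical clustering of attribution columns on
    correlation distance, cut at ``n_clusters``.

    Constant columns (undefined correlation) are excluded with a warning.
    """
    names, cols = [], []
    excluded = []
    for j, f in enumerate(shap.feature_names):
        col = shap.values[:, j]
        if np.std(col) == 0:
            excluded.append(f)
        else:
            names.append(f)
            cols.append(col)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant attribution column(s) "
            f"from clustering: {excluded[:5]}", stacklevel=2)
    if len(names) < n_clusters:
        raise ValueError(
            f"only {len(names)} usable features for {n_clusters} clusters")
    M = np.stack(cols)
    corr = np.corrcoef(M)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return FeatureClustering(
        distance=pd.DataFrame(dist, index=names, columns=names),
        linkage_matrix=Z,
        assignments={f: int(l) for f, l in zip(names, labels)},
        excluded=excluded)


# ---------------------------------------------------------------------------
# Local decomposition
# ---------------------------------------------------------------------------

@dataclass
class LocalExplanation:
    observation: int
    base_value: float
    prediction: float
    contributions: list[tuple[str, float]]   # sorted by |value|, descending


def local_explanation(model, shap: ShapMatrix, index: int,
                      ) -> LocalExplanation:
    """Per-observation signed contribution list (force-plot data).

    Additivity: base + sum(contributions) equals the prediction the
    matrix encodes for that observation.
    """
    n = shap.values.shape[0]
    if not (0 <= index < n):
        raise IndexError(f"observation {index} out of range [0, {n})")
    row = shap.values[index]
    contribs = sorted(zip(shap.feature_names, row.tolist()),
                      key=lambda t: (-abs(t[1]), t[0]))
    return LocalExplanation(
        observation=index,
        base_value=shap.base_value,
        prediction=float(shap.base_value + row.sum()),
        contributions=contribs)
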
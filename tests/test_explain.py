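"""Signed cumulative decomposition, ranking, selection, clustering, local."""

import numpy as np
import pandas as pd
import pytest

from counselhelp.explain import (ShapMatrix, cluster_features,
                                 grouped_decomposition,
                                 incremental_selection, local_explanation,
                                 rank_features, share_of_total)
from counselhelp.models import ModelSpec, cross_validate_mae


def _matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return ShapMatrix(values=values, base_value=0.0, feature_names=names)


class TestGroupedDecomposition:
    def test_hand_summed_signed_components(self):
        shap = _matrix([[1.0], [-2.0], [3.0]])
        d = grouped_decomposition(shap, {"f0": "g"})
        row = d.table.loc["g"]
        assert row["positive"] == 4.0
        assert row["negative"] == -2.0
        assert row["total"] == 6.0

    def test_counselor_components_total(self):
        # positive 3.2436 and negative -2.8497 combine to 6.0933
        shap = _matrix([[3.2436], [-2.8497]])
        d = grouped_decomposition(shap, {"f0": "counselor"})
        assert d.table.loc["counselor", "total"] == pytest.approx(6.0933)

    def test_affective_components_total(self):
        shap = _matrix([[-0.1090], [0.1082]])
        d = grouped_decomposition(shap, {"f0": "affective"})
        assert d.table.loc["affective", "total"] == pytest.approx(0.2172)

    def test_uncovered_feature_rejected(self):
        shap = _matrix([[1.0, 2.0]])
        with pytest.raises(KeyError, match="f1"):
            grouped_decomposition(shap, {"f0": "g"})

    def test_merging_groups_sums_fields_exactly(self):
        rng = np.random.default_rng(1)
        shap = _matrix(rng.normal(size=(40, 6)))
        grouping = {f"f{j}": f"g{j % 3}" for j in range(6)}
        d = grouped_decomposition(shap, grouping)
        m = d.merged({"g01": ["g0", "g1"]})
        assert m.table.loc["g01", "positive"] == (
            d.table.loc["g0", "positive"] + d.table.loc["g1", "positive"])
        assert m.table.loc["g01", "negative"] == (
            d.table.loc["g0", "negative"] + d.table.loc["g1", "negative"])
        assert m.table.loc["g01", "total"] == pytest.approx(
            d.table.loc["g0", "total"] + d.table.loc["g1", "total"])
        assert m.grand_total == d.grand_total
        # grouping consistency: total over groups is total over features
        per_feature = np.abs(shap.values).sum()
        assert d.table["total"].sum() == pytest.approx(per_feature)


class TestShareOfTotal:
    def test_reported_three_source_shares(self):
        """Totals 6.0933 / 0.1699 / 0.2621 split the grand total
        93.38% / 2.60% / 4.02%."""
        shap = _matrix([[3.2436, 0.1, 0.15],
                        [-2.8497, 0.0699, 0.1121]],
                       names=["counselor", "counselee", "synchrony"])
        d = grouped_decomposition(shap, {n: n for n in shap.feature_names})
        np.testing.assert_allclose(d.table["total"],
                                   [6.0933, 0.1699, 0.2621], atol=1e-12)
        shares = share_of_total(d)
        assert round(shares["counselor"], 2) == 93.38
        assert round(shares["counselee"], 2) == 2.60
        assert round(shares["synchrony"], 2) == 4.02
        assert shares.sum() == pytest.approx(100.0)

    def test_single_group_is_hundred_percent(self):
        d = grouped_decomposition(_matrix([[1.0], [2.0]]), {"f0": "only"})
        assert share_of_total(d)["only"] == pytest.approx(100.0)

    def test_two_equal_groups_split_evenly(self):
        shap = _matrix([[1.0, -1.0]])
        d = grouped_decomposition(shap, {"f0": "a", "f1": "b"})
        shares = share_of_total(d)
        assert shares["a"] == pytest.approx(50.0)
        assert shares["b"] == pytest.approx(50.0)

    def test_zero_grand_total_rejected(self):
        d = grouped_decomposition(_matrix([[0.0]]), {"f0": "g"})
        with pytest.raises(ValueError, match="zero grand total"):
            share_of_total(d)


class TestRankFeatures:
    def test_zero_column_ranks_last(self):
        shap = _matrix([[1.0, 0.0], [-2.0, 0.0]])
        r = rank_features(shap)
        assert r.iloc[-1]["feature"] == "f1"

    def test_magnitudes_and_cumulative_shares(self):
        shap = _matrix([[3.0, -1.0]])
        r = rank_features(shap)
        assert r["feature"].tolist() == ["f0", "f1"]
        np.testing.assert_allclose(r["cumulative_share_pct"], [75.0, 100.0])

    def test_column_order_invariant(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 5))
        names = ["a", "b", "c", "d", "e"]
        r1 = rank_features(_matrix(vals, names))
        perm = [3, 0, 4, 1, 2]
        r2 = rank_features(_matrix(vals[:, perm],
                                   [names[j] for j in perm]))
        assert r1["feature"].tolist() == r2["feature"].tolist()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rank_features(_matrix(np.zeros((0, 0)), []))


class TestIncrementalSelection:
    def _data(self, n=120, p=4, seed=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{j}" for j in range(p)])
        y = X["f0"] * 2 + rng.normal(size=n) * 0.5
        return X, y.to_numpy()

    def test_full_k_reproduces_all_feature_cv_mae(self):
        X, y = self._data()
        spec = ModelSpec("ridge")
        curve, _ = incremental_selection(X, y, list(X.columns), spec,
                                         n_folds=5, cv_seed=7)
        full = cross_validate_mae(X[list(X.columns)].to_numpy(), y, spec,
                                  n_folds=5, cv_seed=7)
        assert curve.iloc[-1]["mae"] == pytest.approx(full.mean_mae)

    def test_single_feature_curve(self):
        X, y = self._data()
        curve, best_k = incremental_selection(X, y, ["f0"],
                                              ModelSpec("ridge"), n_folds=5)
        assert len(curve) == 1
        assert best_k == 1

    def test_empty_ranking_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError, match="empty ranking"):
            incremental_selection(X, y, [], ModelSpec("ridge"))

    def test_unknown_feature_rejected(self):
        X, y = self._data()
        with pytest.raises(KeyError):
            incremental_selection(X, y, ["nope"], ModelSpec("ridge"))


class TestClusterFeatures:
    def test_identical_columns_share_a_cluster(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=40)
        cols = np.column_stack([base, base, rng.normal(size=40),
                                rng.normal(size=40), rng.normal(size=40),
                                rng.normal(size=40)])
        fc = cluster_features(_matrix(cols), n_clusters=5)
        assert fc.assignments["f0"] == fc.assignments["f1"]
        assert fc.distance.loc["f0", "f1"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_at_distance_two(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=30)
        cols = np.column_stack([base, -base, rng.normal(size=30)])
        fc = cluster_features(_matrix(cols), n_clusters=2)
        assert fc.distance.loc["f0", "f1"] == pytest.approx(2.0)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(6)
        n, per_block = 200, 4
        cols, names = [], []
        for b in range(5):
            z = rng.normal(size=n)
            for j in range(per_block):
                cols.append(z + 0.3 * rng.normal(size=n))
                names.append(f"b{b}_{j}")
        fc = cluster_features(_matrix(np.column_stack(cols), names),
                              n_clusters=5)
        labels = {}
        for b in range(5):
            block_labels = {fc.assignments[f"b{b}_{j}"]
                            for j in range(per_block)}
            assert len(block_labels) == 1
            labels[b] = block_labels.pop()
        assert len(set(labels.values())) == 5

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(7)
        cols = np.column_stack([np.zeros(30)] +
                               [rng.normal(size=30) for _ in range(5)])
        with pytest.warns(UserWarning, match="constant"):
            fc = cluster_features(_matrix(cols), n_clusters=2)
        assert fc.excluded == ["f0"]
        assert "f0" not in fc.assignments

    def test_too_few_usable_features_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            cluster_features(_matrix(rng.normal(size=(20, 3))), n_clusters=5)


class TestLocalExplanation:
    def test_additivity_and_sorting(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(10, 4))
        shap = ShapMatrix(values=vals, base_value=1.5,
                          feature_names=list("abcd"))
        le = local_explanation(None, shap, 3)
        assert le.prediction == pytest.approx(1.5 + vals[3].sum())
        mags = [abs(v) for _, v in le.contributions]
        assert mags == sorted(mags, reverse=True)

    def test_index_out_of_range(self):
        shap = _matrix([[1.0]])
        with pytest.raises(IndexError):
            local_explanation(None, shap, 5)

    def test_stump_local_single_contribution(self):
        from sklearn.tree import DecisionTreeRegressor
        from counselhelp.explain import compute_shap
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 1] > 0, 8.0, 2.0)
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        shap = compute_shap(stump, X[:5], method="exact-tree")
        le = local_explanation(stump, shap, 0)
        nonzero = [f for f, v in le.contributions if abs(v) > 1e-12]
        assert nonzero == ["x1"]
        assert le.prediction == pytest.approx(stump.predict(X[:1])[0])
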
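"""Shapley-value attribution algorithms.

Three routes, kept deliberately independent of each other:

* :func:`tree_shap_values` — the polynomial-time path-dependent algorithm
  for tree ensembles.  The coalition value function is the tree-traversal
  conditional expectation: descending past a split on an out-of-coalition
  feature averages both children weighted by training cover.  The hot
  recursion is numba-compiled; per (sample, tree) cost is O(L * D^2) for
  L leaves and depth D.
* :func:`brute_force_tree_shap` — the same value function evaluated by
  exhaustive coalition enumeration and the factorial Shapley sum.
  Exponential in the feature count; serves as the independent oracle for
  small trees.
* :func:`kernel_shap_values` — model-agnostic interventional Shapley
  against a background sample.  Exact (full coalition enumeration) for
  small feature counts, seeded coalition sampling with the Shapley-kernel
  weighted least squares otherwise; the efficiency constraint is enforced
  in both cases, so additivity holds by construction.

All routes satisfy local accuracy: base value plus the attribution row
sums to the model prediction.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "TreeArrays", "extract_trees", "tree_shap_values",
    "brute_force_tree_shap", "kernel_shap_values", "tree_expected_value",
]


# ---------------------------------------------------------------------------
# sklearn tree access
# ---------------------------------------------------------------------------

class TreeArrays:
    """Flat arrays of one fitted sklearn regression tree."""

    def __init__(self, sk_tree) -> None:
        t = sk_tree.tree_
        self.children_left = t.children_left.astype(np.int64)
        self.children_right = t.children_right.astype(np.int64)
        self.features = t.feature.astype(np.int64)
        self.thresholds = t.threshold.astype(np.float64)
        self.values = t.value.reshape(-1).astype(np.float64)
        self.covers = t.weighted_n_node_samples.astype(np.float64)
        self.max_depth = int(t.max_depth)


def extract_trees(model) -> list[TreeArrays]:
    """Tree arrays for a DecisionTreeRegressor or RandomForestRegressor."""
    if hasattr(model, "estimators_"):
        return [TreeArrays(est) for est in model.estimators_]
    if hasattr(model, "tree_"):
        return [TreeArrays(model)]
    raise TypeError(
        f"exact-tree attribution needs a tree model, got {type(model).__name__}")


def tree_expected_value(trees: Sequence[TreeArrays]) -> float:
    """Cover-weighted mean output — the explainer base value.

    For sklearn regression trees the root node value *is* the
    cover-weighted mean of the leaves, so the root suffices.
    """
    return float(np.mean([t.values[0] for t in trees]))


# ---------------------------------------------------------------------------
# Path-dependent TreeSHAP (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _extend_path(fi, zf, of, pw, unique_depth, zero_fraction, one_fraction,
                 feature_index):
    fi[unique_depth] = feature_index
    zf[unique_depth] = zero_fraction
    of[unique_depth] = one_fraction
    pw[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[i + 1] += one_fraction * pw[i] * (i + 1.0) / (unique_depth + 1.0)
        pw[i] = zero_fraction * pw[i] * (unique_depth - i) / (unique_depth + 1.0)


@njit(cache=False)
def _unwind_path(fi, zf, of, pw, unique_depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one = pw[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[i]
            pw[i] = next_one * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one = tmp - pw[i] * zero_fraction * (unique_depth - i) \
                / (unique_depth + 1.0)
        else:
            pw[i] = pw[i] * (unique_depth + 1.0) \
                / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        fi[i] = fi[i + 1]
        zf[i] = zf[i + 1]
        of[i] = of[i + 1]


@njit(cache=False)
def _unwound_path_sum(zf, of, pw, unique_depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one = pw[unique_depth]
    total = 0.0
    if one_fraction != 0.0:
        for i in range(unique_depth - 1, -1, -1):
            tmp = next_one * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one = pw[i] - tmp * zero_fraction * (unique_depth - i) \
                / (unique_depth + 1.0)
    else:
        for i in range(unique_depth - 1, -1, -1):
            total += pw[i] * (unique_depth + 1.0) \
                / (zero_fraction * (unique_depth - i))
    return total


@njit(cache=False)
def _tree_shap_recurse(children_left, children_right, features, thresholds,
                       values, covers, x, phi,
                       node, unique_depth, parent_fi, parent_zf, parent_of,
                       parent_pw, parent_zero_fraction, parent_one_fraction,
                       parent_feature_index):
    # this call's path segment lives just past the parent's segment
    fi = parent_fi[unique_depth + 1:]
    zf = parent_zf[unique_depth + 1:]
    of = parent_of[unique_depth + 1:]
    pw = parent_pw[unique_depth + 1:]
    for i in range(unique_depth + 1):
        fi[i] = parent_fi[i]
        zf[i] = parent_zf[i]
        of[i] = parent_of[i]
        pw[i] = parent_pw[i]
    _extend_path(fi, zf, of, pw, unique_depth, parent_zero_fraction,
                 parent_one_fraction, parent_feature_index)

    if children_left[node] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_path_sum(zf, of, pw, unique_depth, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * values[node]
        return

    split = features[node]
    if x[split] <= thresholds[node]:
        hot, cold = children_left[node], children_right[node]
    else:
        hot, cold = children_right[node], children_left[node]
    hot_zero = covers[hot] / covers[node]
    cold_zero = covers[cold] / covers[node]

    incoming_zero = 1.0
    incoming_one = 1.0
    path_index = 0
    while path_index <= unique_depth:
        if fi[path_index] == split:
            break
        path_index += 1
    if path_index != unique_depth + 1:
        incoming_zero = zf[path_index]
        incoming_one = of[path_index]
        _unwind_path(fi, zf, of, pw, unique_depth, path_index)
        unique_depth -= 1

    _tree_shap_recurse(children_left, children_right, features, thresholds,
                       values, covers, x, phi, hot, unique_depth + 1,
                       fi, zf, of, pw,
                       hot_zero * incoming_zero, incoming_one, split)
    _tree_shap_recurse(children_left, children_right, features, thresholds,
                       values, covers, x, phi, cold, unique_depth + 1,
                       fi, zf, of, pw,
                       cold_zero * incoming_zero, 0.0, split)


@njit(cache=False)
def _tree_shap_single(children_left, children_right, features, thresholds,
                      values, covers, max_depth, x, phi):
    size = (max_depth + 2) * (max_depth + 3) // 2
    fi = np.full(size, -1, dtype=np.int64)
    zf = np.zeros(size, dtype=np.float64)
    of = np.zeros(size, dtype=np.float64)
    pw = np.zeros(size, dtype=np.float64)
    _tree_shap_recurse(children_left, children_right, features, thresholds,
                       values, covers, x, phi, 0, 0, fi, zf, of, pw,
                       1.0, 1.0, -1)


def tree_shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Path-dependent TreeSHAP attributions for every row of ``X``.

    Returns ``(phi, base)`` with ``phi`` of shape (n_rows, n_features);
    ``base + phi.sum(axis=1)`` equals the model prediction exactly (up to
    float accumulation).  Ensembles average tree attributions, matching
    the forest's mean-of-trees prediction.
    """
    # sklearn compares float32-cast inputs against float64 thresholds at
    # predict time; replicate that routing exactly
    X = np.ascontiguousarray(X, dtype=np.float32).astype(np.float64)
    trees = extract_trees(model)
    n, p = X.shape
    phi = np.zeros((n, p), dtype=np.float64)
    buf = np.zeros(p, dtype=np.float64)
    for t in trees:
        for i in range(n):
            buf[:] = 0.0
            _tree_shap_single(t.children_left, t.children_right, t.features,
                              t.thresholds, t.values, t.covers, t.max_depth,
                              X[i], buf)
            phi[i] += buf
    phi /= len(trees)
    return phi, tree_expected_value(trees)


# ---------------------------------------------------------------------------
# Brute-force oracle (exhaustive coalitions, same value function)
# ---------------------------------------------------------------------------

def _conditional_expectation(t: TreeArrays, x: np.ndarray,
                             in_coalition: frozenset, node: int = 0) -> float:
    if t.children_left[node] < 0:
        return t.values[node]
    f = t.features[node]
    left, right = t.children_left[node], t.children_right[node]
    if f in in_coalition:
        child = left if x[f] <= t.thresholds[node] else right
        return _conditional_expectation(t, x, in_coalition, child)
    wl = t.covers[left] / t.covers[node]
    wr = t.covers[right] / t.covers[node]
    return (wl * _conditional_expectation(t, x, in_coalition, left)
            + wr * _conditional_expectation(t, x, in_coalition, right))


def brute_force_tree_shap(model, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive-coalition Shapley values for one observation.

    O(2^P) — the test oracle for :func:`tree_shap_values`; never used on
    real problem sizes.
    """
    x = np.asarray(x, dtype=np.float32).astype(np.float64)
    trees = extract_trees(model)
    p = len(x)
    phi = np.zeros(p)
    fact = [math.factorial(k) for k in range(p + 1)]
    for t in trees:
        v_cache: dict[frozenset, float] = {}

        def v(s: frozenset) -> float:
            if s not in v_cache:
                v_cache[s] = _conditional_expectation(t, x, s)
            return v_cache[s]

        for j in range(p):
            others = [k for k in range(p) if k != j]
            for r in range(p):
                w = fact[r] * fact[p - r - 1] / fact[p]
                for subset in combinations(others, r):
                    s = frozenset(subset)
                    phi[j] += w * (v(s | {j}) - v(s))
    phi /= len(trees)
    return phi, tree_expected_value(trees)


# ---------------------------------------------------------------------------
# Kernel SHAP (model-agnostic, interventional against a background)
# ---------------------------------------------------------------------------

def _masked_rows(x: np.ndarray, background: np.ndarray,
                 mask: np.ndarray) -> np.ndarray:
    """Background rows with coalition features replaced by ``x``'s values."""
    rows = background.copy()
    rows[:, mask] = x[mask]
    return rows


def _coalition_values(predict, x, background, masks) -> np.ndarray:
    blocks = [_masked_rows(x, background, m) for m in masks]
    preds = predict(np.vstack(blocks))
    b = len(background)
    return np.array([preds[i * b:(i + 1) * b].mean()
                     for i in range(len(masks))])


def _exact_kernel_shap(predict, x, background) -> tuple[np.ndarray, float]:
    p = len(x)
    fact = [math.factorial(k) for k in range(p + 1)]
    masks = []
    for bits in range(2 ** p):
        masks.append(np.array([(bits >> j) & 1 for j in range(p)], dtype=bool))
    vals = _coalition_values(predict, x, background, masks)
    value_by_bits = {bits: vals[bits] for bits in range(2 ** p)}
    phi = np.zeros(p)
    for j in range(p):
        for bits in range(2 ** p):
            if (bits >> j) & 1:
                continue
            s = bin(bits).count("1")
            w = fact[s] * fact[p - s - 1] / fact[p]
            phi[j] += w * (value_by_bits[bits | (1 << j)]
                           - value_by_bits[bits])
    base = value_by_bits[0]
    return phi, base


def _sampled_kernel_shap(predict, x, background, n_coalitions, rng,
                         ) -> tuple[np.ndarray, float]:
    p = len(x)
    base = float(predict(background).mean())
    fx = float(predict(x[None, :])[0])

    # always include singletons and their complements; sample the rest
    masks = []
    for j in range(p):
        m = np.zeros(p, dtype=bool); m[j] = True
        masks.append(m)
        masks.append(~m)
    sizes = np.arange(1, p)
    size_w = (p - 1) / (sizes * (p - sizes))
    size_w = size_w / size_w.sum()
    extra = max(0, n_coalitions - len(masks))
    for _ in range(extra):
        s = int(rng.choice(sizes, p=size_w))
        idx = rng.choice(p, size=s, replace=False)
        m = np.zeros(p, dtype=bool); m[idx] = True
        masks.append(m)

    Z = np.array(masks, dtype=float)
    vals = _coalition_values(predict, x, background, masks)
    sz = Z.sum(axis=1).astype(int)
    w = (p - 1) / (np.array([math.comb(p, s) for s in sz]) * sz * (p - sz))

    # weighted LS with the efficiency constraint sum(phi) = fx - base,
    # eliminating the last coefficient
    y = vals - base - Z[:, -1] * (fx - base)
    A = Z[:, :-1] - Z[:, [-1]]
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * W[:, None], y * W, rcond=None)
    phi = np.empty(p)
    phi[:-1] = coef
    phi[-1] = (fx - base) - coef.sum()
    return phi, base


def kernel_shap_values(predict: Callable[[np.ndarray], np.ndarray],
                       X: np.ndarray, background: np.ndarray,
                       seed: int = 0, n_coalitions: int = 2048,
                       exact_up_to: int = 11,
                       ) -> tuple[np.ndarray, float]:
    """Interventional Shapley values for every row of ``X``.

    Full coalition enumeration (exact) when the feature count is at most
    ``exact_up_to``; otherwise seeded coalition sampling with the
    Shapley-kernel weighted least squares.  Either way the efficiency
    constraint makes ``base + phi.sum(1)`` match predictions exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    base = float(predict(background).mean())
    for i in range(n):
        if p <= exact_up_to:
            phi[i], _ = _exact_kernel_shap(predict, X[i], background)
        else:
            phi[i], _ = _sampled_kernel_shap(predict, X[i], background,
                                             n_coalitions, rng)
    return phi, base
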
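"""Exact Shapley attributions for decision-tree ensembles.

Path-dependent polynomial-time TreeSHAP: node cover fractions approximate
the conditional expectation E[f(x) | x_S] along each decision path, and the
recursion keeps, for every subset size, the proportion of feature-subset
permutations flowing down the path ("extend"/"unwind" bookkeeping).  The
attributions satisfy local accuracy exactly:

    sum_i phi_i(x) = f(x) - E[f]

Supported models: sklearn DecisionTree/RandomForest/ExtraTrees/
GradientBoosting (classifier attributions are on the probability of
``class_index``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "expected_value"]


class _PathElement:
    __slots__ = ("feature", "zero", "one", "weight")

    def __init__(self, feature, zero, one, weight):
        self.feature = feature
        self.zero = zero
        self.one = one
        self.weight = weight

    def copy(self):
        return _PathElement(self.feature, self.zero, self.one, self.weight)


def _extend(path, zero, one, feature):
    path = [p.copy() for p in path]
    d = len(path)
    path.append(_PathElement(feature, zero, one, 1.0 if d == 0 else 0.0))
    for i in range(d - 1, -1, -1):
        path[i + 1].weight += one * path[i].weight * (i + 1) / (d + 1)
        path[i].weight = zero * path[i].weight * (d - i) / (d + 1)
    return path


def _unwind(path, index):
    path = [p.copy() for p in path]
    d = len(path) - 1
    one = path[index].one
    zero = path[index].zero
    carry = path[d].weight
    for i in range(d - 1, -1, -1):
        if one != 0:
            tmp = path[i].weight
            path[i].weight = carry * (d + 1) / ((i + 1) * one)
            carry = tmp - path[i].weight * zero * (d - i) / (d + 1)
        else:
            path[i].weight = path[i].weight * (d + 1) / (zero * (d - i))
    for i in range(index, d):
        path[i].feature = path[i + 1].feature
        path[i].zero = path[i + 1].zero
        path[i].one = path[i + 1].one
    path.pop()
    return path


def _unwound_sum(path, index):
    d = len(path) - 1
    one = path[index].one
    zero = path[index].zero
    total = 0.0
    if one != 0:
        carry = path[d].weight
        for i in range(d - 1, -1, -1):
            tmp = carry * (d + 1) / ((i + 1) * one)
            total += tmp
            carry = path[i].weight - tmp * zero * (d - i) / (d + 1)
    else:
        for i in range(d - 1, -1, -1):
            total += path[i].weight * (d + 1) / (zero * (d - i))
    return total


def _single_tree_shap(arrays, x, phi):
    left, right, feature, threshold, values, cover = arrays

    def recurse(node, path, zero, one, parent_feature):
        path = _extend(path, zero, one, parent_feature)
        if left[node] < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[path[i].feature] += w * (path[i].one - path[i].zero) * values[node]
        else:
            f = feature[node]
            hot, cold = (
                (left[node], right[node])
                if x[f] <= threshold[node]
                else (right[node], left[node])
            )
            iz, io = 1.0, 1.0
            k = next((i for i in range(1, len(path)) if path[i].feature == f), None)
            if k is not None:
                iz, io = path[k].zero, path[k].one
                path = _unwind(path, k)
            recurse(hot, path, iz * cover[hot] / cover[node], io, f)
            recurse(cold, path, iz * cover[cold] / cover[node], 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def _leaf_values(sk_tree, class_index):
    values = sk_tree.tree_.value  # (n_nodes, 1, n_out)
    v = values[:, 0, :]
    if v.shape[1] > 1:  # classifier: normalize to class probability
        totals = v.sum(axis=1, keepdims=True)
        v = v / np.where(totals > 0, totals, 1.0)
        return v[:, class_index].astype(float)
    return v[:, 0].astype(float)


def _tree_arrays(sk_tree, class_index):
    t = sk_tree.tree_
    return (
        t.children_left,
        t.children_right,
        t.feature,
        t.threshold,
        _leaf_values(sk_tree, class_index),
        t.weighted_n_node_samples,
    )


def _tree_expected(arrays):
    left, right, _, _, values, cover = arrays
    leaves = left < 0
    return float(np.sum(values[leaves] * cover[leaves]) / cover[0])


def _component_trees(model):
    if hasattr(model, "estimators_"):
        ests = np.asarray(model.estimators_).ravel()
        return list(ests), 1.0 / len(ests)
    if hasattr(model, "tree_"):
        return [model], 1.0
    raise TypeError(
        f"unsupported model type {type(model).__name__}; supported: sklearn "
        "DecisionTree*, RandomForest*, ExtraTrees* (and tree ensembles with estimators_)"
    )


def expected_value(model, class_index: int = 1) -> float:
    """Cover-weighted mean prediction (the attribution baseline)."""
    trees, scale = _component_trees(model)
    return scale * sum(_tree_expected(_tree_arrays(t, class_index)) for t in trees)


def tree_shap_values(model, X, class_index: int = 1) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature Shapley attributions and the expected value.

    For classifiers the explained output is predict_proba[:, class_index].
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    trees, scale = _component_trees(model)
    arrays = [_tree_arrays(t, class_index) for t in trees]
    phi = np.zeros((X.shape[0], X.shape[1]))
    for row in range(X.shape[0]):
        acc = np.zeros(X.shape[1] + 1)  # slot -1 absorbs the root marker
        for arr in arrays:
            _single_tree_shap(arr, X[row], acc)
        phi[row] = scale * acc[: X.shape[1]]
    base = scale * sum(_tree_expected(a) for a in arrays)
    return phi, base
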
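"""Path-dependent TreeSHAP for scikit-learn decision-tree ensembles.

Computes exact Shapley values of the conditional-expectation game defined by a
decision tree, where the value of a feature coalition S is the tree's expected
output when features in S are fixed to the explained instance and the
complement is marginalised along the tree's own training-cover distribution
(the "tree-path-dependent" formulation).  For a forest that averages tree
outputs, Shapley values are the mean of the per-tree values, so additivity

    baseline + sum_i(phi_i) = f(x)

holds exactly, with ``f`` the forest's class-1 probability and ``baseline``
the cover-weighted expectation of the forest output.

The per-tree computation runs in O(L * D^2) per explained instance (L leaves,
D maximum depth) by maintaining a path of "unique" features with the weights
of all coalition subsets extended/unwound incrementally.  The inner recursion
is numba-compiled; the first call in a process pays a one-off JIT cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tree_shap_values", "forest_shap_values"]


@njit(cache=False)
def _unwound_sum(path, ud, k):
    # Sum of subset weights after removing path element k, without mutating.
    one = path[k, 2]
    zero = path[k, 1]
    total = 0.0
    if one != 0.0:
        nxt = path[ud, 3]
        for i in range(ud - 1, -1, -1):
            tmp = nxt * (ud + 1.0) / ((i + 1.0) * one)
            total += tmp
            nxt = path[i, 3] - tmp * zero * (ud - i) / (ud + 1.0)
    else:
        for i in range(ud - 1, -1, -1):
            total += path[i, 3] * (ud + 1.0) / (zero * (ud - i))
    return total


@njit(cache=False)
def _unwind(path, ud, k):
    # Remove path element k in place; path length shrinks from ud+1 to ud.
    one = path[k, 2]
    zero = path[k, 1]
    nxt = path[ud, 3]
    for i in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = path[i, 3]
            path[i, 3] = nxt * (ud + 1.0) / ((i + 1.0) * one)
            nxt = tmp - path[i, 3] * zero * (ud - i) / (ud + 1.0)
        else:
            path[i, 3] = path[i, 3] * (ud + 1.0) / (zero * (ud - i))
    for i in range(k, ud):
        path[i, 0] = path[i + 1, 0]
        path[i, 1] = path[i + 1, 1]
        path[i, 2] = path[i + 1, 2]


@njit(cache=False)
def _recurse(j, ud, parent_path, pz, po, pf,
             x, left, right, feat, thresh, value, cover, phi):
    # path columns: 0=feature index, 1=zero fraction, 2=one fraction, 3=weight
    path = np.empty((ud + 1, 4))
    for i in range(ud):
        for c in range(4):
            path[i, c] = parent_path[i, c]
    # extend with the incoming split
    path[ud, 0] = pf
    path[ud, 1] = pz
    path[ud, 2] = po
    path[ud, 3] = 1.0 if ud == 0 else 0.0
    for i in range(ud - 1, -1, -1):
        path[i + 1, 3] += po * path[i, 3] * (i + 1.0) / (ud + 1.0)
        path[i, 3] = pz * path[i, 3] * (ud - i) / (ud + 1.0)

    if left[j] < 0:  # leaf
        v = value[j]
        for i in range(1, ud + 1):
            w = _unwound_sum(path, ud, i)
            phi[int(path[i, 0])] += w * (path[i, 2] - path[i, 1]) * v
    else:
        f = feat[j]
        if x[f] <= thresh[j]:
            hot, cold = left[j], right[j]
        else:
            hot, cold = right[j], left[j]
        hot_z = cover[hot] / cover[j]
        cold_z = cover[cold] / cover[j]
        iz = 1.0
        io = 1.0
        cur = ud
        k = -1
        for i in range(1, ud + 1):
            if int(path[i, 0]) == f:
                k = i
                break
        if k >= 0:  # feature already on the path: merge its fractions
            iz = path[k, 1]
            io = path[k, 2]
            _unwind(path, cur, k)
            cur -= 1
        _recurse(hot, cur + 1, path, hot_z * iz, io, f,
                 x, left, right, feat, thresh, value, cover, phi)
        _recurse(cold, cur + 1, path, cold_z * iz, 0.0, f,
                 x, left, right, feat, thresh, value, cover, phi)


@njit(cache=False)
def _tree_shap_batch(X, left, right, feat, thresh, value, cover):
    n, p = X.shape
    phi = np.zeros((n, p))
    root = np.empty((1, 4))
    for s in range(n):
        _recurse(0, 0, root, 1.0, 1.0, -1,
                 X[s], left, right, feat, thresh, value, cover, phi[s])
    return phi


def _tree_arrays(tree, class_index=1):
    """Extract flat arrays from a fitted sklearn Tree, output = class fraction."""
    t = tree.tree_
    val = np.asarray(t.value[:, 0, :], dtype=np.float64)
    row = val.sum(axis=1)
    row[row == 0] = 1.0
    if val.shape[1] == 1:  # regression tree
        out = val[:, 0]
    else:
        out = val[:, class_index] / row
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        out,
        t.weighted_n_node_samples.astype(np.float64),
    )


def tree_shap_values(tree, X, class_index=1):
    """Shapley values (n, p) and baseline for one fitted decision tree."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    left, right, feat, thresh, value, cover = _tree_arrays(tree, class_index)
    phi = _tree_shap_batch(X, left, right, feat, thresh, value, cover)
    return phi, float(value[0])


def forest_shap_values(forest, X, class_index=1):
    """Shapley values for a RandomForestClassifier's class probability.

    Returns
    -------
    phi : ndarray (n_samples, n_features)
        Per-feature additive contributions in probability units.
    baseline : float
        Cover-weighted expected forest output E[f(x)]; baseline + phi.sum(1)
        equals ``forest.predict_proba(X)[:, class_index]`` to float precision.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, p = X.shape
    phi = np.zeros((n, p))
    baseline = 0.0
    trees = forest.estimators_
    for est in trees:
        left, right, feat, thresh, value, cover = _tree_arrays(est, class_index)
        phi += _tree_shap_batch(X, left, right, feat, thresh, value, cover)
        baseline += float(value[0])
    m = len(trees)
    return phi / m, baseline / m
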
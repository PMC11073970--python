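"""Shapley-additive feature attributions for tree ensembles.

Path-dependent TreeSHAP for scikit-learn decision trees and random forests:
for each sample, the exact Shapley values of the tree's conditional
expectation function are computed in O(leaves x depth^2) per tree by
propagating subset-permutation weights down each root-to-leaf path.

The attributions satisfy the additivity (local accuracy) contract exactly:
``phi.sum(axis=1) + expected_value == model prediction`` for every sample,
which the test suite asserts to 1e-6.  The per-tree kernel is numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _extend(pd_, pz_, po_, pw_, plen, pz, po, pi):
    l = plen
    pd_[l] = pi
    pz_[l] = pz
    po_[l] = po
    pw_[l] = 1.0 if l == 0 else 0.0
    for i in range(l - 1, -1, -1):
        pw_[i + 1] += po * pw_[i] * (i + 1.0) / (l + 1.0)
        pw_[i] = pz * pw_[i] * (l - i) / (l + 1.0)
    return l + 1


@njit(cache=False)
def _unwind(pd_, pz_, po_, pw_, plen, i):
    l = plen - 1
    one = po_[i]
    zero = pz_[i]
    n = pw_[l]
    for j in range(l - 1, -1, -1):
        if one != 0.0:
            tmp = pw_[j]
            pw_[j] = n * (l + 1.0) / ((j + 1.0) * one)
            n = tmp - pw_[j] * zero * (l - j) / (l + 1.0)
        else:
            pw_[j] = pw_[j] * (l + 1.0) / (zero * (l - j))
    for j in range(i, l):
        pd_[j] = pd_[j + 1]
        pz_[j] = pz_[j + 1]
        po_[j] = po_[j + 1]
    return plen - 1


@njit(cache=False)
def _unwound_sum(pz_, po_, pw_, plen, i):
    l = plen - 1
    one = po_[i]
    zero = pz_[i]
    n = pw_[l]
    total = 0.0
    for j in range(l - 1, -1, -1):
        if one != 0.0:
            tmp = n * (l + 1.0) / ((j + 1.0) * one)
            total += tmp
            n = pw_[j] - tmp * zero * (l - j) / (l + 1.0)
        else:
            total += pw_[j] * (l + 1.0) / (zero * (l - j))
    return total


@njit(cache=False)
def _tree_shap_sample(cl, cr, feat, thr, cover, leafval, x, phi, max_depth):
    depth_cap = max_depth + 2
    # per-level path buffers: a frame at level t derives its path from t-1
    pd_ = np.empty((depth_cap + 1, depth_cap + 1), dtype=np.int64)
    pz_ = np.empty((depth_cap + 1, depth_cap + 1), dtype=np.float64)
    po_ = np.empty((depth_cap + 1, depth_cap + 1), dtype=np.float64)
    pw_ = np.empty((depth_cap + 1, depth_cap + 1), dtype=np.float64)
    plen = np.zeros(depth_cap + 1, dtype=np.int64)

    cap = 2 * depth_cap + 4
    st_node = np.empty(cap, dtype=np.int64)
    st_lvl = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_pi = np.empty(cap, dtype=np.int64)

    sp = 0
    st_node[sp], st_lvl[sp], st_pz[sp], st_po[sp], st_pi[sp] = 0, 0, 1.0, 1.0, -1
    sp += 1

    while sp > 0:
        sp -= 1
        j = st_node[sp]
        t = st_lvl[sp]
        pz = st_pz[sp]
        po = st_po[sp]
        pi = st_pi[sp]

        if t == 0:
            cur = 0
        else:
            cur = plen[t - 1]
            for q in range(cur):
                pd_[t, q] = pd_[t - 1, q]
                pz_[t, q] = pz_[t - 1, q]
                po_[t, q] = po_[t - 1, q]
                pw_[t, q] = pw_[t - 1, q]
        cur = _extend(pd_[t], pz_[t], po_[t], pw_[t], cur, pz, po, pi)
        plen[t] = cur

        if cl[j] < 0:  # leaf
            for i in range(1, cur):
                w = _unwound_sum(pz_[t], po_[t], pw_[t], cur, i)
                phi[pd_[t, i]] += w * (po_[t, i] - pz_[t, i]) * leafval[j]
        else:
            d = feat[j]
            if x[d] <= thr[j]:
                hot, cold = cl[j], cr[j]
            else:
                hot, cold = cr[j], cl[j]
            iz = 1.0
            io = 1.0
            for q in range(cur):
                if pd_[t, q] == d:
                    iz = pz_[t, q]
                    io = po_[t, q]
                    cur = _unwind(pd_[t], pz_[t], po_[t], pw_[t], cur, q)
                    plen[t] = cur
                    break
            # cold child first so the hot subtree is explored first
            st_node[sp], st_lvl[sp], st_pi[sp] = cold, t + 1, d
            st_pz[sp] = iz * cover[cold] / cover[j]
            st_po[sp] = 0.0
            sp += 1
            st_node[sp], st_lvl[sp], st_pi[sp] = hot, t + 1, d
            st_pz[sp] = iz * cover[hot] / cover[j]
            st_po[sp] = io
            sp += 1


@njit(cache=False)
def _tree_shap_batch(cl, cr, feat, thr, cover, leafval, X, phi, max_depth):
    for s in range(X.shape[0]):
        _tree_shap_sample(cl, cr, feat, thr, cover, leafval, X[s], phi[s], max_depth)


def _leaf_values(tree) -> np.ndarray:
    """Scalar per-node output: class-1 probability or regression value."""
    v = tree.value
    if v.shape[2] == 1:  # regression
        return np.ascontiguousarray(v[:, 0, 0], dtype=np.float64)
    totals = v[:, 0, :].sum(axis=1)
    return np.ascontiguousarray(v[:, 0, 1] / np.where(totals > 0, totals, 1.0))


def tree_shap_values(model, X) -> tuple[np.ndarray, float]:
    """Shapley attributions (n_samples, n_features) and the expected value.

    ``model`` is a fitted sklearn decision tree or random forest; for
    classifiers the explained output is the predicted probability of the
    second class.  ``phi.sum(1) + expected_value`` equals the model output.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    estimators = getattr(model, "estimators_", [model])
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    for est in estimators:
        t = est.tree_
        leafval = _leaf_values(t)
        cover = np.ascontiguousarray(t.weighted_n_node_samples, dtype=np.float64)
        _tree_shap_batch(
            np.ascontiguousarray(t.children_left, dtype=np.int64),
            np.ascontiguousarray(t.children_right, dtype=np.int64),
            np.ascontiguousarray(t.feature, dtype=np.int64),
            np.ascontiguousarray(t.threshold, dtype=np.float64),
            cover,
            leafval,
            X,
            phi,
            int(t.max_depth),
        )
        leaves = t.children_left < 0
        base += float((cover[leaves] * leafval[leaves]).sum() / cover[0])
    n_trees = len(estimators)
    return phi / n_trees, base / n_trees
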
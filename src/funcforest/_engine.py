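"""JIT-compiled tree growth and traversal kernels.

All SSD-family node costs (scalar SSD, region-wise SSD, PCA, basis, and
Mahalanobis) can be written as the per-column sum of squared deviances of a
linearly transformed target matrix ``Z``.  For such costs the split reward

    C = D(parent) - D(left) - D(right)
      = sum_c [ S_L(c)^2 / n_L + S_R(c)^2 / n_R - S_P(c)^2 / n_P ]

depends only on prefix sums of ``Z`` in feature-sorted order, which the
kernels below exploit: every candidate threshold (midpoints of consecutive
distinct feature values) is scored in O(n * k) per feature.

Trees are stored packed in flat arrays (one row block per tree): split
feature (-1 marks a leaf), threshold, child ids, and the [start, end) slice
of the tree's member array (original sample ids with bootstrap multiplicity).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: relative tolerance for requiring a strictly positive split reward
_REWARD_TOL = 1e-10


@njit(cache=True)
def _draw_subset(n_features, m):
    """m distinct feature indices, sorted ascending (partial Fisher-Yates)."""
    pool = np.arange(n_features)
    for i in range(m):
        j = i + np.random.randint(0, n_features - i)
        tmp = pool[i]
        pool[i] = pool[j]
        pool[j] = tmp
    return np.sort(pool[:m])


@njit(cache=True)
def best_split_ssd(X, Z, idxs, subset):
    """Best (feature, threshold, reward) over a candidate feature subset.

    ``idxs`` are original-sample row indices (with bootstrap multiplicity)
    of the node; returns feature -1 when no admissible split has a strictly
    positive reward.  Ties are broken by lowest feature index, then lowest
    threshold.
    """
    ns = idxs.size
    k = Z.shape[1]
    s_tot = np.zeros(k)
    for p in range(ns):
        r = idxs[p]
        for c in range(k):
            s_tot[c] += Z[r, c]
    base = 0.0
    for c in range(k):
        base += s_tot[c] * s_tot[c] / ns
    best_val = base + _REWARD_TOL * (base + 1.0)
    best_f = -1
    best_thr = 0.0
    xv = np.empty(ns)
    s = np.empty(k)
    for fi in range(subset.size):
        f = subset[fi]
        for p in range(ns):
            xv[p] = X[idxs[p], f]
        order = np.argsort(xv)
        for c in range(k):
            s[c] = 0.0
        for i in range(ns - 1):
            r = idxs[order[i]]
            for c in range(k):
                s[c] += Z[r, c]
            if xv[order[i]] == xv[order[i + 1]]:
                continue
            nl = i + 1
            nr = ns - nl
            val = 0.0
            for c in range(k):
                d = s_tot[c] - s[c]
                val += s[c] * s[c] / nl + d * d / nr
            if val > best_val:
                best_val = val
                best_f = f
                best_thr = 0.5 * (xv[order[i]] + xv[order[i + 1]])
    return best_f, best_thr, best_val - base


@njit(cache=True)
def grow_tree(X, Z, members, m, n_size, max_depth, seed,
              feature, thr, left, right, start, end, picked, selected):
    """Grow one tree in place; returns the number of nodes.

    ``members`` holds original sample ids (bootstrap draw) and is reordered
    in place so each node owns a contiguous [start, end) slice.  ``picked``
    and ``selected`` accumulate per-feature candidacy/selection counts for
    the frequency-based variable importance.
    """
    np.random.seed(seed)
    n = members.size
    cap = feature.size
    stack_node = np.empty(cap, dtype=np.int64)
    stack_start = np.empty(cap, dtype=np.int64)
    stack_end = np.empty(cap, dtype=np.int64)
    stack_depth = np.empty(cap, dtype=np.int64)
    buf = np.empty(n, dtype=members.dtype)

    n_nodes = 1
    top = 0
    stack_node[0] = 0
    stack_start[0] = 0
    stack_end[0] = n
    stack_depth[0] = 0
    while top >= 0:
        node = stack_node[top]
        lo = stack_start[top]
        hi = stack_end[top]
        depth = stack_depth[top]
        top -= 1
        feature[node] = -1
        thr[node] = np.nan
        left[node] = -1
        right[node] = -1
        start[node] = lo
        end[node] = hi
        ns = hi - lo
        if ns <= n_size or (max_depth >= 0 and depth >= max_depth):
            continue
        subset = _draw_subset(X.shape[1], m)
        for fi in range(subset.size):
            picked[subset[fi]] += 1
        f, t, reward = best_split_ssd(X, Z, members[lo:hi], subset)
        if f < 0:
            continue
        selected[f] += 1
        # stable partition by x <= t
        nl = 0
        for p in range(lo, hi):
            if X[members[p], f] <= t:
                buf[nl] = members[p]
                nl += 1
        nr = nl
        for p in range(lo, hi):
            if X[members[p], f] > t:
                buf[nr] = members[p]
                nr += 1
        for p in range(ns):
            members[lo + p] = buf[p]
        feature[node] = f
        thr[node] = t
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        top += 1
        stack_node[top] = rid
        stack_start[top] = lo + nl
        stack_end[top] = hi
        stack_depth[top] = depth + 1
        top += 1
        stack_node[top] = lid
        stack_start[top] = lo
        stack_end[top] = lo + nl
        stack_depth[top] = depth + 1
    return n_nodes


@njit(cache=True)
def fit_forest(X, Z, boot, seeds, m, n_size, max_depth,
               feature, thr, left, right, start, end, members,
               node_count, picked, selected):
    """Grow T trees from pre-drawn bootstrap index lists."""
    T = boot.shape[0]
    for t in range(T):
        members[t, :] = boot[t, :]
        node_count[t] = grow_tree(X, Z, members[t], m, n_size, max_depth,
                                  seeds[t], feature[t], thr[t], left[t],
                                  right[t], start[t], end[t], picked, selected)


@njit(cache=True)
def leaf_ids(Xq, feature, thr, left, right):
    """Leaf node id reached by each query row, for each tree."""
    nq = Xq.shape[0]
    T = feature.shape[0]
    out = np.empty((T, nq), dtype=np.int64)
    for t in range(T):
        for qi in range(nq):
            node = 0
            while feature[t, node] >= 0:
                if Xq[qi, feature[t, node]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            out[t, qi] = node
    return out


@njit(cache=True)
def forest_weights(Xq, feature, thr, left, right, start, end, members, n_train):
    """Forest prediction weights over training samples (rows sum to 1).

    Per tree, the weight of training sample i is its bootstrap multiplicity
    in the leaf containing the query, divided by the leaf size; forest
    weights average over trees.
    """
    nq = Xq.shape[0]
    T = feature.shape[0]
    W = np.zeros((nq, n_train))
    for t in range(T):
        for qi in range(nq):
            node = 0
            while feature[t, node] >= 0:
                if Xq[qi, feature[t, node]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            lo = start[t, node]
            hi = end[t, node]
            inc = 1.0 / ((hi - lo) * T)
            for p in range(lo, hi):
                W[qi, members[t, p]] += inc
    return W
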
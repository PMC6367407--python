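"""Single functional regression trees.

A tree is grown by exhaustive threshold search over a random subset of ``m``
features at each node: every midpoint between consecutive distinct sorted
values of each candidate feature is scored by the reduction in node cost
(reward) ``C = D(parent) - D(left) - D(right)``, and the split maximising the
reward is taken.  Ties are broken by lowest feature index, then lowest
threshold; splits whose reward is not strictly positive are rejected, and a
node with at most ``n_size`` samples (or at the depth limit) becomes a leaf.
Leaves keep their member sample indices so whole response curves can be
retrieved at prediction time.

SSD-family costs are dispatched to the compiled kernels in
:mod:`funcforest._engine`; the distribution-based divergence costs use a
vectorised prefix-sum search implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _engine
from .curves import DoseGrid, ResponseDistributionCurve, fit_bspline, matrix_to_curves
from .split_costs import (
    NodeCostSpec,
    default_omega,
    density_tensor,
    pca_components,
)

__all__ = ["GrowthParams", "TreeNode", "best_split", "grow_tree", "traverse",
           "ssd_family_transform", "tree_to_records"]


@dataclass
class GrowthParams:
    """Tree-growth hyperparameters.

    ``m`` is the feature-subset size drawn fresh at every node, ``n_size`` the
    minimum node size for further splitting (a node with at most ``n_size``
    samples becomes a leaf), ``max_depth`` an optional depth cap, and
    ``rng_seed`` the seed for the subset draws.
    """

    m: int
    n_size: int = 10
    max_depth: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_size < 1:
            raise ValueError("n_size must be >= 1")


class TreeNode:
    """A node of a grown tree; leaves have ``split_feature is None``."""

    __slots__ = ("node_id", "split_feature", "threshold", "left", "right",
                 "member_indices", "leaf_payload")

    def __init__(self, node_id, split_feature=None, threshold=None,
                 left=None, right=None, member_indices=None, leaf_payload=None):
        self.node_id = node_id
        self.split_feature = split_feature
        self.threshold = threshold
        self.left = left
        self.right = right
        self.member_indices = member_indices
        self.leaf_payload = leaf_payload

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"TreeNode(leaf #{self.node_id}, n={len(self.member_indices)})"
        return (f"TreeNode(#{self.node_id}, x[{self.split_feature}] "
                f"<= {self.threshold:.6g})")


# ---------------------------------------------------------------------------
# target transforms for the SSD cost family
# ---------------------------------------------------------------------------


def _whitening_matrix(cov: np.ndarray, ridge: float | None) -> np.ndarray:
    m = cov.shape[0]
    if ridge is None:
        ridge = 1e-6 * np.trace(cov) / m
    w, v = np.linalg.eigh(cov + ridge * np.eye(m))
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("covariance not positive definite")
    return v / np.sqrt(w)


def ssd_family_transform(spec: NodeCostSpec, targets: np.ndarray,
                         grid: DoseGrid | None = None,
                         covariance: np.ndarray | None = None) -> np.ndarray:
    """Transformed target matrix ``Z`` whose per-column SSD equals the cost.

    Every SSD-family node cost is a quadratic form around the node mean, so
    it equals the plain SSD of ``Z = Y @ A`` for a suitable ``A``: identity
    (region_ssd), the leading principal axes (pca), the Cholesky factor of
    the basis Gram matrix applied to spline coefficients (basis), or the
    covariance whitening matrix (mahalanobis).
    """
    y = np.asarray(targets, dtype=float)
    if spec.kind == "ssd":
        if y.ndim != 1:
            raise ValueError("ssd cost expects scalar targets")
        return y[:, None].copy()
    y = np.atleast_2d(y)
    if spec.kind == "region_ssd":
        return np.ascontiguousarray(y)
    if spec.kind == "pca":
        comps = pca_components(y, spec.pc_count)
        return np.ascontiguousarray(y @ comps)
    if spec.kind == "mahalanobis":
        if covariance is None:
            covariance = np.cov(y, rowvar=False, bias=False)
        return np.ascontiguousarray(y @ _whitening_matrix(covariance, None))
    if spec.kind == "basis":
        if grid is None:
            raise ValueError("basis cost needs the dose grid")
        curves = matrix_to_curves(y, grid)
        n_basis = min(len(grid), 8)
        splines = [fit_bspline(c, order=min(4, n_basis), n_basis=n_basis)
                   for c in curves]
        coef = np.vstack([s.coefficients for s in splines])
        gram = splines[0].gram
        chol = np.linalg.cholesky(gram + 1e-10 * np.trace(gram) * np.eye(gram.shape[0]))
        return np.ascontiguousarray(coef @ chol)
    raise ValueError(f"not an SSD-family cost: {spec.kind!r}")


# ---------------------------------------------------------------------------
# divergence-cost split search (prefix-sum form)
# ---------------------------------------------------------------------------


def _div_stat(S: np.ndarray, n, kind: str, R: np.ndarray | None):
    """Node-cost statistic whose across-children sum yields the reward.

    For KL the node cost is ``sum_i H_i - G(S, n)`` with
    ``G = sum_k S_k (ln S_k - ln n)``; the per-sample entropies ``H_i`` cancel
    in the reward, so ``reward = G_L + G_R - G_P``.  For Hellinger the cost is
    ``2 n q - 2 A(S, R, n)`` with ``A = sum_k sqrt(S_k / n) R_k`` and ``R`` the
    summed square-root masses, giving ``reward = 2 (A_L + A_R - A_P)``.
    """
    n = np.asarray(n, dtype=float)
    if kind == "kl":
        return np.sum(S * (np.log(S) - np.log(n)[..., None]), axis=-1)
    return 2.0 * np.sum(np.sqrt(S / n[..., None]) * R, axis=-1)


def _best_split_divergence(X: np.ndarray, P: np.ndarray, idxs: np.ndarray,
                           subset: np.ndarray, kind: str):
    """Exact analogue of the compiled SSD split search for divergence costs."""
    ns = idxs.size
    sqrtP = np.sqrt(P) if kind == "hellinger" else None
    S_P = P[idxs].sum(axis=0)
    R_P = sqrtP[idxs].sum(axis=0) if kind == "hellinger" else None
    base = float(_div_stat(S_P, ns, kind, R_P))
    tol = _engine._REWARD_TOL * (abs(base) + 1.0)
    best = (-1, 0.0, 0.0)
    best_val = base + tol
    n_l = np.arange(1, ns, dtype=float)
    n_r = ns - n_l
    for f in np.sort(subset):
        xv = X[idxs, f]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        valid = xs[:-1] != xs[1:]
        if not valid.any():
            continue
        cs = np.cumsum(P[idxs[order]], axis=0)
        S_L = cs[:-1]
        if kind == "hellinger":
            cr = np.cumsum(sqrtP[idxs[order]], axis=0)
            vals = _div_stat(S_L, n_l, kind, cr[:-1]) \
                + _div_stat(S_P - S_L, n_r, kind, cr[-1] - cr[:-1])
        else:
            vals = _div_stat(S_L, n_l, kind, None) \
                + _div_stat(S_P - S_L, n_r, kind, None)
        vals = np.where(valid, vals, -np.inf)
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val = float(vals[i])
            best = (int(f), 0.5 * (xs[i] + xs[i + 1]), best_val - base)
    return None if best[0] < 0 else best


def grow_tree_divergence(X, P, members, m, n_size, max_depth, rng,
                         feature, thr, left, right, start, end,
                         picked, selected, kind):
    """Python twin of the compiled grower, for divergence node costs.

    ``P`` is the flattened density tensor (one row per training sample,
    regions concatenated).  Fills the same packed node arrays.
    """
    n = members.size
    buf = np.empty_like(members)
    n_nodes = 1
    stack = [(0, 0, n, 0)]
    while stack:
        node, lo, hi, depth = stack.pop()
        feature[node] = -1
        thr[node] = np.nan
        left[node] = right[node] = -1
        start[node], end[node] = lo, hi
        ns = hi - lo
        if ns <= n_size or (max_depth is not None and depth >= max_depth):
            continue
        subset = np.sort(rng.choice(X.shape[1], size=m, replace=False))
        picked[subset] += 1
        res = _best_split_divergence(X, P, members[lo:hi], subset, kind)
        if res is None:
            continue
        f, t, _ = res
        selected[f] += 1
        node_members = members[lo:hi]
        go_left = X[node_members, f] <= t
        nl = int(go_left.sum())
        buf[:nl] = node_members[go_left]
        buf[nl:ns] = node_members[~go_left]
        members[lo:hi] = buf[:ns]
        feature[node] = f
        thr[node] = t
        lid, rid = n_nodes, n_nodes + 1
        n_nodes += 2
        left[node], right[node] = lid, rid
        stack.append((rid, lo + nl, hi, depth + 1))
        stack.append((lid, lo, lo + nl, depth + 1))
    return n_nodes


# ---------------------------------------------------------------------------
# public single-tree API
# ---------------------------------------------------------------------------


def _divergence_density_matrix(targets, spec: NodeCostSpec) -> np.ndarray:
    """Flattened (n, q * |omega|) density matrix from distribution targets."""
    if isinstance(targets, tuple):
        means, sds = targets
    else:
        means = np.vstack([d.means for d in targets])
        sds = np.vstack([d.sds for d in targets])
    means = np.atleast_2d(np.asarray(means, dtype=float))
    sds = np.atleast_2d(np.asarray(sds, dtype=float))
    omega = spec.omega
    if omega is None:
        omega = default_omega(means, sds, spec.omega_points)
    P = density_tensor(means, sds, omega, spec.epsilon or 1e-12)
    return P.reshape(P.shape[0], -1)


def best_split(features: np.ndarray, targets, feature_subset: Sequence[int],
               cost: NodeCostSpec, grid: DoseGrid | None = None):
    """Best split of one node over a candidate feature subset.

    ``targets`` are the node's payloads: a scalar vector (ssd), a response
    matrix or curve list (functional costs), or per-dose (means, sds) /
    distribution curves (divergence costs).  Returns ``(feature, threshold,
    reward)`` or ``None`` when no admissible split has positive reward.
    """
    X = np.ascontiguousarray(np.asarray(features, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("node needs at least 2 samples")
    subset = np.sort(np.asarray(list(feature_subset), dtype=np.int64))
    if subset.size == 0:
        raise ValueError("feature subset must be nonempty")
    idxs = np.arange(X.shape[0], dtype=np.int64)
    if cost.is_divergence:
        P = _divergence_density_matrix(targets, cost)
        return _best_split_divergence(X, P, idxs, subset, cost.kind)
    if not isinstance(targets, np.ndarray):
        targets = np.vstack([c.values for c in targets])
    Z = ssd_family_transform(cost, targets, grid=grid)
    f, t, reward = _engine.best_split_ssd(X, Z, idxs, subset)
    return None if f < 0 else (int(f), float(t), float(reward))


def _packed_arrays(n: int):
    cap = 2 * n
    return (np.full(cap, -1, dtype=np.int64), np.full(cap, np.nan),
            np.full(cap, -1, dtype=np.int64), np.full(cap, -1, dtype=np.int64),
            np.zeros(cap, dtype=np.int64), np.zeros(cap, dtype=np.int64))


def grow_tree(features: np.ndarray, targets, params: GrowthParams,
              cost: NodeCostSpec, grid: DoseGrid | None = None,
              sample_indices: np.ndarray | None = None) -> TreeNode:
    """Grow a single tree and return its root :class:`TreeNode`.

    ``sample_indices`` (default all samples once) may repeat indices to
    express a bootstrap draw.  Leaf payloads are the member indices' targets.
    """
    X = np.ascontiguousarray(np.asarray(features, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    members = (np.arange(n, dtype=np.int64) if sample_indices is None
               else np.asarray(sample_indices, dtype=np.int64).copy())
    feature, thr, left, right, start, end = _packed_arrays(members.size)
    picked = np.zeros(X.shape[1], dtype=np.int64)
    selected = np.zeros(X.shape[1], dtype=np.int64)
    if cost.is_divergence:
        P = _divergence_density_matrix(targets, cost)
        rng = np.random.default_rng(params.rng_seed)
        grow_tree_divergence(X, P, members, params.m, params.n_size,
                             params.max_depth, rng, feature, thr, left, right,
                             start, end, picked, selected, cost.kind)
    else:
        if not isinstance(targets, np.ndarray):
            targets = np.vstack([c.values for c in targets])
        Z = ssd_family_transform(cost, targets, grid=grid)
        max_depth = -1 if params.max_depth is None else params.max_depth
        _engine.grow_tree(X, Z, members, params.m, params.n_size, max_depth,
                          params.rng_seed, feature, thr, left, right,
                          start, end, picked, selected)
    return _build_node(0, feature, thr, left, right, start, end, members, targets)


def _build_node(i, feature, thr, left, right, start, end, members, targets):
    idx = members[start[i]:end[i]].copy()
    if feature[i] < 0:
        payload = None
        if isinstance(targets, np.ndarray):
            payload = targets[idx]
        return TreeNode(node_id=int(i), member_indices=idx, leaf_payload=payload)
    return TreeNode(
        node_id=int(i), split_feature=int(feature[i]), threshold=float(thr[i]),
        left=_build_node(left[i], feature, thr, left, right, start, end, members, targets),
        right=_build_node(right[i], feature, thr, left, right, start, end, members, targets),
        member_indices=idx)


def traverse(root: TreeNode, x: np.ndarray) -> TreeNode:
    """Follow ``x[feature] <= threshold -> left`` to the unique leaf."""
    x = np.asarray(x, dtype=float)
    node = root
    while not node.is_leaf:
        v = x[node.split_feature]
        if np.isnan(v):
            raise ValueError(f"missing feature {node.split_feature}")
        node = node.left if v <= node.threshold else node.right
    return node


def tree_to_records(root: TreeNode) -> list[dict]:
    """Flat JSON-friendly node records (for inspection/serialisation)."""
    records = []

    def visit(node: TreeNode) -> None:
        rec = {"node_id": node.node_id,
               "split_feature": node.split_feature,
               "threshold": node.threshold,
               "n_members": int(len(node.member_indices)),
               "left": node.left.node_id if node.left else None,
               "right": node.right.node_id if node.right else None}
        records.append(rec)
        if not node.is_leaf:
            visit(node.left)
            visit(node.right)

    visit(root)
    return records
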
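"""Brute-force split-search oracle used by the tree tests.

Independently of the package's prefix-sum kernels, this enumerates every
candidate threshold of every candidate feature, computes parent/child node
costs with the direct cost functions from ``funcforest.split_costs``, and
returns the reward-maximising split under the same tie rules (lowest
feature index, then lowest threshold; strictly positive reward required).
"""

import numpy as np
import pytest

from funcforest.curves import fit_bspline, matrix_to_curves
from funcforest.split_costs import (
    NodeCostSpec,
    basis_cost,
    divergence_cost,
    mahalanobis_cost,
    pca_components,
    pca_cost,
    region_ssd_cost,
    ssd_cost,
)


def _direct_cost(targets, spec: NodeCostSpec, context: dict):
    if spec.kind == "ssd":
        return ssd_cost(targets)
    if spec.kind == "region_ssd":
        return region_ssd_cost(np.atleast_2d(targets))
    if spec.kind == "pca":
        return pca_cost(np.atleast_2d(targets), spec.pc_count,
                        components=context["components"])
    if spec.kind == "mahalanobis":
        return mahalanobis_cost(np.atleast_2d(targets),
                                covariance=context["covariance"])
    if spec.kind == "basis":
        idx = context["row_index"]
        return basis_cost(context["coefficients"][idx], context["gram"])
    # divergence: targets is (means, sds) restricted to the node
    means, sds = targets
    dists = context["dist_factory"](means, sds)
    return divergence_cost(dists, spec)


def brute_force_best_split(X, targets, subset, spec: NodeCostSpec,
                           grid=None):
    """Exhaustive reward-maximising split, or None."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    context = {}
    if spec.kind == "pca":
        context["components"] = pca_components(np.atleast_2d(targets), spec.pc_count)
    elif spec.kind == "mahalanobis":
        context["covariance"] = np.cov(np.atleast_2d(targets), rowvar=False,
                                       bias=False)
    elif spec.kind == "basis":
        curves = matrix_to_curves(np.atleast_2d(targets), grid)
        n_basis = min(len(grid), 8)
        splines = [fit_bspline(c, order=min(4, n_basis), n_basis=n_basis)
                   for c in curves]
        context["coefficients"] = np.vstack([s.coefficients for s in splines])
        context["gram"] = splines[0].gram
        context["row_index"] = np.arange(n)
    elif spec.is_divergence:
        from funcforest.curves import DoseGrid, ResponseDistributionCurve

        means, sds = targets
        dose_grid = DoseGrid(np.arange(1, means.shape[1] + 1, dtype=float))

        def dist_factory(ms, ss):
            return [ResponseDistributionCurve(grid=dose_grid, means=m, sds=s)
                    for m, s in zip(np.atleast_2d(ms), np.atleast_2d(ss))]

        context["dist_factory"] = dist_factory

    def node_cost(idx):
        if spec.is_divergence:
            means, sds = targets
            return _direct_cost((means[idx], sds[idx]), spec, context)
        if spec.kind == "basis":
            ctx = dict(context, row_index=idx)
            return _direct_cost(None, spec, ctx)
        t = np.asarray(targets)
        return _direct_cost(t[idx], spec, context)

    parent = node_cost(np.arange(n))

    def reward_of(f, thr):
        xv = X[:, f]
        left = np.nonzero(xv <= thr)[0]
        right = np.nonzero(xv > thr)[0]
        if not left.size or not right.size:
            return None
        return parent - node_cost(left) - node_cost(right)

    best = None
    for f in sorted(int(j) for j in subset):
        xv = X[:, f]
        levels = np.unique(xv)
        for lo, hi in zip(levels[:-1], levels[1:]):
            thr = 0.5 * (lo + hi)
            left = np.nonzero(xv <= thr)[0]
            right = np.nonzero(xv > thr)[0]
            if not left.size or not right.size:
                continue
            reward = parent - node_cost(left) - node_cost(right)
            if reward <= 1e-10 * (abs(parent) + 1.0):
                continue
            if best is None or reward > best[2] * (1 + 1e-12):
                best = (f, thr, reward)
    if best is None:
        return None
    return best + (reward_of,)


def assert_split_matches_oracle(got, want, rel):
    """The found split must attain the oracle's maximal reward.

    On exact reward ties between distinct splits (equal to floating-point
    jitter), either choice is a valid maximiser, so the comparison is on the
    oracle-recomputed reward of the chosen split, not on split identity.
    """
    if want is None:
        assert got is None
        return
    assert got is not None
    f_w, thr_w, reward_w, reward_of = want
    tol = rel * (abs(reward_w) + 1e-9)
    if got[0] == f_w and got[1] == pytest.approx(thr_w):
        assert got[2] == pytest.approx(reward_w, rel=rel, abs=1e-9)
        return
    # different split chosen: it must be reward-tied with the oracle's best
    got_reward = reward_of(got[0], got[1])
    assert got_reward is not None
    assert abs(got_reward - reward_w) <= tol
    assert abs(got[2] - reward_w) <= tol
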
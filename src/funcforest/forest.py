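"""Random-forest estimators over scalar, multivariate and functional targets.

All estimators share one bootstrap-ensemble engine and differ in the node
cost used during growth and in what the leaves predict:

* :class:`ScalarRandomForest` -- univariate regression forest (scalar SSD
  cost, scalar leaf average); the conventional baseline.
* :class:`MultivariateRandomForest` -- Mahalanobis node cost on response
  vectors, curve-valued prediction.
* :class:`FunctionalRandomForest` -- functional node costs (region-wise SSD,
  PCA, basis, or KL/Hellinger divergence of per-dose response distributions)
  with whole curves stored in the leaves.  Prediction at each dose fits a
  Gaussian to the forest-weighted training responses and reports its mode
  (equal to the weighted mean), yielding a full predicted dose-response
  curve plus per-dose variances for uncertainty bands.
* :class:`FunctionalMetricForest` -- the hybrid: functional node costs but a
  scalar summary metric (e.g. AUC) averaged at the leaves.
* :class:`PerDoseRandomForest` -- a bank of independent scalar forests, one
  per dose; the standard way to emulate curve prediction with univariate
  forests.

Predictions are weight-based: a tree assigns a training sample the weight
(bootstrap multiplicity in the leaf containing the query) / (leaf size), the
forest averages weights over trees, and any leaf payload (scalar, metric, or
per-dose curve values) is predicted as the weighted sum over training
samples.  Variable importance is frequency-based: the fraction of node
subsets containing a feature in which the feature was chosen for the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _engine
from .curves import DoseGrid, ResponseCurve, matrix_to_curves, summary_metrics
from .split_costs import NodeCostSpec, default_omega
from .tree import _divergence_density_matrix, grow_tree_divergence, ssd_family_transform

__all__ = [
    "ScalarRandomForest",
    "MultivariateRandomForest",
    "FunctionalRandomForest",
    "FunctionalMetricForest",
    "PerDoseRandomForest",
    "ForestPrediction",
    "fit_forest",
    "forest_weights",
    "tree_weights",
    "predict_scalar",
    "predict_curve",
    "predict_summary_from_curve",
    "variable_importance",
]


@dataclass
class ForestPrediction:
    """Full prediction for one query point: normalised training-sample
    weights, the point prediction, and (curve modes) per-dose Gaussian
    parameters for uncertainty bands."""

    weights: np.ndarray
    scalar: float | None = None
    curve: np.ndarray | None = None
    dose_means: np.ndarray | None = None
    dose_variances: np.ndarray | None = None


def _check_matrix(X, name="X"):
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values (missing feature)")
    return X


class _BaseForest(BaseEstimator):
    """Shared bootstrap/growth/weights machinery."""

    def __init__(self, n_trees=150, max_features=10, min_node_size=10,
                 max_depth=None, bootstrap=True, random_state=None):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_node_size = min_node_size
        self.max_depth = max_depth
        self.bootstrap = bootstrap
        self.random_state = random_state

    # -- growth -----------------------------------------------------------

    def _setup(self, X):
        n, M = X.shape
        if n < 2:
            raise ValueError("need at least 2 training samples")
        rng = np.random.default_rng(self.random_state)
        T = int(self.n_trees)
        if self.bootstrap:
            boot = rng.integers(0, n, size=(T, n), dtype=np.int64)
        else:
            boot = np.tile(np.arange(n, dtype=np.int64), (T, 1))
        seeds = rng.integers(0, 2**31 - 1, size=T, dtype=np.int64)
        cap = 2 * n
        self.n_features_in_ = M
        self._m = min(int(self.max_features), M)
        self.bootstrap_indices_ = boot
        self._tree_seeds = seeds
        self._feat = np.full((T, cap), -1, dtype=np.int64)
        self._thr = np.full((T, cap), np.nan)
        self._left = np.full((T, cap), -1, dtype=np.int64)
        self._right = np.full((T, cap), -1, dtype=np.int64)
        self._start = np.zeros((T, cap), dtype=np.int64)
        self._end = np.zeros((T, cap), dtype=np.int64)
        self._members = np.zeros((T, n), dtype=np.int64)
        self._node_count = np.zeros(T, dtype=np.int64)
        self.vim_picked_ = np.zeros(M, dtype=np.int64)
        self.vim_selected_ = np.zeros(M, dtype=np.int64)
        return rng

    def _max_depth_flag(self):
        return -1 if self.max_depth is None else int(self.max_depth)

    def _grow_shared_z(self, X, Z):
        """All trees share one transformed target matrix -> one kernel call."""
        _engine.fit_forest(X, np.ascontiguousarray(Z), self.bootstrap_indices_,
                           self._tree_seeds, self._m, int(self.min_node_size),
                           self._max_depth_flag(), self._feat, self._thr,
                           self._left, self._right, self._start, self._end,
                           self._members, self._node_count,
                           self.vim_picked_, self.vim_selected_)

    def _grow_per_tree_z(self, X, z_for_tree):
        for t in range(int(self.n_trees)):
            self._members[t, :] = self.bootstrap_indices_[t]
            self._node_count[t] = _engine.grow_tree(
                X, np.ascontiguousarray(z_for_tree(t)), self._members[t],
                self._m, int(self.min_node_size), self._max_depth_flag(),
                self._tree_seeds[t], self._feat[t], self._thr[t],
                self._left[t], self._right[t], self._start[t], self._end[t],
                self.vim_picked_, self.vim_selected_)

    def _grow_divergence(self, X, P, kind):
        for t in range(int(self.n_trees)):
            self._members[t, :] = self.bootstrap_indices_[t]
            rng = np.random.default_rng(int(self._tree_seeds[t]))
            self._node_count[t] = grow_tree_divergence(
                X, P, self._members[t], self._m, int(self.min_node_size),
                self.max_depth, rng, self._feat[t], self._thr[t],
                self._left[t], self._right[t], self._start[t], self._end[t],
                self.vim_picked_, self.vim_selected_, kind)

    # -- weights ----------------------------------------------------------

    def forest_weights(self, X):
        """Prediction weights over training samples; each row sums to 1."""
        X = self._validate_query(X)
        return _engine.forest_weights(X, self._feat, self._thr, self._left,
                                      self._right, self._start, self._end,
                                      self._members, self._n_train)

    def tree_weights(self, tree_index, X):
        """Single-tree weights (bootstrap multiplicity in the reached leaf
        over leaf size)."""
        X = self._validate_query(X)
        s = slice(tree_index, tree_index + 1)
        return _engine.forest_weights(X, self._feat[s], self._thr[s],
                                      self._left[s], self._right[s],
                                      self._start[s], self._end[s],
                                      self._members[s], self._n_train)

    def _validate_query(self, X):
        if not hasattr(self, "n_features_in_"):
            raise RuntimeError("forest is not fitted")
        X = _check_matrix(np.atleast_2d(X))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("query feature count mismatch")
        return X

    # -- variable importance ---------------------------------------------

    def variable_importance(self):
        """Frequency VIM: (#times selected) / (#times in a candidate subset);
        features never picked score 0."""
        picked = self.vim_picked_
        with np.errstate(invalid="ignore", divide="ignore"):
            vim = np.where(picked > 0, self.vim_selected_ / np.maximum(picked, 1), 0.0)
        return vim

    @property
    def feature_importances_(self):
        return self.variable_importance()

    @property
    def never_picked_mask_(self):
        return self.vim_picked_ == 0


class _CurveLeafMixin:
    """Curve-valued prediction shared by the functional and multivariate
    forests: per dose, fit a Gaussian to the forest-weighted training
    responses and predict its mode (= weighted mean)."""

    def predict_distribution(self, X):
        W = self.forest_weights(X)
        mu = W @ self.y_train_
        var = W @ (self.y_train_ ** 2) - mu ** 2
        return mu, np.maximum(var, 0.0)

    def predict(self, X):
        """Predicted dose-response matrix, one row per query sample."""
        mu, _ = self.predict_distribution(X)
        return mu

    def predict_curves(self, X):
        if self.grid_ is None:
            raise ValueError("dose grid unknown; pass doses= at fit time")
        return matrix_to_curves(self.predict(X), self.grid_)

    def predict_full(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != 1:
            raise ValueError("predict_full takes a single query point")
        W = self.forest_weights(x)
        mu = W @ self.y_train_
        var = np.maximum(W @ (self.y_train_ ** 2) - mu ** 2, 0.0)
        return ForestPrediction(weights=W[0], curve=mu[0],
                                dose_means=mu[0], dose_variances=var[0])

    def predict_summary(self, X, metric="auc", reference=1.0):
        """Summary metric (auc/ic50/ec50/amax) of each predicted curve."""
        curves = self.predict_curves(X)
        out = np.empty(len(curves))
        for i, c in enumerate(curves):
            sm = summary_metrics(c, reference=reference, sigmoid_fallback=True)
            out[i] = getattr(sm, metric)
        return out


class ScalarRandomForest(RegressorMixin, _BaseForest):
    """Univariate regression forest with the scalar SSD node cost.

    Parameters follow the package defaults of 150 trees, m=10 candidate
    features per node and minimum node size 10.
    """

    def fit(self, X, y):
        X = _check_matrix(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ValueError("scalar forest expects a 1-d target vector")
        self._setup(X)
        self._n_train = X.shape[0]
        self.y_train_ = y.copy()
        self._grow_shared_z(X, y[:, None])
        return self

    def predict(self, X):
        return self.forest_weights(X) @ self.y_train_

    def predict_full(self, x):
        W = self.forest_weights(np.atleast_2d(np.asarray(x, dtype=float)))
        return ForestPrediction(weights=W[0], scalar=float(W[0] @ self.y_train_))

    def predict_curve(self, X):  # pragma: no cover - guard
        raise AttributeError("scalar forest predicts scalars; use predict")


class FunctionalRandomForest(_CurveLeafMixin, _BaseForest):
    """Functional random forest: functional node cost, curve-storing leaves.

    ``cost`` selects the node deviance: ``'region_ssd'`` (default, per-dose
    SSD summed over regions), ``'pca'``, ``'basis'``, or the
    distribution-based ``'kl'`` / ``'hellinger'`` (which require per-dose
    replicate SDs via ``y_sd`` at fit time).
    """

    def __init__(self, n_trees=150, max_features=10, min_node_size=10,
                 max_depth=None, bootstrap=True, random_state=None,
                 cost="region_ssd", pc_count=3, omega_points=256,
                 epsilon=1e-12):
        super().__init__(n_trees=n_trees, max_features=max_features,
                         min_node_size=min_node_size, max_depth=max_depth,
                         bootstrap=bootstrap, random_state=random_state)
        self.cost = cost
        self.pc_count = pc_count
        self.omega_points = omega_points
        self.epsilon = epsilon

    def _cost_spec(self):
        return NodeCostSpec(kind=self.cost, pc_count=self.pc_count,
                            omega_points=self.omega_points, epsilon=self.epsilon)

    def _fit_curves(self, X, Y, doses, y_sd):
        X = _check_matrix(X)
        Y = _check_matrix(Y, "Y")
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y sample counts differ")
        if Y.shape[1] < 1:
            raise ValueError("curve forest expects a 2-d (samples x doses) "
                             "target matrix; use ScalarRandomForest for scalars")
        self._setup(X)
        self._n_train = X.shape[0]
        self.y_train_ = Y.copy()
        self.grid_ = DoseGrid(np.asarray(doses, dtype=float)) if doses is not None else None
        spec = self._cost_spec()
        if spec.is_divergence:
            if y_sd is None:
                raise ValueError(f"cost {spec.kind!r} needs per-dose replicate "
                                 "SDs (y_sd)")
            sd = _check_matrix(y_sd, "y_sd")
            if sd.shape != Y.shape:
                raise ValueError("y_sd shape must match Y")
            self.omega_ = default_omega(Y, sd, spec.omega_points)
            spec.omega = self.omega_
            P = _divergence_density_matrix((Y, sd), spec)
            self._grow_divergence(X, P, spec.kind)
        else:
            grid = self.grid_
            if grid is None and spec.kind == "basis":
                grid = DoseGrid(np.arange(1, Y.shape[1] + 1, dtype=float))
            self._grow_shared_z(X, ssd_family_transform(spec, Y, grid=grid))
        return self

    def fit(self, X, Y, doses=None, y_sd=None):
        return self._fit_curves(X, Y, doses, y_sd)


class MultivariateRandomForest(_CurveLeafMixin, _BaseForest):
    """Multivariate forest: Mahalanobis node cost on response vectors.

    The covariance is estimated once per tree from that tree's bootstrap
    responses (ridge-regularised); ``covariance='identity'`` reduces the
    cost to the region-wise SSD and is mainly useful for equivalence checks.
    """

    def __init__(self, n_trees=150, max_features=10, min_node_size=10,
                 max_depth=None, bootstrap=True, random_state=None,
                 covariance="per_tree"):
        super().__init__(n_trees=n_trees, max_features=max_features,
                         min_node_size=min_node_size, max_depth=max_depth,
                         bootstrap=bootstrap, random_state=random_state)
        self.covariance = covariance

    def fit(self, X, Y, doses=None):
        X = _check_matrix(X)
        Y = _check_matrix(Y, "Y")
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y sample counts differ")
        self._setup(X)
        self._n_train = X.shape[0]
        self.y_train_ = Y.copy()
        self.grid_ = DoseGrid(np.asarray(doses, dtype=float)) if doses is not None else None
        if self.covariance == "identity":
            self._grow_shared_z(X, Y)
        elif self.covariance == "per_tree":
            spec = NodeCostSpec(kind="mahalanobis")

            def z_for_tree(t):
                yb = Y[self.bootstrap_indices_[t]]
                cov = np.cov(yb, rowvar=False, bias=False)
                return ssd_family_transform(spec, Y, covariance=cov)

            self._grow_per_tree_z(X, z_for_tree)
        else:
            raise ValueError("covariance must be 'per_tree' or 'identity'")
        return self


class FunctionalMetricForest(RegressorMixin, _BaseForest):
    """FRFL: functional node cost, conventional scalar-metric leaves.

    Trees are grown on whole curves (so splits see curve shape), but each
    leaf stores only a summary metric of its member curves and prediction is
    the forest-weighted average of that metric.
    """

    def __init__(self, n_trees=150, max_features=10, min_node_size=10,
                 max_depth=None, bootstrap=True, random_state=None,
                 cost="region_ssd", metric="auc", pc_count=3,
                 omega_points=256, epsilon=1e-12):
        super().__init__(n_trees=n_trees, max_features=max_features,
                         min_node_size=min_node_size, max_depth=max_depth,
                         bootstrap=bootstrap, random_state=random_state)
        self.cost = cost
        self.metric = metric
        self.pc_count = pc_count
        self.omega_points = omega_points
        self.epsilon = epsilon

    def fit(self, X, Y, doses=None, y_sd=None, leaf_values=None):
        inner = FunctionalRandomForest(
            n_trees=self.n_trees, max_features=self.max_features,
            min_node_size=self.min_node_size, max_depth=self.max_depth,
            bootstrap=self.bootstrap, random_state=self.random_state,
            cost=self.cost, pc_count=self.pc_count,
            omega_points=self.omega_points, epsilon=self.epsilon)
        inner.fit(X, Y, doses=doses, y_sd=y_sd)
        # adopt the grown ensemble, then swap leaf payloads for the metric
        self.__dict__.update({k: v for k, v in inner.__dict__.items()
                              if k.endswith("_") or k.startswith("_")})
        if leaf_values is not None:
            vals = np.asarray(leaf_values, dtype=float)
            if vals.shape != (np.asarray(X).shape[0],):
                raise ValueError("leaf_values must be one scalar per sample")
        else:
            vals = self._metric_from_curves(np.asarray(Y, dtype=float))
        self.leaf_metric_ = vals
        return self

    def _metric_from_curves(self, Y):
        if self.grid_ is None:
            raise ValueError("metric extraction needs doses= at fit time")
        vals = np.empty(Y.shape[0])
        for i, c in enumerate(matrix_to_curves(np.asarray(Y, dtype=float), self.grid_)):
            if callable(self.metric):
                vals[i] = self.metric(c)
            else:
                vals[i] = getattr(summary_metrics(c, sigmoid_fallback=True), self.metric)
        return vals

    def predict(self, X):
        return self.forest_weights(X) @ self.leaf_metric_


class PerDoseRandomForest(_BaseForest):
    """Bank of independent scalar forests, one per dose column.

    This is the conventional way to obtain a curve-shaped prediction from
    univariate forests: dose ``j``'s responses are modelled by their own
    :class:`ScalarRandomForest`, ignoring the continuity of the curve.
    """

    def fit(self, X, Y, doses=None):
        X = _check_matrix(X)
        Y = _check_matrix(Y, "Y")
        if Y.shape[0] != X.shape[0]:
            raise ValueError("X and Y sample counts differ")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.grid_ = DoseGrid(np.asarray(doses, dtype=float)) if doses is not None else None
        self.forests_ = []
        for j in range(Y.shape[1]):
            f = ScalarRandomForest(
                n_trees=self.n_trees, max_features=self.max_features,
                min_node_size=self.min_node_size, max_depth=self.max_depth,
                bootstrap=self.bootstrap,
                random_state=int(rng.integers(0, 2**31 - 1)))
            f.fit(X, Y[:, j])
            self.forests_.append(f)
        return self

    def predict(self, X):
        return np.column_stack([f.predict(X) for f in self.forests_])


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

_MODES = {"rf": ScalarRandomForest, "mrf": MultivariateRandomForest,
          "frf": FunctionalRandomForest, "frfl": FunctionalMetricForest,
          "per_dose_rf": PerDoseRandomForest}


def fit_forest(features, targets, config: dict):
    """Fit a forest from a config dict with a ``mode`` key (rf/mrf/frf/frfl/
    per_dose_rf); remaining keys are estimator parameters, plus optional
    ``doses`` and ``y_sd`` fit arguments."""
    config = dict(config)
    mode = config.pop("mode", "frf")
    doses = config.pop("doses", None)
    y_sd = config.pop("y_sd", None)
    try:
        cls = _MODES[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}") from None
    est = cls(**config)
    if mode == "rf":
        return est.fit(features, targets)
    if mode in ("frf", "frfl"):
        return est.fit(features, targets, doses=doses, y_sd=y_sd)
    return est.fit(features, targets, doses=doses)


def forest_weights(model, x):
    return model.forest_weights(np.atleast_2d(np.asarray(x, dtype=float)))[0]


def tree_weights(model, tree_index, x):
    return model.tree_weights(tree_index, np.atleast_2d(np.asarray(x, dtype=float)))[0]


def predict_scalar(model, x):
    if isinstance(model, (FunctionalRandomForest, MultivariateRandomForest)):
        raise TypeError("curve-mode model: use predict_curve")
    return float(model.predict(np.atleast_2d(np.asarray(x, dtype=float)))[0])


def predict_curve(model, x) -> ResponseCurve:
    if not isinstance(model, (FunctionalRandomForest, MultivariateRandomForest)):
        raise TypeError("scalar-mode model: use predict_scalar")
    return model.predict_curves(np.atleast_2d(np.asarray(x, dtype=float)))[0]


def predict_summary_from_curve(model, x, metric="auc"):
    return float(model.predict_summary(np.atleast_2d(np.asarray(x, dtype=float)),
                                       metric=metric)[0])


def variable_importance(model):
    return model.variable_importance()
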
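"""Dose-response curve containers, spline/polynomial fitting and summary metrics.

A dose-response curve is a vector of responses (viability/activity, typically
in ``[0, 1]``) measured on an ordered grid of drug concentrations.  All fitting
and integration in this package happens on the ``log10(dose)`` axis, which is
the axis on which pharmacological dose series are (approximately) equispaced.

Summary metrics follow the conventions of large pharmacogenomic screens:

* ``AUC`` -- normalised area between a reference (untreated) level and the
  curve, clamped at the reference so that activation above baseline does not
  produce negative area.
* ``IC50``/``IC_p`` -- smallest in-span dose at which the fitted curve has
  declined ``p`` percent of the way from its fitted maximum to its fitted
  minimum.  Metrics whose crossing does not occur inside the measured dose
  span are reported as :data:`NOT_REACHED`; no extrapolation is performed.
* ``EC50``/``Amax`` -- inflection dose and maximal-effect asymptote of a
  four-parameter sigmoid fit ``y(d) = A0 + (Amax - A0) / (1 + (IC50/d)^theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline
from scipy.optimize import brentq, least_squares

__all__ = [
    "NOT_REACHED",
    "is_reached",
    "DoseGrid",
    "ResponseCurve",
    "ResponseDistributionCurve",
    "SplineRepresentation",
    "SummaryMetrics",
    "four_param_sigmoid",
    "fit_sigmoid",
    "fit_bspline",
    "evaluate_spline",
    "curve_auc",
    "ic_from_polynomial",
    "summary_metrics",
    "rank_curves_by_slope",
    "rank_curves_by_dominance",
    "curves_to_matrix",
    "matrix_to_curves",
]

#: Sentinel for a metric whose defining crossing/fit does not exist within the
#: measured dose span.  A NaN float so it propagates cleanly through arrays
#: and serialises to an empty CSV cell.
NOT_REACHED: float = float("nan")


def is_reached(value: float) -> bool:
    """True when ``value`` is an actual dose/metric rather than NOT_REACHED."""
    return value is not None and not math.isnan(value)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseGrid:
    """Ordered grid of positive drug concentrations (uM).

    ``scale`` records the axis convention used for plotting/integration;
    the package default is ``"log10"``.
    """

    doses: np.ndarray
    scale: str = "log10"

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "doses", doses)
        if doses.ndim != 1 or doses.size < 2:
            raise ValueError("dose grid needs at least 2 doses")
        if not np.all(np.isfinite(doses)) or np.any(doses <= 0):
            raise ValueError("doses must be finite and > 0")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.scale not in ("log10", "linear"):
            raise ValueError("scale must be 'log10' or 'linear'")

    def __len__(self) -> int:
        return int(self.doses.size)

    @property
    def log10(self) -> np.ndarray:
        return np.log10(self.doses)

    @property
    def axis(self) -> np.ndarray:
        """The integration/fitting axis implied by ``scale``."""
        return self.log10 if self.scale == "log10" else self.doses


@dataclass(frozen=True)
class ResponseCurve:
    """One sample's responses over a dose grid."""

    grid: DoseGrid
    values: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != len(self.grid):
            raise ValueError("values must be one per dose")
        if not np.all(np.isfinite(values)):
            raise ValueError("curve values must be finite")


@dataclass(frozen=True)
class ResponseDistributionCurve:
    """Per-dose Gaussian summaries (replicate mean and SD) for one sample."""

    grid: DoseGrid
    means: np.ndarray
    sds: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        if means.shape != sds.shape or means.size != len(self.grid):
            raise ValueError("means/sds must be one per dose")
        if not (np.all(np.isfinite(means)) and np.all(np.isfinite(sds))):
            raise ValueError("means/sds must be finite")
        if np.any(sds < 0):
            raise ValueError("sds must be nonnegative")


@dataclass(frozen=True)
class SplineRepresentation:
    """A fitted B-spline: knots/coefficients on the log10-dose axis plus the
    Gram matrix of basis-function inner products (used by the basis node cost).
    """

    knots: np.ndarray
    coefficients: np.ndarray
    order: int  # spline order k (degree + 1)
    gram: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be nondecreasing")
        if self.coefficients.size != self.knots.size - self.order:
            raise ValueError("coefficient count inconsistent with knots/order")

    @property
    def degree(self) -> int:
        return self.order - 1

    def as_bspline(self, extrapolate: bool = False) -> BSpline:
        return BSpline(self.knots, self.coefficients, self.degree,
                       extrapolate=extrapolate)

    @property
    def span(self) -> tuple[float, float]:
        k = self.degree
        return float(self.knots[k]), float(self.knots[-k - 1])


@dataclass(frozen=True)
class SummaryMetrics:
    """Scalar drug-sensitivity summaries extracted from one curve."""

    auc: float
    ic50: float
    ec50: float
    amax: float
    ic_table: Mapping[float, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sigmoid model
# ---------------------------------------------------------------------------


def four_param_sigmoid(d, a0: float, amax: float, ic50: float, theta: float):
    """Four-parameter sigmoidal dose-response model.

    ``y(d) = A0 + (Amax - A0) / (1 + (IC50 / d) ** theta)`` with ``A0`` the
    zero-dose level, ``Amax`` the infinite-dose asymptote, ``IC50`` the
    inflection dose (where ``y = (A0 + Amax)/2``) and ``theta`` the slope.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0) or ic50 <= 0 or theta <= 0:
        raise ValueError("doses, IC50 and theta must be positive")
    return a0 + (amax - a0) / (1.0 + (ic50 / d) ** theta)


def fit_sigmoid(doses: np.ndarray, values: np.ndarray) -> tuple[float, float, float, float]:
    """Bounded least-squares fit of :func:`four_param_sigmoid`.

    Multistart over three slope values; asymptotes are bounded within 1.5x the
    data range around the data, theta in (0, 10], IC50 within a decade of the
    dose span.  Raises ``RuntimeError`` when no start converges (e.g. a flat
    curve, whose sigmoid parameters are unidentifiable).
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(values, dtype=float)
    vmin, vmax = float(v.min()), float(v.max())
    rng = vmax - vmin
    if rng <= 1e-12 * max(1.0, abs(vmax)):
        raise RuntimeError("fit failed: flat curve")
    lo_a, hi_a = vmin - 1.5 * rng, vmax + 1.5 * rng
    bounds = ([lo_a, lo_a, d[0] / 10.0, 1e-3],
              [hi_a, hi_a, d[-1] * 10.0, 10.0])
    ld = np.log(d)

    def resid(p):
        a0, amax, lic50, theta = p[0], p[1], p[2], p[3]
        return a0 + (amax - a0) / (1.0 + np.exp(-theta * (ld - np.log(lic50)))) - v

    ic0 = math.sqrt(d[0] * d[-1])
    best = None
    for theta0 in (0.5, 2.0, 8.0):
        x0 = np.array([v[0], v[-1], ic0, theta0])
        try:
            sol = least_squares(resid, x0, bounds=bounds, method="trf")
        except Exception:  # pragma: no cover - scipy failure paths
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("fit failed")
    a0, amax, ic50, theta = map(float, best.x)
    return a0, amax, ic50, theta


# ---------------------------------------------------------------------------
# B-splines
# ---------------------------------------------------------------------------


def _knot_vector(x: np.ndarray, order: int, n_basis: int) -> np.ndarray:
    """Clamped knot vector on span(x) whose interior knots follow the data."""
    n_interior = n_basis - order
    if n_interior > 0:
        pos = np.linspace(0, x.size - 1, n_interior + 2)[1:-1]
        interior = np.interp(pos, np.arange(x.size), x)
    else:
        interior = np.empty(0)
    return np.concatenate([np.full(order, x[0]), interior, np.full(order, x[-1])])


def _gram_matrix(knots: np.ndarray, degree: int) -> np.ndarray:
    """Gram matrix of B-spline basis inner products by Gauss-Legendre
    quadrature per knot interval (exact for the polynomial integrand)."""
    n_basis = knots.size - degree - 1
    nodes, weights = np.polynomial.legendre.leggauss(degree + 1)
    gram = np.zeros((n_basis, n_basis))
    breaks = np.unique(knots)
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        xs = mid + half * nodes
        design = BSpline.design_matrix(xs, knots, degree).toarray()
        gram += half * design.T @ (weights[:, None] * design)
    return 0.5 * (gram + gram.T)


def fit_bspline(curve: ResponseCurve, order: int = 4,
                n_basis: int | None = None) -> SplineRepresentation:
    """Least-squares B-spline fit of a curve on the log10-dose axis.

    With ``n_basis`` equal to the number of dose points the fit interpolates
    the observations; with fewer basis functions it smooths them.
    """
    x = curve.grid.log10
    y = curve.values
    n = x.size
    if n_basis is None:
        n_basis = min(n, 8)
    if order < 2:
        raise ValueError("order must be >= 2")
    if n < order:
        raise ValueError("insufficient points")
    if not (order <= n_basis <= n):
        raise ValueError("need order <= n_basis <= number of dose points")
    knots = _knot_vector(x, order, n_basis)
    degree = order - 1
    design = BSpline.design_matrix(x, knots, degree).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return SplineRepresentation(knots=knots, coefficients=coef, order=order,
                                gram=_gram_matrix(knots, degree))


def evaluate_spline(spline: SplineRepresentation, doses: np.ndarray,
                    extrapolate: bool = False) -> np.ndarray:
    """Evaluate a fitted spline at doses (uM); linear in the coefficients."""
    x = np.log10(np.asarray(doses, dtype=float))
    lo, hi = spline.span
    tol = 1e-9 * max(1.0, abs(hi - lo))
    if not extrapolate and (np.any(x < lo - tol) or np.any(x > hi + tol)):
        raise ValueError("dose outside the fitted span (set extrapolate=True)")
    return spline.as_bspline(extrapolate=True)(np.clip(x, lo, hi) if not extrapolate else x)


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------


def curve_auc(curve: ResponseCurve, reference: float | np.ndarray = 1.0,
              clamp_above_reference: bool = True) -> float:
    """Normalised trapezoidal area between a reference level and the curve.

    Integration is over the grid's axis (log10-dose by default) and divided by
    the axis width, so the result is in response units and comparable across
    dose grids.  With clamping, curve values above the reference contribute
    zero (activation is not counted as negative sensitivity).
    """
    ref = np.broadcast_to(np.asarray(reference, dtype=float), curve.values.shape)
    if not np.all(np.isfinite(ref)):
        raise ValueError("reference must be finite")
    diff = ref - curve.values
    if clamp_above_reference:
        diff = np.maximum(diff, 0.0)
    x = curve.grid.axis
    return float(np.trapezoid(diff, x) / (x[-1] - x[0]))


def _first_crossing(poly_vals: np.ndarray, xs: np.ndarray, level: float) -> float:
    """Smallest x where the dense-evaluated curve crosses ``level``."""
    sign = poly_vals - level
    hits = np.nonzero(np.abs(sign) <= 1e-12)[0]
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    cands = []
    if hits.size:
        cands.append(xs[hits[0]])
    if crossings.size:
        i = crossings[0]
        # linear refinement inside the bracketing cell
        x0, x1 = xs[i], xs[i + 1]
        f0, f1 = sign[i], sign[i + 1]
        cands.append(x0 - f0 * (x1 - x0) / (f1 - f0))
    return min(cands) if cands else NOT_REACHED


def ic_from_polynomial(curve: ResponseCurve,
                       percentiles: Sequence[float] = (25.0, 50.0, 75.0),
                       n_grid: int = 1024) -> dict[float, float]:
    """IC_p doses from a cubic polynomial fit in log10-dose.

    The fitted curve's range over the dose span defines the percentile levels:
    ``level_p = max_fit - (p/100) * (max_fit - min_fit)`` (p percent of decline
    from the fitted maximum, the pharmacological orientation -- a decreasing
    curve yields IC25 < IC50 < IC75 in dose).  The smallest in-span dose where
    the fitted curve crosses the level is returned; :data:`NOT_REACHED` when no
    in-span crossing exists or the fitted curve is flat.
    """
    if len(curve.grid) < 4:
        raise ValueError("cubic IC extraction needs at least 4 dose points")
    for p in percentiles:
        if not (0.0 < p < 100.0):
            raise ValueError("percentiles must lie in (0, 100)")
    x = curve.grid.log10
    poly = np.polynomial.Polynomial.fit(x, curve.values, deg=3)
    xs = np.linspace(x[0], x[-1], n_grid)
    vals = poly(xs)
    vmin, vmax = float(vals.min()), float(vals.max())
    out: dict[float, float] = {}
    if vmax - vmin <= 1e-12 * max(1.0, abs(vmax)):
        return {float(p): NOT_REACHED for p in percentiles}
    for p in percentiles:
        level = vmax - (p / 100.0) * (vmax - vmin)
        xc = _first_crossing(vals, xs, level)
        out[float(p)] = 10.0 ** xc if is_reached(xc) else NOT_REACHED
    return out


def _spline_level_crossing(curve: ResponseCurve, level: float) -> float:
    """Smallest in-span dose where the interpolating spline crosses ``level``."""
    x = curve.grid.log10
    k = min(3, x.size - 1)
    spl = make_interp_spline(x, curve.values, k=k)
    xs = np.linspace(x[0], x[-1], 1024)
    vals = spl(xs)
    sign = vals - level
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if np.abs(sign[0]) <= 1e-12:
        return float(10.0 ** xs[0])
    if idx.size == 0:
        hits = np.nonzero(np.abs(sign) <= 1e-12)[0]
        return float(10.0 ** xs[hits[0]]) if hits.size else NOT_REACHED
    i = idx[0]
    root = brentq(lambda t: float(spl(t)) - level, xs[i], xs[i + 1])
    return float(10.0 ** root)


def _sigmoid_level_crossing(a0, amax, ic50, theta, doses, level) -> float:
    """Smallest in-span dose where the fitted sigmoid crosses ``level``."""
    lo, hi = float(doses[0]), float(doses[-1])

    def f(logd):
        return float(four_param_sigmoid(10.0 ** logd, a0, amax, ic50, theta)) - level

    xs = np.linspace(np.log10(lo), np.log10(hi), 512)
    vals = np.array([f(x) for x in xs])
    if abs(vals[0]) <= 1e-12:
        return lo
    idx = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
    if idx.size == 0:
        return NOT_REACHED
    i = idx[0]
    return float(10.0 ** brentq(f, xs[i], xs[i + 1]))


def summary_metrics(curve: ResponseCurve, reference: float = 1.0,
                    sigmoid_fallback: bool = True,
                    ic_percentiles: Sequence[float] = ()) -> SummaryMetrics:
    """AUC, IC50, EC50 and Amax for one dose-response curve.

    AUC is the clamped area against ``reference``; IC50 is the smallest
    in-span dose where the fitted curve crosses ``0.5 * reference``; EC50
    (inflection dose) and Amax (asymptote) come from the four-parameter
    sigmoid fit, which also supplies the IC50 crossing when it converges.
    When the sigmoid fit fails, ``sigmoid_fallback=True`` falls back to an
    interpolating-spline crossing for IC50 and reports EC50/Amax as
    NOT_REACHED; with the fallback off the failure is raised.
    """
    auc = curve_auc(curve, reference=reference, clamp_above_reference=True)
    level = 0.5 * reference
    try:
        a0, amax, ec50, theta = fit_sigmoid(curve.grid.doses, curve.values)
        ic50 = _sigmoid_level_crossing(a0, amax, ec50, theta,
                                       curve.grid.doses, level)
    except RuntimeError:
        if not sigmoid_fallback:
            raise
        ec50, amax = NOT_REACHED, NOT_REACHED
        ic50 = _spline_level_crossing(curve, level)
    table = ic_from_polynomial(curve, ic_percentiles) if ic_percentiles else {}
    return SummaryMetrics(auc=auc, ic50=ic50, ec50=ec50, amax=amax, ic_table=table)


# ---------------------------------------------------------------------------
# curve ranking (function-to-function feature extraction)
# ---------------------------------------------------------------------------


def _check_shared_grid(curves: Sequence[ResponseCurve]) -> np.ndarray:
    if not curves:
        raise ValueError("need at least one curve")
    g0 = curves[0].grid.doses
    for c in curves[1:]:
        if len(c.grid) != g0.size or not np.allclose(c.grid.doses, g0):
            raise ValueError("curves must share one dose grid")
    return np.vstack([c.values for c in curves])


def rank_curves_by_slope(curves: Sequence[ResponseCurve]) -> np.ndarray:
    """Rank curves by mean rate of change: rank 1 is the steepest decline.

    The slope is the least-squares slope of values against log10-dose; ties
    are broken stably by input order.
    """
    mat = _check_shared_grid(curves)
    x = curves[0].grid.log10
    xc = x - x.mean()
    slopes = (mat - mat.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    order = np.argsort(slopes, kind="stable")
    ranks = np.empty(len(curves), dtype=int)
    ranks[order] = np.arange(1, len(curves) + 1)
    return ranks


def rank_curves_by_dominance(curves: Sequence[ResponseCurve]) -> np.ndarray:
    """Rank curves by pairwise position: rank 1 dominates the rest.

    Curve A beats curve B when strictly more than half of A's dose points lie
    above B's.  A curve's rank is 1 + the number of curves that beat it; ties
    are resolved by higher mean value, then input order.
    """
    mat = _check_shared_grid(curves)
    n, q = mat.shape
    beats = np.zeros((n, n), dtype=bool)
    for a in range(n):
        higher = (mat[a][None, :] > mat).sum(axis=1)
        beats[a] = higher > q / 2.0
        beats[a, a] = False
    beaten_by = beats.sum(axis=0)
    means = mat.mean(axis=1)
    order = np.lexsort((np.arange(n), -means, beaten_by))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


# ---------------------------------------------------------------------------
# matrix conversion helpers
# ---------------------------------------------------------------------------


def curves_to_matrix(curves: Sequence[ResponseCurve]) -> tuple[np.ndarray, DoseGrid]:
    return _check_shared_grid(curves), curves[0].grid


def matrix_to_curves(matrix: np.ndarray, grid: DoseGrid,
                     sample_ids: Sequence[str] | None = None) -> list[ResponseCurve]:
    matrix = np.asarray(matrix, dtype=float)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(matrix.shape[0])]
    return [ResponseCurve(grid=grid, values=row, sample_id=str(sid))
            for row, sid in zip(matrix, ids)]
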
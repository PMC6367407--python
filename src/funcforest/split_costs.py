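"""Node-cost (deviance) functions selectable at tree-growth time.

Six costs are available, all nonnegative and zero on a node of identical
responses:

* ``ssd`` -- scalar sum of squared deviances around the node mean.
* ``region_ssd`` -- the functional point-based cost: per-dose-region SSD
  summed over regions (with the default one-region-per-dose scheme this is
  the SSD summed over all dose columns).
* ``mahalanobis`` -- SSD of Mahalanobis distances of response vectors to the
  node mean (the multivariate-forest cost).
* ``pca`` -- SSD of responses projected onto the leading principal components
  of the root training response matrix.
* ``basis`` -- SSD of basis (B-spline) coefficients under the Gram metric of
  basis inner products.
* ``kl`` / ``hellinger`` -- the distribution-based functional costs: each
  sample's per-dose Gaussian is compared by f-divergence to the node's
  equal-weight mixture distribution, summed over samples and dose regions.

All divergences operate on densities discretised on a fixed support grid
(Omega) so that parent and child costs are measured on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curves import ResponseCurve, ResponseDistributionCurve

__all__ = [
    "NodeCostSpec",
    "DiscretizedDensity",
    "ssd_cost",
    "region_ssd_cost",
    "mahalanobis_cost",
    "pca_cost",
    "basis_cost",
    "discretize_gaussian",
    "density_tensor",
    "default_omega",
    "mixture_node_distribution",
    "f_divergence",
    "divergence_cost",
    "COST_KINDS",
]

COST_KINDS = ("ssd", "region_ssd", "pca", "basis", "mahalanobis", "kl", "hellinger")

#: default probability floor applied before logs/ratios
PROB_FLOOR = 1e-12


@dataclass
class NodeCostSpec:
    """Configuration of a node cost.

    ``kind`` selects the cost; ``divergence_kind`` applies when
    ``kind='divergence'`` (or equivalently kind 'kl'/'hellinger');
    ``region_count`` is the number of dose regions (default: one per dose);
    ``omega`` the divergence support grid; ``pc_count`` the number of
    principal components; ``epsilon`` the probability floor.
    """

    kind: str = "region_ssd"
    divergence_kind: str = "kl"
    region_count: int | None = None
    omega: np.ndarray | None = None
    omega_points: int = 256
    pc_count: int = 3
    epsilon: float = PROB_FLOOR

    def __post_init__(self) -> None:
        kind = self.kind
        if kind == "divergence":
            kind = self.divergence_kind
            self.kind = kind
        elif kind in ("kl", "hellinger"):
            self.divergence_kind = kind
        if kind not in COST_KINDS:
            raise ValueError(f"unknown cost kind {kind!r}")
        if self.divergence_kind not in ("kl", "hellinger"):
            raise ValueError("divergence_kind must be 'kl' or 'hellinger'")
        if self.region_count is not None and self.region_count < 1:
            raise ValueError("region_count must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.omega is not None:
            om = np.asarray(self.omega, dtype=float)
            if om.size < 32 or np.any(np.diff(om) <= 0):
                raise ValueError("omega must be strictly increasing with >= 32 points")
            self.omega = om

    @property
    def is_divergence(self) -> bool:
        return self.kind in ("kl", "hellinger")


@dataclass(frozen=True)
class DiscretizedDensity:
    """A probability mass function on a fixed support grid."""

    support: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "masses", masses)
        if support.shape != masses.shape:
            raise ValueError("support/masses shape mismatch")
        if np.any(masses < 0):
            raise ValueError("masses must be nonnegative")
        if abs(masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")


# ---------------------------------------------------------------------------
# SSD-family costs
# ---------------------------------------------------------------------------


def ssd_cost(values: Sequence[float]) -> float:
    """Sum of squared deviances of scalar responses around the node mean."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty node")
    return float(np.sum((v - v.mean()) ** 2))


def _as_matrix(curves) -> np.ndarray:
    if isinstance(curves, np.ndarray):
        return np.atleast_2d(np.asarray(curves, dtype=float))
    grid = curves[0].grid.doses
    for c in curves[1:]:
        if c.grid.doses.size != grid.size or not np.allclose(c.grid.doses, grid):
            raise ValueError("curves must share one dose grid")
    return np.vstack([c.values for c in curves])


def region_ssd_cost(curves, regions: Sequence[Sequence[int]] | None = None) -> float:
    """Region-wise SSD summed over dose regions.

    ``regions`` is a disjoint cover of the dose indices; by default every dose
    is its own region, in which case the cost is the per-dose SSD summed over
    all doses.
    """
    mat = _as_matrix(curves)
    n, q = mat.shape
    if regions is None:
        regions = [[j] for j in range(q)]
    seen = np.zeros(q, dtype=bool)
    total = 0.0
    for region in regions:
        idx = np.asarray(region, dtype=int)
        if np.any(seen[idx]):
            raise ValueError("regions must be disjoint")
        seen[idx] = True
        sub = mat[:, idx]
        total += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    if not seen.all():
        raise ValueError("regions must cover all dose indices")
    return total


def mahalanobis_cost(response_matrix: np.ndarray,
                     covariance: np.ndarray | None = None,
                     ridge: float | None = None) -> float:
    """SSD of Mahalanobis distances to the node mean vector.

    ``covariance`` defaults to the sample covariance of the matrix itself;
    in forest growth it is estimated once per tree from the bootstrap
    responses.  ``ridge`` adds ``ridge * I`` before inversion (default
    ``1e-6 * trace/m``); pass ``ridge=0`` to forbid regularisation, in which
    case a singular covariance raises.
    """
    y = np.atleast_2d(np.asarray(response_matrix, dtype=float))
    n, m = y.shape
    if covariance is None:
        covariance = np.cov(y, rowvar=False, bias=False) if n > 1 else np.eye(m)
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    if cov.shape != (m, m):
        raise ValueError("covariance shape mismatch")
    if ridge is None:
        ridge = 1e-6 * np.trace(cov) / m
    cov = cov + ridge * np.eye(m)
    centered = y - y.mean(axis=0)
    try:
        sol = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance; provide a positive ridge") from exc
    return float(np.sum(centered.T * sol))


def pca_components(response_matrix: np.ndarray, pc_count: int) -> np.ndarray:
    """Leading principal axes (columns) of a response matrix."""
    y = np.atleast_2d(np.asarray(response_matrix, dtype=float))
    if pc_count < 1:
        raise ValueError("pc_count must be >= 1")
    if pc_count > y.shape[1]:
        raise ValueError("pc_count exceeds number of response coordinates")
    centered = y - y.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[:pc_count].T


def pca_cost(response_matrix: np.ndarray, pc_count: int,
             components: np.ndarray | None = None) -> float:
    """SSD of responses projected onto leading principal components.

    ``components`` are the root-level principal axes (fixed per forest); when
    omitted they are computed from the matrix itself.
    """
    y = np.atleast_2d(np.asarray(response_matrix, dtype=float))
    if components is None:
        components = pca_components(y, pc_count)
    z = y @ components[:, :pc_count]
    return float(np.sum((z - z.mean(axis=0)) ** 2))


def basis_cost(coefficient_matrix: np.ndarray, gram: np.ndarray) -> float:
    """SSD of basis coefficients under the Gram metric:
    ``sum_i (c_i - mu)^T Phi (c_i - mu)``."""
    c = np.atleast_2d(np.asarray(coefficient_matrix, dtype=float))
    gram = np.asarray(gram, dtype=float)
    if gram.shape != (c.shape[1], c.shape[1]):
        raise ValueError("gram dimension mismatch")
    if not np.allclose(gram, gram.T, atol=1e-10):
        raise ValueError("gram must be symmetric")
    centered = c - c.mean(axis=0)
    return float(np.sum(centered @ gram * centered))


# ---------------------------------------------------------------------------
# discretised distributions and f-divergences
# ---------------------------------------------------------------------------


def discretize_gaussian(mean: float, sd: float, omega: np.ndarray,
                        floor: float = PROB_FLOOR) -> np.ndarray:
    """Gaussian pdf sampled on the support grid, floored and renormalised.

    The SD is floored at half the grid step so the density stays resolvable
    on the grid (a point mass cannot be represented on a finite support).
    """
    omega = np.asarray(omega, dtype=float)
    step = float(np.min(np.diff(omega)))
    sd = max(float(sd), 0.5 * step)
    z = (omega - mean) / sd
    pdf = np.exp(-0.5 * z * z)
    pdf = np.maximum(pdf, floor)
    return pdf / pdf.sum()


def default_omega(means: np.ndarray, sds: np.ndarray,
                  n_points: int = 256) -> np.ndarray:
    """Support grid spanning pooled means +/- 4x the largest SD."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    pad = 4.0 * max(float(sds.max()), 1e-6)
    lo, hi = float(means.min()) - pad, float(means.max()) + pad
    return np.linspace(lo, hi, n_points)


def density_tensor(means: np.ndarray, sds: np.ndarray, omega: np.ndarray,
                   floor: float = PROB_FLOOR) -> np.ndarray:
    """Discretised per-sample, per-dose Gaussians: shape (n, q, len(omega))."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    sds = np.atleast_2d(np.asarray(sds, dtype=float))
    n, q = means.shape
    out = np.empty((n, q, omega.size))
    for i in range(n):
        for j in range(q):
            out[i, j] = discretize_gaussian(means[i, j], sds[i, j], omega, floor)
    return out


def mixture_node_distribution(dists: Sequence[ResponseDistributionCurve],
                              dose_index: int,
                              omega: np.ndarray,
                              floor: float = PROB_FLOOR) -> DiscretizedDensity:
    """Equal-weight Gaussian mixture of the node samples' per-dose Gaussians,
    discretised on the support grid."""
    if not dists:
        raise ValueError("empty node")
    masses = np.mean([discretize_gaussian(d.means[dose_index], d.sds[dose_index],
                                          omega, floor) for d in dists], axis=0)
    return DiscretizedDensity(support=np.asarray(omega, dtype=float),
                              masses=masses / masses.sum())


def f_divergence(p: DiscretizedDensity | np.ndarray,
                 q: DiscretizedDensity | np.ndarray,
                 kind: str = "kl",
                 floor: float = PROB_FLOOR) -> float:
    """f-divergence between two discretised densities on a shared support.

    ``kind='kl'`` gives ``sum p * ln(p/q)`` (divergence of the sample
    distribution from the node mean); ``kind='hellinger'`` gives the squared
    Hellinger distance ``sum (sqrt(p) - sqrt(q))**2``, which lies in [0, 2].
    """
    if isinstance(p, DiscretizedDensity) and isinstance(q, DiscretizedDensity):
        if p.support.shape != q.support.shape or not np.allclose(p.support, q.support):
            raise ValueError("support mismatch")
        pm, qm = p.masses, q.masses
    else:
        pm = np.asarray(p, dtype=float)
        qm = np.asarray(q, dtype=float)
        if pm.shape != qm.shape:
            raise ValueError("support mismatch")
    pm = np.maximum(pm, floor)
    qm = np.maximum(qm, floor)
    if kind == "kl":
        return float(np.sum(pm * np.log(pm / qm)))
    if kind == "hellinger":
        return float(np.sum((np.sqrt(pm) - np.sqrt(qm)) ** 2))
    raise ValueError("kind must be 'kl' or 'hellinger'")


def divergence_cost(dists: Sequence[ResponseDistributionCurve],
                    spec: NodeCostSpec) -> float:
    """Distribution-based node cost: per dose region, the f-divergence of each
    sample's Gaussian from the node's mixture distribution, summed over
    samples and regions."""
    if not spec.is_divergence:
        raise ValueError("spec.kind must be a divergence cost")
    if not dists:
        raise ValueError("empty node")
    means = np.vstack([d.means for d in dists])
    sds = np.vstack([d.sds for d in dists])
    if spec.epsilon == 0 and np.any(sds == 0):
        raise ValueError("zero-SD distribution with epsilon=0")
    omega = spec.omega
    if omega is None:
        omega = default_omega(means, sds, spec.omega_points)
    total = 0.0
    for j in range(means.shape[1]):
        node = mixture_node_distribution(dists, j, omega, spec.epsilon or PROB_FLOOR)
        for d in dists:
            pj = discretize_gaussian(d.means[j], d.sds[j], omega,
                                     spec.epsilon or PROB_FLOOR)
            total += f_divergence(pj, node.masses, spec.divergence_kind,
                                  spec.epsilon or PROB_FLOOR)
    return total
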
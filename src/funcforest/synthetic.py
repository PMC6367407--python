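"""Synthetic benchmark generators.

The main benchmark emulates a clustered pharmacogenomic screen: samples fall
into ``n_clusters`` groups; each group has its own characteristic IC50, and
each sample's dose-response curve is a four-parameter sigmoid whose IC50
jitters around the group centre.  Relevant features are drawn from
per-cluster Gaussians whose ranges overlap only slightly (adjacent cluster
means 4 SDs apart, ~5% overlapping mass), and an equal number of spurious
standard-Gaussian noise features is appended; columns are shuffled with a
recorded relevant/noise mask.  Defaults produce a 75 x 20 design matrix
(15 samples from each of 5 clusters, 10 relevant + 10 noise features) and a
75 x 101 target matrix on 101 log-spaced doses spanning 0.0025-8 uM.

Additive Gaussian noise on the targets is parameterised as a fraction of the
global (noiseless) response range, so "5% noise" has a fixed meaning across
configurations.

A second generator builds a small function-to-function toy: per-sample
dose-expression curves for a panel of proteins with mixed trends
(decreasing / flat / increasing), a vehicle-control (DMSO) reference level,
and viability curves functionally linked to a subset of the protein curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DoseGrid, four_param_sigmoid

__all__ = [
    "SyntheticConfig",
    "SyntheticBenchmark",
    "FunctionalPredictorToy",
    "sigmoid_response",
    "make_design_matrix",
    "make_target_matrix",
    "make_benchmark",
    "make_functional_predictor_toy",
]


def sigmoid_response(d, a0: float, amax: float, ic50: float, theta: float):
    """Four-parameter sigmoid ``y(d) = A0 + (Amax - A0) / (1 + (IC50/d)^theta)``."""
    return four_param_sigmoid(d, a0, amax, ic50, theta)


@dataclass
class SyntheticConfig:
    """Full parameterisation of the clustered sigmoid benchmark.

    ``noise_level`` is the additive-noise SD as a fraction of the global
    noiseless response range (0.05 = "5% additive noise"); ``ic50_jitter_frac``
    the within-cluster relative IC50 jitter.  Defaults give the 75 x 20 design
    and 75 x 101 target shapes.
    """

    n_clusters: int = 5
    samples_per_cluster: int = 15
    n_relevant: int = 10
    n_noise: int = 10
    n_doses: int = 101
    a0: float = 1.0
    amax: float = 0.0
    theta: float = 2.0
    cluster_ic50_centers: np.ndarray | None = None
    ic50_jitter_frac: float = 0.10
    noise_level: float = 0.0
    dose_range: tuple[float, float] = (0.0025, 8.0)
    cluster_sep: float = 1.0  # Delta between adjacent cluster feature means
    wide_padding: int = 0  # extra spurious features for stress tests
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_ic50_centers is None:
            self.cluster_ic50_centers = np.logspace(
                np.log10(0.01), np.log10(4.0), self.n_clusters)
        centers = np.asarray(self.cluster_ic50_centers, dtype=float)
        if centers.size != self.n_clusters or np.any(np.diff(centers) <= 0):
            raise ValueError("cluster_ic50_centers must be strictly increasing, "
                             "one per cluster")
        self.cluster_ic50_centers = centers
        if not (0.0 <= self.ic50_jitter_frac < 1.0):
            raise ValueError("ic50_jitter_frac must be in [0, 1)")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_clusters * self.samples_per_cluster

    @property
    def n_features(self) -> int:
        return self.n_relevant + self.n_noise + self.wide_padding

    def doses(self) -> np.ndarray:
        lo, hi = self.dose_range
        return np.logspace(np.log10(lo), np.log10(hi), self.n_doses)


@dataclass
class SyntheticBenchmark:
    """One realisation of the benchmark (features, targets and ground truth)."""

    config: SyntheticConfig
    features: np.ndarray
    labels: np.ndarray
    relevant_mask: np.ndarray
    doses: np.ndarray
    targets: np.ndarray           # noisy (equals clean when noise_level == 0)
    targets_clean: np.ndarray
    ic50s: np.ndarray

    @property
    def grid(self) -> DoseGrid:
        return DoseGrid(self.doses)


def make_design_matrix(config: SyntheticConfig, rng: np.random.Generator):
    """Clustered feature matrix.

    Relevant features for a sample of cluster ``k`` are drawn from
    ``N(k * Delta, (Delta/4)^2)``, so adjacent clusters overlap in ~5% of
    their mass; noise features are standard Gaussians.  Columns are shuffled;
    returns ``(matrix, labels, relevant_mask)``.
    """
    n = config.n_samples
    labels = np.repeat(np.arange(config.n_clusters), config.samples_per_cluster)
    delta = config.cluster_sep
    sd = delta / 4.0
    relevant = labels[:, None] * delta + rng.normal(0.0, sd, size=(n, config.n_relevant))
    noise = rng.normal(0.0, 1.0, size=(n, config.n_noise + config.wide_padding))
    X = np.hstack([relevant, noise])
    mask = np.zeros(config.n_features, dtype=bool)
    mask[: config.n_relevant] = True
    perm = rng.permutation(config.n_features)
    return X[:, perm], labels, mask[perm]


def make_target_matrix(labels: np.ndarray, config: SyntheticConfig,
                       rng: np.random.Generator, return_details: bool = False):
    """Sigmoid dose-response targets for given cluster labels.

    Each sample's IC50 is its cluster centre scaled by ``1 + U(-j, +j)``
    jitter; responses are the four-parameter sigmoid on the log-spaced dose
    grid, plus additive Gaussian noise with SD ``noise_level`` x (global
    noiseless response range).
    """
    labels = np.asarray(labels)
    doses = config.doses()
    centers = config.cluster_ic50_centers[labels]
    j = config.ic50_jitter_frac
    ic50s = centers * (1.0 + rng.uniform(-j, j, size=labels.size)) if j > 0 \
        else centers.astype(float)
    clean = np.vstack([
        four_param_sigmoid(doses, config.a0, config.amax, ic, config.theta)
        for ic in ic50s])
    if config.noise_level > 0:
        sd = config.noise_level * float(clean.max() - clean.min())
        noisy = clean + rng.normal(0.0, sd, size=clean.shape)
    else:
        noisy = clean.copy()
    if return_details:
        return noisy, clean, ic50s, doses
    return noisy


def make_benchmark(config: SyntheticConfig | None = None,
                   seed: int | None = None) -> SyntheticBenchmark:
    """Generate one seeded realisation of the full benchmark."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X, labels, mask = make_design_matrix(config, rng)
    noisy, clean, ic50s, doses = make_target_matrix(labels, config, rng,
                                                    return_details=True)
    return SyntheticBenchmark(config=config, features=X, labels=labels,
                              relevant_mask=mask, doses=doses, targets=noisy,
                              targets_clean=clean, ic50s=ic50s)


# ---------------------------------------------------------------------------
# function-to-function toy
# ---------------------------------------------------------------------------


@dataclass
class FunctionalPredictorToy:
    """Per-sample dose-expression curves plus linked viability curves."""

    doses: np.ndarray                    # protein/viability dose grid (uM)
    expression: np.ndarray               # (n_samples, n_proteins, n_doses)
    dmso_reference: np.ndarray           # (n_proteins,) control expression
    viability: np.ndarray                # (n_samples, n_doses)
    trends: list[str] = field(default_factory=list)   # per protein
    linked_proteins: np.ndarray | None = None

    @property
    def grid(self) -> DoseGrid:
        return DoseGrid(self.doses)


def make_functional_predictor_toy(n_samples: int = 10, n_proteins: int = 21,
                                  n_doses: int = 7,
                                  rng: np.random.Generator | int | None = 0
                                  ) -> FunctionalPredictorToy:
    """Small functional-input benchmark (proteomic-screen shaped).

    A third of the proteins decrease with dose (sigmoid decline from the
    DMSO reference), a third stay flat, a third increase; each sample has a
    latent sensitivity that shifts the inflection dose of its decreasing
    proteins, and the viability curve's IC50 is tied to those same proteins,
    so curve features (AUC, IC_p) of the decreasing proteins are predictive.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    doses = np.logspace(np.log10(0.0032), np.log10(3.2), n_doses)
    trends = [("decreasing", "flat", "increasing")[p % 3] for p in range(n_proteins)]
    dmso = rng.uniform(0.8, 1.2, size=n_proteins)
    sens = rng.uniform(-0.5, 0.5, size=n_samples)  # latent log10 IC50 shift
    expression = np.empty((n_samples, n_proteins, n_doses))
    mid = np.sqrt(doses[0] * doses[-1])
    for i in range(n_samples):
        for p, trend in enumerate(trends):
            noise = rng.normal(0.0, 0.01, size=n_doses)
            if trend == "flat":
                # exactly flat: stays at the control level at every dose
                expression[i, p] = dmso[p]
                continue
            ic = mid * 10.0 ** (sens[i] + rng.normal(0.0, 0.05))
            drop = four_param_sigmoid(doses, 1.0, 0.0, ic, 2.0)
            depth = rng.uniform(0.6, 0.9)
            if trend == "decreasing":
                expression[i, p] = dmso[p] * (1.0 - depth * (1.0 - drop)) + noise
            else:
                expression[i, p] = dmso[p] * (1.0 + depth * (1.0 - drop)) + noise
    linked = np.array([p for p, t in enumerate(trends) if t == "decreasing"])
    viability = np.vstack([
        four_param_sigmoid(doses, 1.0, 0.05, mid * 10.0 ** sens[i], 2.0)
        for i in range(n_samples)])
    return FunctionalPredictorToy(doses=doses, expression=expression,
                                  dmso_reference=dmso, viability=viability,
                                  trends=trends, linked_proteins=linked)
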
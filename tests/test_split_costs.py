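import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from funcforest.curves import DoseGrid, ResponseDistributionCurve
from funcforest.split_costs import (
    NodeCostSpec,
    basis_cost,
    default_omega,
    discretize_gaussian,
    divergence_cost,
    f_divergence,
    mahalanobis_cost,
    mixture_node_distribution,
    pca_components,
    pca_cost,
    region_ssd_cost,
    ssd_cost,
)


class TestSSD:
    @pytest.mark.parametrize("values,expected", [
        ([1, 1, 1], 0.0),
        ([0, 2], 2.0),
        ([1, 2, 3, 4], 5.0),
    ])
    def test_values(self, values, expected):
        assert ssd_cost(values) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ssd_cost([])


class TestRegionSSD:
    def test_identical_curves_zero(self):
        assert region_ssd_cost(np.tile([0.3, 0.7], (4, 1))) == pytest.approx(0.0)

    def test_single_dose_reduces_to_ssd(self, rng):
        y = rng.normal(size=(6, 1))
        assert region_ssd_cost(y) == pytest.approx(ssd_cost(y[:, 0]))

    def test_worked_example(self):
        # per-dose SSDs of [[0,0],[2,4]] are 2 and 8
        assert region_ssd_cost(np.array([[0.0, 0.0], [2.0, 4.0]])) == pytest.approx(10.0)

    def test_region_partition_invariance(self, rng):
        y = rng.normal(size=(7, 6))
        assert region_ssd_cost(y) == pytest.approx(
            region_ssd_cost(y, regions=[[0, 1, 2], [3, 4], [5]]))

    def test_bad_regions(self, rng):
        y = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="disjoint"):
            region_ssd_cost(y, regions=[[0, 1], [1, 2]])
        with pytest.raises(ValueError, match="cover"):
            region_ssd_cost(y, regions=[[0, 1]])

    def test_mismatched_grids_error(self):
        g1 = DoseGrid(np.array([1.0, 2.0]))
        g2 = DoseGrid(np.array([1.0, 3.0]))
        from funcforest.curves import ResponseCurve
        curves = [ResponseCurve(grid=g1, values=np.zeros(2)),
                  ResponseCurve(grid=g2, values=np.zeros(2))]
        with pytest.raises(ValueError, match="share"):
            region_ssd_cost(curves)


class TestMahalanobis:
    def test_identity_reduces_to_region_ssd(self, rng):
        y = rng.normal(size=(8, 4))
        assert mahalanobis_cost(y, covariance=np.eye(4), ridge=0.0) == \
            pytest.approx(region_ssd_cost(y), rel=1e-10)

    def test_univariate_scaling(self, rng):
        y = rng.normal(size=(6, 1))
        sigma2 = 2.5
        assert mahalanobis_cost(y, covariance=np.array([[sigma2]]), ridge=0.0) == \
            pytest.approx(ssd_cost(y[:, 0]) / sigma2)

    def test_two_dose_explicit_arithmetic(self):
        y = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 0.0]])
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        inv = np.linalg.inv(cov)
        centered = y - y.mean(axis=0)
        expected = sum(c @ inv @ c for c in centered)
        assert mahalanobis_cost(y, covariance=cov, ridge=0.0) == \
            pytest.approx(expected)

    def test_singular_without_ridge_errors(self):
        y = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(np.linalg.LinAlgError):
            mahalanobis_cost(y, covariance=np.ones((2, 2)), ridge=0.0)


class TestPCABasis:
    def test_full_pc_count_equals_total_ssd(self, rng):
        y = rng.normal(size=(9, 4))
        assert pca_cost(y, 4) == pytest.approx(region_ssd_cost(y), rel=1e-9)

    def test_identical_rows_zero(self):
        assert pca_cost(np.tile([1.0, 2.0, 3.0], (5, 1)), 2) == pytest.approx(0.0)

    def test_rank_one_single_pc_captures_all(self, rng):
        base = rng.normal(size=4)
        y = np.outer(rng.normal(size=8), base)
        assert pca_cost(y, 1) == pytest.approx(region_ssd_cost(y), rel=1e-9)

    def test_pc_count_validation(self, rng):
        with pytest.raises(ValueError):
            pca_components(rng.normal(size=(3, 2)), 0)

    def test_basis_identity_gram_is_coefficient_ssd(self, rng):
        c = rng.normal(size=(6, 3))
        assert basis_cost(c, np.eye(3)) == pytest.approx(region_ssd_cost(c))

    def test_basis_worked_example(self):
        c = np.array([[1.0, 0.0], [0.0, 1.0]])
        gram = np.array([[2.0, 1.0], [1.0, 2.0]])
        centered = c - c.mean(axis=0)  # rows (.5,-.5), (-.5,.5)
        expected = sum(r @ gram @ r for r in centered)
        assert basis_cost(c, gram) == pytest.approx(expected)
        assert basis_cost(np.tile([3.0, 4.0], (4, 1)), gram) == pytest.approx(0.0)

    def test_basis_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            basis_cost(rng.normal(size=(4, 3)), np.eye(2))


def _dist(grid, means, sds):
    return ResponseDistributionCurve(grid=grid, means=np.asarray(means, float),
                                     sds=np.asarray(sds, float))


@pytest.fixture
def two_dose_grid():
    return DoseGrid(np.array([1.0, 2.0]))


class TestMixture:
    def test_single_sample_is_own_density(self, two_dose_grid):
        omega = np.linspace(-5, 5, 256)
        d = _dist(two_dose_grid, [0.0, 1.0], [1.0, 1.0])
        mix = mixture_node_distribution([d], 0, omega)
        assert np.allclose(mix.masses, discretize_gaussian(0.0, 1.0, omega))

    def test_two_identical_gaussians_same_as_one(self, two_dose_grid):
        omega = np.linspace(-5, 5, 256)
        d = _dist(two_dose_grid, [0.0, 1.0], [1.0, 1.0])
        mix2 = mixture_node_distribution([d, d], 0, omega)
        mix1 = mixture_node_distribution([d], 0, omega)
        assert np.allclose(mix1.masses, mix2.masses)

    def test_bimodal_mixture_mass_split(self, two_dose_grid):
        omega = np.linspace(-6, 10, 2048)
        a = _dist(two_dose_grid, [0.0, 0.0], [1.0, 1.0])
        b = _dist(two_dose_grid, [4.0, 4.0], [1.0, 1.0])
        mix = mixture_node_distribution([a, b], 0, omega)
        below = mix.masses[omega < 2.0].sum()
        assert below == pytest.approx(0.5, abs=1e-3)

    def test_empty_node_errors(self):
        with pytest.raises(ValueError):
            mixture_node_distribution([], 0, np.linspace(-1, 1, 64))


class TestFDivergence:
    def test_identical_densities_zero(self):
        omega = np.linspace(-6, 6, 512)
        p = discretize_gaussian(0.0, 1.0, omega)
        assert f_divergence(p, p, "kl") == pytest.approx(0.0, abs=1e-12)
        assert f_divergence(p, p, "hellinger") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_hellinger_is_two(self):
        p = np.zeros(64)
        q = np.zeros(64)
        p[:32] = 1 / 32
        q[32:] = 1 / 32
        assert f_divergence(p, q, "hellinger") == pytest.approx(2.0, abs=1e-4)

    def test_gaussian_closed_forms(self):
        omega = np.linspace(-6.5, 7.5, 4096)
        p = discretize_gaussian(0.0, 1.0, omega)
        q = discretize_gaussian(1.0, 1.0, omega)
        assert f_divergence(p, q, "kl") == pytest.approx(0.5, abs=1e-3)
        assert f_divergence(p, q, "hellinger") == \
            pytest.approx(2 - 2 * math.exp(-1 / 8), abs=1e-3)

    def test_kl_error_shrinks_with_grid_refinement(self):
        # convergence to the closed form is at least geometric in the grid
        # (in practice it is much faster, so allow a small numerical floor)
        errs = []
        for n in (32, 64, 128, 256, 512, 1024):
            omega = np.linspace(-6.5, 7.5, n)
            kl = f_divergence(discretize_gaussian(0.0, 1.0, omega),
                              discretize_gaussian(1.0, 1.0, omega), "kl")
            errs.append(abs(kl - 0.5))
        for coarse, fine in zip(errs[:-1], errs[1:]):
            assert fine <= max(coarse / 2, 1e-8)
        assert errs[-1] < 1e-6

    def test_hellinger_symmetric_kl_not(self):
        omega = np.linspace(-8, 8, 512)
        p = discretize_gaussian(0.0, 0.5, omega)
        q = discretize_gaussian(1.0, 2.0, omega)
        assert f_divergence(p, q, "hellinger") == \
            pytest.approx(f_divergence(q, p, "hellinger"), rel=1e-9)
        assert abs(f_divergence(p, q, "kl") - f_divergence(q, p, "kl")) > 0.1

    def test_support_mismatch_errors(self):
        with pytest.raises(ValueError):
            f_divergence(np.full(32, 1 / 32), np.full(64, 1 / 64))


class TestDivergenceCost:
    def test_shared_distribution_zero(self, two_dose_grid):
        spec = NodeCostSpec(kind="kl")
        d = _dist(two_dose_grid, [0.0, 1.0], [0.5, 0.5])
        assert divergence_cost([d, d, d], spec) == pytest.approx(0.0, abs=1e-9)

    def test_single_sample_zero(self, two_dose_grid):
        spec = NodeCostSpec(kind="hellinger")
        d = _dist(two_dose_grid, [0.2, 0.8], [0.3, 0.3])
        assert divergence_cost([d], spec) == pytest.approx(0.0, abs=1e-9)

    def test_two_gaussians_match_quadrature_oracle(self):
        grid = DoseGrid(np.array([1.0, 2.0]))
        a = _dist(grid, [0.0, 0.0], [1.0, 1.0])
        b = _dist(grid, [2.0, 2.0], [1.0, 1.0])
        omega = np.linspace(-8, 10, 4096)
        spec = NodeCostSpec(kind="kl", omega=omega)

        def mix_pdf(x):
            return 0.5 * norm.pdf(x, 0, 1) + 0.5 * norm.pdf(x, 2, 1)

        def integrand_a(x):
            p = norm.pdf(x, 0, 1)
            return p * math.log(p / mix_pdf(x)) if p > 0 else 0.0

        kl_a, _ = quad(integrand_a, -10, 12, limit=200)
        # by symmetry KL(a || mix) == KL(b || mix); two doses double it again
        expected = 4 * kl_a
        assert divergence_cost([a, b], spec) == pytest.approx(expected, rel=5e-3)

    def test_zero_sd_with_zero_epsilon_errors(self, two_dose_grid):
        spec = NodeCostSpec(kind="kl", epsilon=0.0)
        d = _dist(two_dose_grid, [0.0, 1.0], [0.0, 0.5])
        with pytest.raises(ValueError, match="zero-SD"):
            divergence_cost([d, d], spec)


class TestCostProperties:
    @pytest.mark.parametrize("kind", ["ssd", "region_ssd", "pca", "basis"])
    def test_splitting_never_increases_cost(self, kind, rng):
        """Variance decomposition: D(L) + D(R) <= D(P) for quadratic costs."""
        for _ in range(20):
            n = int(rng.integers(4, 12))
            y = rng.normal(size=(n, 5))
            components = pca_components(y, 2)
            gram = np.array([[2.0, 0.3, 0], [0.3, 1.0, 0.1], [0, 0.1, 0.5]])

            def cost(rows):
                if kind == "ssd":
                    return ssd_cost(rows[:, 0])
                if kind == "region_ssd":
                    return region_ssd_cost(rows)
                if kind == "pca":
                    return pca_cost(rows, 2, components=components)
                return basis_cost(rows[:, :3], gram)

            mask = rng.integers(0, 2, n).astype(bool)
            if mask.all() or not mask.any():
                continue
            assert cost(y[mask]) + cost(y[~mask]) <= cost(y) + 1e-9

    def test_omega_default_spans_means(self, rng):
        means = rng.normal(size=(5, 3))
        sds = rng.uniform(0.1, 0.5, size=(5, 3))
        omega = default_omega(means, sds, 64)
        assert omega[0] < means.min() and omega[-1] > means.max()
        assert omega.size == 64

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NodeCostSpec(kind="nope")
        with pytest.raises(ValueError):
            NodeCostSpec(kind="kl", omega=np.linspace(0, 1, 8))
        spec = NodeCostSpec(kind="divergence", divergence_kind="hellinger")
        assert spec.kind == "hellinger" and spec.is_divergence
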
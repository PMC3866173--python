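import numpy as np
import pytest

import cdac
from cdac.energy import EnergyParams, segment_energy, transition_cost
from cdac.optimizer import build_candidate_grid, edge_flux_matrices

from conftest import make_smooth_gradient, random_simple_contour


def dense_quadrature(grad, a, b, na, nb, n=5000):
    """Independent oracle: fine midpoint quadrature of the blended-normal flux."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    t = (np.arange(n) + 0.5) / n
    pts = a + t[:, None] * (b - a)
    mix = (1 - t)[:, None] * na + t[:, None] * nb
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    g = cdac.sample_gradient(grad, pts)
    return np.sum(mix * g) * np.linalg.norm(b - a) / n


class TestSegmentEnergy:
    def test_zero_on_constant_image(self):
        grad = cdac.sobel_gradient(cdac.frame_from_array(np.full((10, 10), 0.5)))
        e = segment_energy(grad, (1, 1), (8, 8), (1, 0), (0, 1))
        assert e == 0.0

    def test_step_edge_matches_dense_quadrature(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        grad = cdac.sobel_gradient(cdac.frame_from_array(img))
        a, b = (9.5, 3.0), (9.5, 15.0)  # runs along the edge
        n = (1.0, 0.0)  # normals aligned with the gradient
        e = segment_energy(grad, a, b, n, n, step=0.5)
        assert e > 0
        assert e == pytest.approx(dense_quadrature(grad, a, b, np.array(n), np.array(n)), rel=0.02)

    def test_flipping_both_normals_negates(self):
        grad = make_smooth_gradient(7)
        a, b = (4.0, 5.0), (15.0, 12.0)
        na, nb = np.array([0.6, 0.8]), np.array([1.0, 0.0])
        e = segment_energy(grad, a, b, na, nb)
        assert segment_energy(grad, a, b, -na, -nb) == pytest.approx(-e, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_default_step_close_to_refined_quadrature(self, seed):
        """Representative segments: short, with nearly parallel endpoint
        normals, as produced by a contour resampled at ~2 px spacing."""
        rng = np.random.default_rng(seed)
        grad = make_smooth_gradient(seed + 100, shape=(30, 30))
        a = rng.uniform(6, 22, 2)
        th = rng.uniform(0, 2 * np.pi)
        b = a + rng.uniform(1, 8) * np.array([np.cos(th), np.sin(th)])
        th1 = rng.uniform(0, 2 * np.pi)
        th2 = th1 + rng.uniform(-0.5, 0.5)
        na = np.array([np.cos(th1), np.sin(th1)])
        nb = np.array([np.cos(th2), np.sin(th2)])
        coarse = segment_energy(grad, a, b, na, nb, step=0.25)
        fine = segment_energy(grad, a, b, na, nb, step=0.0025)
        assert coarse == pytest.approx(fine, rel=0.02, abs=1e-6)


class TestExternalEnergy:
    def test_zero_on_constant_image(self, fine_circle):
        grad = cdac.sobel_gradient(cdac.frame_from_array(np.full((100, 100), 0.7)))
        assert cdac.external_energy(fine_circle, grad) == 0.0

    def test_never_positive_and_orientation_invariant(self, fine_circle):
        grad = make_smooth_gradient(9, shape=(100, 100), sigma=5)
        e = cdac.external_energy(fine_circle, grad)
        assert e <= 0
        reversed_c = cdac.Contour(fine_circle.vertices[::-1], orient=False)
        assert cdac.external_energy(reversed_c, grad) == pytest.approx(e, abs=1e-9)

    def test_bounded_by_max_gradient_magnitude(self):
        rng = np.random.default_rng(12)
        grad = cdac.sobel_gradient(cdac.frame_from_array(rng.uniform(size=(60, 60))))
        c = random_simple_contour(rng, 40, center=(30, 30), rmin=10, rmax=20)
        assert abs(cdac.external_energy(c, grad)) <= grad.max_magnitude() + 1e-9

    def test_stable_under_finer_resampling(self):
        img = np.zeros((80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        img[(xx - 40) ** 2 + (yy - 40) ** 2 <= 20**2] = 1.0
        from scipy import ndimage

        grad = cdac.sobel_gradient(
            cdac.frame_from_array(ndimage.gaussian_filter(img, 2))
        )
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        c = cdac.Contour(np.column_stack([40 + 20 * np.cos(th), 40 + 20 * np.sin(th)]))
        e1 = cdac.external_energy(c, grad)
        e2 = cdac.external_energy(cdac.resample(c, 0.2), grad)
        assert e1 == pytest.approx(e2, rel=0.02)


class TestTransitionCost:
    @pytest.fixture
    def setup(self):
        grad = make_smooth_gradient(21)
        params = EnergyParams(kappa=0.05)
        a, b = np.array([5.0, 5.0]), np.array([8.0, 6.0])
        na = nb = np.array([0.0, 1.0])
        return grad, params, a, b, na, nb

    def test_unmoved_segment_pays_no_kappa(self, setup):
        grad, params, a, b, na, nb = setup
        e = segment_energy(grad, a, b, na, nb, params.segment_sample_step)
        mean = e / np.linalg.norm(b - a)
        assert transition_cost(grad, a, b, a, b, na, nb, params) == pytest.approx(mean)

    def test_single_moved_endpoint_pays_kappa_once(self, setup):
        grad, params, a, b, na, nb = setup
        b2 = b + np.array([0.0, 1.0])
        mean = segment_energy(grad, a, b2, na, nb, params.segment_sample_step) / np.linalg.norm(b2 - a)
        assert transition_cost(grad, a, b, a, b2, na, nb, params) == pytest.approx(mean + params.kappa)

    def test_zero_kappa_is_plain_mean_energy(self, setup):
        grad, _, a, b, na, nb = setup
        params = EnergyParams(kappa=0.0)
        b2 = b + 1.0
        mean = segment_energy(grad, a, b2, na, nb, params.segment_sample_step) / np.linalg.norm(b2 - a)
        assert transition_cost(grad, a, b, a, b2, na, nb, params) == pytest.approx(mean)


class TestVectorizedFlux:
    def test_matches_scalar_segment_energy(self):
        """Per-edge flux matrices agree with the scalar quadrature path.

        The vectorized path shares one sample count per edge (from the
        longest candidate), so agreement is to quadrature accuracy, not
        bitwise.
        """
        rng = np.random.default_rng(31)
        grad = make_smooth_gradient(31, shape=(40, 40), sigma=2)
        c = random_simple_contour(rng, 8, center=(20, 20), rmin=6, rmax=12)
        grid = build_candidate_grid(c, R=2)
        flux = edge_flux_matrices(grid, grad, step=0.1)
        n, K = flux.shape[0], flux.shape[1]
        for e in range(n):
            for ki in range(0, K, 2):
                for kj in range(1, K, 2):
                    ref = segment_energy(
                        grad,
                        grid.positions[e, ki],
                        grid.positions[(e + 1) % n, kj],
                        grid.normals[e, ki],
                        grid.normals[(e + 1) % n, kj],
                        step=0.1,
                    )
                    assert flux[e, ki, kj] == pytest.approx(ref, rel=0.02, abs=1e-4)
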
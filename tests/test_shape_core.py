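"""Unit and property tests for Procrustes superimposition and shape distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import lvmotion as lv
from lvmotion.shape_core import (
    DegenerateConfigurationError,
    DegenerateRegressionError,
    _aligned_inner_product,
)

from conftest import random_preshape


def equilateral_triangle():
    ang = np.pi / 2 + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    return np.column_stack([np.cos(ang), np.sin(ang)])


class TestCenterAndScale:
    def test_translation_invariance(self, rng):
        x = rng.normal(size=(7, 3))
        a, _ = lv.center_and_scale(x)
        b, _ = lv.center_and_scale(x + np.array([10.0, -3.0, 7.0]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_scale_factorization(self, rng):
        x = rng.normal(size=(7, 3))
        a, sa = lv.center_and_scale(x)
        b, sb = lv.center_and_scale(5.0 * x)
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert sb == pytest.approx(5.0 * sa)

    def test_unit_size_and_centering(self, rng):
        pre, _ = lv.center_and_scale(rng.normal(size=(9, 3)))
        assert np.linalg.norm(pre) == pytest.approx(1.0)
        np.testing.assert_allclose(pre.mean(axis=0), 0.0, atol=1e-14)

    def test_coincident_landmarks_raise(self):
        with pytest.raises(DegenerateConfigurationError):
            lv.center_and_scale(np.ones((5, 3)))


class TestOptimalRotation:
    def test_identity_for_same_shape(self, rng):
        a = random_preshape(rng)
        np.testing.assert_allclose(lv.optimal_rotation(a, a), np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self, rng):
        a = random_preshape(rng)
        rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        r = lv.optimal_rotation(a, a @ rz.T)
        np.testing.assert_allclose(r, rz.T, atol=1e-10)

    def test_proper_rotation(self, rng):
        for _ in range(10):
            a, b = random_preshape(rng), random_preshape(rng)
            r = lv.optimal_rotation(a, b)
            np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)

    def test_beats_brute_force_rotation_sampling(self, rng):
        """Optimal fit is at least as good as 1e5 random candidate rotations."""
        a = random_preshape(rng, k=6)
        b = random_preshape(rng, k=6)
        best = np.linalg.norm(a @ lv.optimal_rotation(a, b) - b)
        cands = Rotation.random(100_000, random_state=7).as_matrix()
        fits = np.linalg.norm(np.einsum("km,nml->nkl", a, cands) - b, axis=(1, 2))
        assert best <= fits.min() + 1e-12

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            lv.optimal_rotation(random_preshape(rng, k=5), random_preshape(rng, k=6))


class TestDistances:
    def test_self_distance_zero(self, rng):
        a = random_preshape(rng)
        assert lv.riemannian_distance(a, a) == pytest.approx(0.0, abs=1e-7)
        assert lv.euclidean_distance(a, a) == pytest.approx(0.0, abs=1e-7)

    def test_mirrored_equilateral_triangle_attains_maximum(self):
        """A planar equilateral triangle and its mirror image lie a quarter
        circle apart -- the largest possible geodesic Procrustes distance."""
        tri = equilateral_triangle()
        a, _ = lv.center_and_scale(tri)
        b, _ = lv.center_and_scale(tri * np.array([-1.0, 1.0]))
        assert lv.riemannian_distance(a, b) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_chord_le_arc_random_pairs(self, rng):
        for _ in range(50):
            a, b = random_preshape(rng), random_preshape(rng)
            chord = lv.euclidean_distance(a, b)
            arc = lv.riemannian_distance(a, b)
            assert chord <= arc + 1e-12

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(30):
            a, b, c = (random_preshape(rng) for _ in range(3))
            assert lv.riemannian_distance(a, b) == pytest.approx(
                lv.riemannian_distance(b, a), abs=1e-12)
            assert (lv.riemannian_distance(a, c)
                    <= lv.riemannian_distance(a, b) + lv.riemannian_distance(b, c) + 1e-12)

    def test_small_perturbation_arc_matches_chord_cubically(self, rng):
        """chord = 2 sin(rho/2): the two metrics agree to O(rho^3) locally."""
        a = random_preshape(rng, k=12)
        v = rng.normal(size=a.shape)
        for eps in (1e-2, 1e-3):
            b, _ = lv.center_and_scale(a + eps * v)
            rho = lv.riemannian_distance(a, b)
            chord = lv.euclidean_distance(a, b)
            assert abs(rho - chord) < rho**3

    def test_euclidean_matches_direct_implementation(self, rng):
        """Closed form equals align-subtract-norm computed independently."""
        for _ in range(20):
            a, b = random_preshape(rng), random_preshape(rng)
            direct = np.linalg.norm(a @ lv.optimal_rotation(a, b) - b)
            assert lv.euclidean_distance(a, b) == pytest.approx(direct, abs=1e-12)


class TestGPA:
    def test_rigid_copies_collapse(self, rng):
        base = rng.normal(size=(10, 3))
        configs = []
        for i in range(5):
            r = Rotation.random(random_state=i).as_matrix()
            configs.append((1 + i) * base @ r + rng.normal(size=3))
        emb = lv.gpa(configs)
        spread = emb.aligned - emb.aligned.mean(axis=0)
        assert np.abs(spread).max() < 1e-8

    def test_two_shape_symmetry(self, rng):
        """The consensus of two shapes is geodesically equidistant from both."""
        a, b = random_preshape(rng, k=10), random_preshape(rng, k=10)
        emb = lv.gpa([a, b])
        mu = emb.mean_shape
        d0 = lv.riemannian_distance(emb.row_shape(0), mu)
        d1 = lv.riemannian_distance(emb.row_shape(1), mu)
        assert d0 == pytest.approx(d1, abs=1e-8)

    def test_alignment_group_invariance(self, rng):
        """Pairwise aligned distances survive arbitrary rigid motion + rescale
        of every input."""
        base = rng.normal(size=(8, 3))
        configs = [base + 0.2 * rng.normal(size=(8, 3)) for _ in range(6)]
        emb1 = lv.gpa(configs)
        moved = []
        for i, c in enumerate(configs):
            r = Rotation.random(random_state=100 + i).as_matrix()
            moved.append(0.5 * (i + 1) * c @ r + rng.normal(size=3) * 10)
        emb2 = lv.gpa(moved)

        def pairwise(emb):
            s = emb.shapes()
            return np.array([lv.riemannian_distance(s[i], s[j])
                             for i in range(6) for j in range(i + 1, 6)])

        np.testing.assert_allclose(pairwise(emb1), pairwise(emb2), atol=1e-9)

    def test_rows_unit_size_and_consensus_is_mean(self, rng):
        emb = lv.gpa([rng.normal(size=(8, 3)) for _ in range(5)])
        np.testing.assert_allclose(np.linalg.norm(emb.aligned, axis=1), 1.0, atol=1e-12)
        mean = emb.aligned.mean(axis=0)
        np.testing.assert_allclose(mean / np.linalg.norm(mean), emb.grand_mean, atol=1e-9)

    def test_needs_two_configs(self, rng):
        with pytest.raises(ValueError):
            lv.gpa([rng.normal(size=(8, 3))])


class TestTangentAndPCA:
    def test_consensus_maps_to_origin_and_idempotence(self, rng):
        emb = lv.gpa([rng.normal(size=(9, 3)) for _ in range(6)])
        t = lv.tangent_project(emb)
        # consensus row would project to zero
        mu_proj = emb.grand_mean - (emb.grand_mean @ emb.grand_mean) * emb.grand_mean
        np.testing.assert_allclose(mu_proj, 0.0, atol=1e-12)
        # idempotent: re-projecting the projected rows changes nothing
        t2 = t - np.outer(t @ emb.grand_mean, emb.grand_mean)
        np.testing.assert_allclose(t, t2, atol=1e-12)

    def test_collinear_data_has_one_component(self, rng):
        base = rng.normal(size=30)
        direction = rng.normal(size=30)
        x = np.outer(np.linspace(-1, 1, 12), direction) + base
        res = lv.pca(x)
        assert res.eigenvalues.size == 1

    def test_variance_conservation_and_diagonal_scores(self, rng):
        x = rng.normal(size=(15, 6))
        res = lv.pca(x, n_components=None)
        assert res.total_variance == pytest.approx(x.var(axis=0, ddof=1).sum())
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance)
        cov = np.cov(res.scores, rowvar=False)
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-10)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_scores_preserve_pairwise_distances(self, rng):
        x = rng.normal(size=(10, 7))
        res = lv.pca(x, n_components=None)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(res.scores), pdist(x), atol=1e-9)

    def test_variance_explained_sums_below_one(self, rng):
        res = lv.pca(rng.normal(size=(20, 12)), n_components=5)
        assert 0 < res.variance_explained.sum() <= 1 + 1e-12

    def test_requires_three_observations(self, rng):
        with pytest.raises(ValueError):
            lv.pca(rng.normal(size=(2, 5)))

    def test_reconstruction(self, rng):
        emb = lv.gpa([rng.normal(size=(9, 3)) for _ in range(8)])
        t = lv.tangent_project(emb)
        res = lv.pca(t, n_components=None)
        # score zero -> consensus-side center
        np.testing.assert_allclose(
            lv.reconstruct_along_pc(res, 0, 0.0, emb.k, emb.ndim).ravel(),
            res.center, atol=1e-12)
        # reconstructing at a real observation's scores recovers it
        rec = res.center + res.scores[3] @ res.components
        np.testing.assert_allclose(rec, t[3], atol=1e-9)
        # +/- equal scores mirror about the center
        plus = lv.reconstruct_along_pc(res, 1, 0.3, emb.k, emb.ndim)
        minus = lv.reconstruct_along_pc(res, 1, -0.3, emb.k, emb.ndim)
        np.testing.assert_allclose(plus + minus, 2 * res.center.reshape(emb.k, 3),
                                   atol=1e-12)
        with pytest.raises(IndexError):
            lv.reconstruct_along_pc(res, res.n_components, 0.1, emb.k, emb.ndim)


class TestEligibilityDiagnostic:
    def test_identical_shapes_degenerate(self, rng):
        base = rng.normal(size=(8, 3))
        emb = lv.gpa([base.copy() for _ in range(4)])
        with pytest.raises(DegenerateRegressionError):
            lv.eligibility_diagnostic(emb)

    def test_low_dispersion_slope_near_one(self, low_dispersion_cloud):
        configs, _ = low_dispersion_cloud
        emb = lv.gpa(configs)
        rep = lv.eligibility_diagnostic(emb, mode="pairwise")
        assert rep.max_riemannian < 0.1
        assert 0.99 <= rep.slope <= 1.0 + 1e-9

    def test_slope_increases_as_dispersion_shrinks(self, rng):
        base = random_preshape(rng, k=15)
        slopes = []
        for scale in (0.3, 0.1, 0.03):
            configs = []
            for _ in range(10):
                v = rng.normal(size=base.shape)
                configs.append(base + scale * v / np.linalg.norm(v))
            emb = lv.gpa(configs)
            slopes.append(lv.eligibility_diagnostic(emb, mode="pairwise").slope)
        assert slopes[0] < slopes[1] < slopes[2] <= 1 + 1e-9

    def test_modes_and_tangent_distance(self, low_dispersion_cloud):
        configs, _ = low_dispersion_cloud
        emb = lv.gpa(configs)
        for mode in ("pairwise", "from_consensus"):
            for dist in ("chordal", "tangent"):
                rep = lv.eligibility_diagnostic(emb, mode=mode, distance=dist)
                assert 0.97 < rep.slope <= 1.0 + 1e-6
                assert rep.uncentered_correlation > 0.999
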
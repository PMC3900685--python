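"""Tests for homologous-time interpolation and trajectory attributes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import lvmotion as lv
from lvmotion.trajectory import (
    ACTIVE_MASK,
    HomologousTrajectory,
    trajectory_gpa,
)


def make_events(*vals):
    return lv.EventTimes(*vals)


class TestHomologousTimeGrid:
    def test_midpoint_arithmetic(self):
        ev = make_events(0, 100, 200, 300, 400, 500)
        np.testing.assert_allclose(
            lv.homologous_time_grid(ev),
            [0, 50, 100, 200, 300, 350, 400, 450, 500])

    def test_nine_strictly_increasing_times(self):
        ev = make_events(0, 130, 210, 260, 410, 600)
        grid = lv.homologous_time_grid(ev)
        assert len(grid) == 9
        assert np.all(np.diff(grid) > 0)
        assert ACTIVE_MASK.sum() == 6 and len(ACTIVE_MASK) == 9

    def test_nonincreasing_events_rejected(self):
        with pytest.raises(ValueError):
            make_events(0, 100, 50, 300, 400, 500)


class TestInterpolation:
    def test_exact_at_knots(self, rng):
        times = np.arange(0, 500, 50.0)
        scores = rng.normal(size=(10, 3))
        out = lv.interpolate_pc_scores(times, scores, times[[0, 3, 7]])
        np.testing.assert_allclose(out, scores[[0, 3, 7]], atol=1e-12)

    def test_linear_data_reproduced(self):
        times = np.arange(0, 500, 50.0)
        scores = np.outer(times, [0.01, -0.02, 0.003])
        targets = np.array([25.0, 125.0, 333.0])
        out = lv.interpolate_pc_scores(times, scores, targets)
        np.testing.assert_allclose(out, np.outer(targets, [0.01, -0.02, 0.003]),
                                   atol=1e-9)

    def test_sinusoid_recovered_at_frame_sampling(self):
        """A unit-amplitude sinusoidal score curve sampled every 50 ms is
        interpolated with error below 0.01."""
        times = np.arange(0.0, 1000.0, 50.0)
        period = 1000.0
        f = lambda t: np.sin(2 * np.pi * t / period)
        targets = np.linspace(50.0, 900.0, 40)
        out = lv.interpolate_pc_scores(times, f(times)[:, None], targets)
        assert np.abs(out.ravel() - f(targets)).max() < 0.01

    def test_extrapolation_rejected(self, rng):
        times = np.arange(0, 300, 50.0)
        with pytest.raises(ValueError, match="window"):
            lv.interpolate_pc_scores(times, rng.normal(size=(6, 3)), [400.0])

    def test_few_knots_fall_back_with_warning(self):
        times = np.array([0.0, 100.0, 200.0])
        scores = np.array([[0.0], [1.0], [4.0]])  # quadratic t^2/1e4
        with pytest.warns(UserWarning, match="falling back"):
            out = lv.interpolate_pc_scores(times, scores, [50.0])
        assert out.shape == (1, 1)


class TestAttributes:
    def test_size_of_collinear_points(self):
        pts = np.outer(np.arange(9), [1.0, 0.0, 0.0]) * 0.5
        assert lv.trajectory_size(pts) == pytest.approx(8 * 0.5)

    def test_size_zero_for_coincident_points(self):
        assert lv.trajectory_size(np.ones((9, 3))) == 0.0

    def test_size_rotation_invariant(self, rng):
        pts = rng.normal(size=(9, 3))
        r = Rotation.random(random_state=0).as_matrix()
        assert lv.trajectory_size(pts @ r.T) == pytest.approx(lv.trajectory_size(pts))

    @pytest.mark.parametrize("delta,expected", [
        ((1.0, 1.0), 45.0),
        ((-1.0, 0.0), 180.0),
        ((0.0, -2.0), -90.0),
    ])
    def test_orientation_angles(self, delta, expected):
        pts = np.zeros((9, 3))
        pts[3, :2] = delta
        assert lv.trajectory_orientation(pts) == pytest.approx(expected)

    def test_orientation_undefined_for_coincident_endpoints(self):
        with pytest.raises(ValueError, match="undefined"):
            lv.trajectory_orientation(np.zeros((9, 3)))

    def test_attributes_invariant_to_time_units(self, rng):
        """Size and orientation are computed in PC space, so rescaling the
        time axis (ms vs s) changes nothing."""
        times = np.arange(0, 500, 50.0)
        scores = rng.normal(size=(10, 3)).cumsum(axis=0) * 0.1
        ev = make_events(0, 120, 190, 230, 310, 440)
        grid_ms = lv.homologous_time_grid(ev)
        pts_ms = lv.interpolate_pc_scores(times, scores, grid_ms)
        pts_s = lv.interpolate_pc_scores(times / 1000.0, scores, grid_ms / 1000.0)
        np.testing.assert_allclose(pts_ms, pts_s, atol=1e-9)


class TestTrajectoryGPA:
    def _random_trajs(self, rng, n=5):
        return [HomologousTrajectory(subject_id=f"S{i}", times=np.arange(9.0),
                                     points=rng.normal(size=(9, 3)))
                for i in range(n)]

    def test_identical_trajectories_zero_variance(self, rng):
        pts = rng.normal(size=(9, 3))
        trajs = [HomologousTrajectory(f"S{i}", np.arange(9.0), pts.copy())
                 for i in range(4)]
        res = trajectory_gpa(trajs)
        assert res.pca.total_variance < 1e-20

    def test_similarity_copies_align_exactly(self, rng):
        pts = rng.normal(size=(9, 3))
        r = Rotation.random(random_state=3).as_matrix()
        copy = 2.5 * pts @ r.T + np.array([1.0, -2.0, 0.5])
        trajs = [HomologousTrajectory("A", np.arange(9.0), pts),
                 HomologousTrajectory("B", np.arange(9.0), copy),
                 HomologousTrajectory("C", np.arange(9.0), pts.copy())]
        res = trajectory_gpa(trajs)
        assert np.abs(res.aligned[0] - res.aligned[1]).max() < 1e-9

    def test_passive_points_never_influence_transforms(self, rng):
        """Displacing only passive midpoints leaves the fitted transforms
        identical to a fit with the passive points deleted."""
        trajs = self._random_trajs(rng)
        moved = []
        for t in trajs:
            pts = t.points.copy()
            pts[~ACTIVE_MASK] += rng.normal(scale=50.0, size=(3, 3))  # huge offsets
            moved.append(HomologousTrajectory(t.subject_id, t.times, pts))
        res_orig = trajectory_gpa(trajs)
        res_moved = trajectory_gpa(moved)
        # active rows of the aligned shapes agree exactly: the transforms are
        # untouched by passive displacement
        np.testing.assert_allclose(res_orig.aligned[:, ACTIVE_MASK],
                                   res_moved.aligned[:, ACTIVE_MASK], atol=1e-9)
        # independent oracle: a plain GPA of the six active points alone must
        # induce the same aligned-shape geometry (pairwise distances)
        active_only = [t.points[ACTIVE_MASK] for t in trajs]
        oracle = lv.gpa(active_only)
        n = len(trajs)
        for i in range(n):
            for j in range(i + 1, n):
                d_traj = lv.riemannian_distance(
                    res_orig.aligned[i][ACTIVE_MASK]
                    / np.linalg.norm(res_orig.aligned[i][ACTIVE_MASK]),
                    res_orig.aligned[j][ACTIVE_MASK]
                    / np.linalg.norm(res_orig.aligned[j][ACTIVE_MASK]))
                d_oracle = lv.riemannian_distance(oracle.row_shape(i),
                                                  oracle.row_shape(j))
                assert d_traj == pytest.approx(d_oracle, abs=1e-9)

    def test_inconsistent_masks_rejected(self, rng):
        t1 = HomologousTrajectory("A", np.arange(9.0), rng.normal(size=(9, 3)))
        mask = ACTIVE_MASK.copy()
        mask[[1, 2]] = [True, False]
        t2 = HomologousTrajectory("B", np.arange(9.0), rng.normal(size=(9, 3)),
                                  active_mask=mask)
        t3 = HomologousTrajectory("C", np.arange(9.0), rng.normal(size=(9, 3)))
        with pytest.raises(ValueError, match="mask"):
            trajectory_gpa([t1, t2, t3])

    def test_shared_shape_with_random_similarity_noise(self, rng):
        """A cohort sharing one trajectory shape under random rotations and
        scalings has zero trajectory-shape variance after alignment, while
        size and orientation still vary."""
        pts = rng.normal(size=(9, 3))
        trajs, sizes, angles = [], [], []
        for i in range(6):
            r = Rotation.random(random_state=i).as_matrix()
            s = rng.uniform(0.5, 3.0)
            moved = s * pts @ r.T
            trajs.append(HomologousTrajectory(f"S{i}", np.arange(9.0), moved))
            sizes.append(lv.trajectory_size(moved))
            angles.append(lv.trajectory_orientation(moved))
        res = trajectory_gpa(trajs)
        assert res.pca.total_variance < 1e-10
        assert np.std(sizes) > 0 and np.std(angles) > 0
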
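"""Trajectory I/O, arc-length machinery, resampling and distance scoring."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as hs

from fishnav import (
    Trajectory,
    arc_length,
    crop_at_turnback,
    crop_to_common_length,
    interpolate_1000,
    pointwise_distances,
    read_trajectories,
)
from fishnav.errors import ContractError, DegenerateTrajectoryError, ValidationError
from fishnav.trajectory import truncate_to_length, write_trajectories


def _csv(text: str) -> io.StringIO:
    return io.StringIO("trial_id,fish_id,t_s,x_cm,y_cm\n" + text)


class TestReadTrajectories:
    def test_single_trial_parse(self):
        trs = read_trajectories(_csv("a,f1,0,1,2\na,f1,1,2,3\na,f1,2,3,4\n"))
        assert len(trs) == 1 and trs[0].n_samples == 3
        assert trs[0].trial_id == "a" and trs[0].fish_id == "f1"

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValidationError, match="non-monotone|strictly"):
            read_trajectories(_csv("a,f1,0,1,2\na,f1,1,2,3\na,f1,1,3,4\n"))

    def test_interleaved_trials_grouped_and_sorted(self):
        trs = read_trajectories(
            _csv("b,f2,1,5,5\na,f1,0,1,1\nb,f2,0,4,4\na,f1,1,2,2\n")
        )
        assert [t.trial_id for t in trs] == ["a", "b"]
        for t in trs:
            assert np.all(np.diff(t.t) > 0)

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError, match="missing columns"):
            read_trajectories(io.StringIO("trial_id,fish_id,t_s,x_cm\na,f,0,1\n"))

    def test_malformed_rows_reported_with_line_numbers(self):
        with pytest.raises(ValidationError, match=r"lines \[3\]"):
            read_trajectories(_csv("a,f1,0,1,2\na,f1,oops,2,3\na,f1,2,3,4\n"))

    def test_out_of_tank_rejected(self):
        with pytest.raises(ValidationError, match="outside the tank"):
            read_trajectories(_csv("a,f1,0,1,2\na,f1,1,200,3\n"), tank_side=130.0)

    def test_round_trip(self, tmp_path):
        tr = Trajectory("t1", "f1", [0.0, 1.0, 2.0], [[1, 2], [3, 4.5], [5, 6.25]])
        path = tmp_path / "out.csv"
        write_trajectories([tr], path)
        back = read_trajectories(path)[0]
        np.testing.assert_allclose(back.xy, tr.xy, atol=1e-6)


class TestArcLength:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0), (3, 4)], 5.0),
            ([(0, 0), (1, 0), (1, 1)], 2.0),
            ([(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)], 40.0),
        ],
    )
    def test_examples(self, pts, expected):
        assert arc_length(np.asarray(pts, float)) == pytest.approx(expected)

    def test_single_point_rejected(self):
        with pytest.raises(DegenerateTrajectoryError):
            arc_length(np.array([[0.0, 0.0]]))


class TestCropToCommonLength:
    def test_longer_observed_truncated(self):
        obs = np.array([[0, 0], [100, 0]], float)
        mod = np.array([[0, 0], [38.6, 0]], float)
        a, b = crop_to_common_length(obs, mod)
        assert arc_length(a) == pytest.approx(38.6, abs=1e-9)
        assert arc_length(b) == pytest.approx(38.6, abs=1e-9)

    def test_shorter_observed_truncates_model(self):
        obs = np.array([[0, 0], [20, 0]], float)
        mod = np.array([[0, 0], [38.6, 0]], float)
        a, b = crop_to_common_length(obs, mod)
        assert arc_length(a) == pytest.approx(20.0, abs=1e-9)
        assert arc_length(b) == pytest.approx(20.0, abs=1e-9)

    def test_equal_lengths_unchanged(self):
        obs = np.array([[0, 0], [0, 10]], float)
        mod = np.array([[5, 5], [15, 5]], float)
        a, b = crop_to_common_length(obs, mod)
        np.testing.assert_allclose(a, obs)
        np.testing.assert_allclose(b, mod)

    @given(
        lengths=hs.lists(hs.floats(0.5, 20.0), min_size=1, max_size=8),
        cut=hs.floats(0.05, 0.95),
    )
    def test_truncation_never_lengthens(self, lengths, cut):
        """Truncating at any fraction yields exactly that arc length."""
        # staircase polyline with the given segment lengths
        pts = [np.zeros(2)]
        for i, L in enumerate(lengths):
            step = np.array([L, 0.0]) if i % 2 == 0 else np.array([0.0, L])
            pts.append(pts[-1] + step)
        pts = np.vstack(pts)
        total = arc_length(pts)
        out = truncate_to_length(pts, cut * total)
        assert arc_length(out) == pytest.approx(cut * total, abs=1e-9)


class TestInterpolate1000:
    def test_straight_segment_exact(self):
        ip = interpolate_1000(np.array([[0, 0], [999, 0]], float))
        assert ip.points.shape == (1000, 2)
        np.testing.assert_allclose(ip.points[:, 1], 0.0, atol=1e-9)
        np.testing.assert_allclose(ip.points[:, 0], np.arange(1000.0), atol=1e-9)
        spacing = np.linalg.norm(np.diff(ip.points, axis=0), axis=1)
        np.testing.assert_allclose(spacing, 1.0, atol=1e-6)

    def test_l_path_length_preserved(self):
        """Resampled right-angle path keeps its arc length (vs dense oracle)."""
        L = np.array([[0, 0], [10, 0], [10, 10]], float)
        ip = interpolate_1000(L)
        # brute-force oracle: dense linear resampling of the polyline itself
        dense = np.vstack(
            [np.column_stack([np.linspace(0, 10, 5000), np.zeros(5000)]),
             np.column_stack([np.full(5000, 10.0), np.linspace(0, 10, 5000)])]
        )
        assert arc_length(ip.points) == pytest.approx(arc_length(dense), rel=1e-3)
        assert arc_length(ip.points) == pytest.approx(ip.source_length, rel=1e-3)

    def test_two_point_input_is_linear(self):
        ip = interpolate_1000(np.array([[1, 1], [4, 5]], float))
        t = np.linspace(0, 1, 1000)[:, None]
        np.testing.assert_allclose(ip.points, [1, 1] + t * np.array([3.0, 4.0]), atol=1e-9)

    def test_idempotent_on_equal_spacing(self):
        """A 1000-point equal-spacing V path re-interpolates onto itself."""
        h = 0.05
        leg1 = np.column_stack([np.arange(500) * h, np.zeros(500)])
        apex = leg1[-1]
        leg2 = apex + np.column_stack([np.arange(1, 501) * h / math.sqrt(2),
                                       np.arange(1, 501) * h / math.sqrt(2)])
        base = np.vstack([leg1, leg2])
        again = interpolate_1000(base)
        assert np.max(np.linalg.norm(again.points - base, axis=1)) < 1e-6

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateTrajectoryError):
            interpolate_1000(np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_endpoints_exact(self):
        pts = np.array([[0, 0], [3, 1], [5, 4], [2, 7]], float)
        ip = interpolate_1000(pts)
        np.testing.assert_allclose(ip.points[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(ip.points[-1], pts[-1], atol=1e-12)


class TestPointwiseDistances:
    def test_identity_zero(self):
        ip = interpolate_1000(np.array([[0, 0], [10, 5]], float))
        d, m = pointwise_distances(ip, ip)
        assert m == 0.0 and np.all(d == 0.0)

    def test_translation_gives_constant_distance(self):
        a = interpolate_1000(np.array([[0, 0], [10, 0], [10, 10]], float))
        b = interpolate_1000(np.array([[3, 4], [13, 4], [13, 14]], float))
        d, m = pointwise_distances(a, b)
        np.testing.assert_allclose(d, 5.0, atol=1e-9)
        assert m == pytest.approx(5.0, abs=1e-9)

    def test_orthogonal_unit_segments_mean(self):
        """Mean distance of unit segments at right angles = mean of sqrt(2)*s."""
        a = interpolate_1000(np.array([[0, 0], [1, 0]], float))
        b = interpolate_1000(np.array([[0, 0], [0, 1]], float))
        _, m = pointwise_distances(a, b)
        assert m == pytest.approx(math.sqrt(2) / 2, abs=1e-3)

    def test_rigid_motion_invariance(self):
        """Rotating/translating both paths together preserves the mean."""
        pts_a = np.array([[0, 0], [10, 0], [10, 10]], float)
        pts_b = np.array([[0, 0], [8, 3], [12, 9]], float)
        _, m0 = pointwise_distances(interpolate_1000(pts_a), interpolate_1000(pts_b))
        phi = math.radians(37.0)
        R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        shift = np.array([5.0, -2.0])
        _, m1 = pointwise_distances(
            interpolate_1000(pts_a @ R.T + shift), interpolate_1000(pts_b @ R.T + shift)
        )
        # component-wise shape-preserving interpolation is rotation-
        # equivariant only up to sub-station-scale corner smoothing
        assert m1 == pytest.approx(m0, abs=1e-5)

    def test_translation_equivariance_exact(self):
        pts_a = np.array([[0, 0], [10, 0], [10, 10]], float)
        pts_b = np.array([[0, 0], [8, 3], [12, 9]], float)
        _, m0 = pointwise_distances(interpolate_1000(pts_a), interpolate_1000(pts_b))
        shift = np.array([7.0, -3.0])
        _, m1 = pointwise_distances(
            interpolate_1000(pts_a + shift), interpolate_1000(pts_b + shift)
        )
        assert m1 == pytest.approx(m0, abs=1e-9)


class TestCropAtTurnback:
    def _traj(self, xy):
        xy = np.asarray(xy, float)
        return Trajectory("t", "f", np.arange(len(xy), dtype=float), xy)

    def test_straight_out_and_back(self):
        """10 s outbound then a straight return crops at the reversal."""
        out = [(0.0, float(i)) for i in range(11)]  # away from chamber at origin
        back = [(0.0, 10.0 - i) for i in range(1, 6)]
        tr = self._traj(out + back)
        cropped = crop_at_turnback(tr, chamber=np.zeros(2))
        assert cropped.crop_index == 10
        assert cropped.n_samples == 11

    def test_never_oriented_back_returns_window(self):
        xy = [(float(i), 0.0) for i in range(20)]
        tr = self._traj(xy)
        cropped = crop_at_turnback(tr, chamber=np.array([-5.0, 0.0]), analysis_window=15.0)
        assert cropped.crop_index is None
        assert cropped.n_samples == 16  # samples at t = 0..15

    def test_persistence_ignores_single_glance(self):
        """One step toward the chamber does not trigger the crop."""
        xy = [(0, 0), (0, 1), (0, 2), (0, 1.5), (0, 3), (0, 4), (0, 5)]
        tr = self._traj(xy)
        cropped = crop_at_turnback(tr, chamber=np.zeros(2), persistence=2)
        assert cropped.crop_index is None

    def test_short_trajectory_rejected(self):
        with pytest.raises(DegenerateTrajectoryError):
            crop_at_turnback(
                Trajectory("t", "f", [0.0, 1.0], [[0, 0], [1, 1]]), np.zeros(2)
            )

    def test_immediate_turnback_degenerate(self):
        xy = [(0, 5), (0, 4), (0, 3), (0, 2)]
        with pytest.raises(DegenerateTrajectoryError):
            crop_at_turnback(self._traj(xy), chamber=np.zeros(2))
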
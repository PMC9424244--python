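"""Direction-referenced statistics: angles, radial distance, directionality."""

import numpy as np
import pytest

from spherotrack.kinematics import (
    DegenerateGeometryError,
    angular_displacement,
    binned_mean_series,
    directionality,
    directionality_by_distance,
    major_axis,
    phi_angle,
    radial_distance,
    radial_vector,
    radial_velocity,
    step_velocities,
)
from spherotrack.simulate import SimulationConfig, simulate_ensemble
from spherotrack.trackdata import Assay, Ensemble

from conftest import linear_traj, make_traj


def ga_traj(points, dt=1.0, track_id="g"):
    return make_traj(points, dt=dt, track_id=track_id, assay=Assay.GA)


class TestStepVelocities:
    def test_single_step(self):
        v = step_velocities(make_traj([(0, 0), (3, 0)], dt=3.0))
        assert np.allclose(v, [[1, 0]])

    def test_stationary_zero(self):
        assert np.allclose(step_velocities(make_traj([(1, 1)] * 4)), 0.0)

    def test_half_minute_interval(self):
        v = step_velocities(make_traj([(0, 0), (1, 1)], dt=0.5))
        assert np.allclose(v, [[2, 2]])


class TestAngularDisplacement:
    def test_straight_track_zero_angles(self):
        d = angular_displacement(linear_traj(n=10), tau=3.0)
        assert np.allclose(d.angles, 0.0)

    def test_u_turn_is_180(self):
        t = make_traj([(0, 0), (1, 0), (0, 0)])
        d = angular_displacement(t, tau=1.0)
        assert d.angles[0] == pytest.approx(180.0)

    def test_orthogonal_steps_90(self):
        t = make_traj([(0, 0), (1, 0), (1, 1)])
        assert angular_displacement(t, 1.0).angles[0] == pytest.approx(90.0)

    def test_zero_velocity_pairs_skipped(self):
        t = make_traj([(0, 0), (0, 0), (1, 0), (2, 0)])
        d = angular_displacement(t, 1.0)
        assert d.n_skipped == 1
        assert len(d.angles) == 1

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            angular_displacement(linear_traj(n=10), tau=1.5)


class TestMajorAxisAndRadialVector:
    def test_straight_track_step(self):
        assert np.allclose(major_axis(linear_traj(v=(2, 0), n=6)), [2, 0])

    def test_closed_loop_zero(self):
        loop = make_traj([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert np.allclose(major_axis(loop), 0.0)

    def test_mean_of_two_steps(self):
        t = make_traj([(0, 0), (1, 0), (1, 1)])
        assert np.allclose(major_axis(t), [0.5, 0.5])

    def test_ga_radial_vector_is_start(self):
        t = ga_traj([(40, 0), (45, 0)])
        assert np.allclose(radial_vector(t), [40, 0])

    def test_gfa_radial_vector_is_first_step(self):
        t = make_traj([(0, 0), (0, 5), (0, 9)])
        assert np.allclose(radial_vector(t), [0, 5])

    def test_ga_start_at_center_excluded(self):
        t = ga_traj([(0, 0), (1, 0)])
        with pytest.raises(DegenerateGeometryError):
            radial_vector(t)


class TestPhiAngle:
    def test_parallel_zero(self):
        assert phi_angle(ga_traj([(40, 0), (50, 0), (60, 0)])) == pytest.approx(0.0)

    def test_perpendicular_90(self):
        assert phi_angle(ga_traj([(40, 0), (40, 10), (40, 20)])) == pytest.approx(90.0)

    def test_zero_major_axis_excluded(self):
        loop = ga_traj([(40, 0), (41, 0), (40, 0)])
        with pytest.raises(DegenerateGeometryError, match="major axis"):
            phi_angle(loop)

    def test_isotropic_null_median_near_90(self):
        """m independent of a random reference direction gives median phi = 90 deg."""
        config = SimulationConfig(
            delta=0.0, P_mean=16.6, S_mean=1.15, assay=Assay.GFA,
            n_tracks=1500, d_min=0.0, seed=99,
        )
        ens = simulate_ensemble(config)
        rng = np.random.default_rng(5)
        angles = []
        for traj in ens:
            m = major_axis(traj)
            theta = rng.uniform(0, 2 * np.pi)
            r = np.array([np.cos(theta), np.sin(theta)])
            c = np.clip(np.dot(m, r) / np.hypot(*m), -1, 1)
            angles.append(np.degrees(np.arccos(c)))
        assert abs(np.median(angles) - 90.0) < 3.0


class TestRadialDistanceAndVelocity:
    def test_ga_outward(self):
        t = ga_traj([(40, 0), (50, 0)])
        assert radial_distance(t)[-1] == pytest.approx(10.0)

    def test_ga_rotation_invariance(self):
        t = ga_traj([(40, 0), (0, 40)])
        assert radial_distance(t)[-1] == pytest.approx(0.0)

    def test_gfa_three_four_five(self):
        t = make_traj([(0, 0), (3, 4)])
        assert radial_distance(t)[-1] == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "second,expected", [((42, 0), 2.0), ((40, 2), 0.0), ((38, 0), -2.0)]
    )
    def test_radial_velocity_projections(self, second, expected):
        t = ga_traj([(40, 0), second])
        assert radial_velocity(t)[0] == pytest.approx(expected)

    def test_radial_speed_bounded_by_speed(self, random_walk_traj):
        vr = np.abs(radial_velocity(random_walk_traj))
        v = step_velocities(random_walk_traj)
        assert np.all(vr <= np.hypot(v[:, 0], v[:, 1]) + 1e-12)


class TestDirectionality:
    def test_straight_track_is_one(self):
        assert np.allclose(directionality(linear_traj(n=10)), 1.0)

    def test_out_and_back_endpoint_zero(self):
        t = make_traj([(0, 0), (5, 0), (0, 0)])
        assert directionality(t)[-1] == pytest.approx(0.0)

    def test_two_orthogonal_steps(self):
        t = make_traj([(0, 0), (1, 0), (1, 1)])
        assert directionality(t)[-1] == pytest.approx(np.sqrt(2) / 2)

    def test_bounded_unit_interval(self, random_walk_traj):
        d = directionality(random_walk_traj)
        assert np.all((d >= 0) & (d <= 1))


class TestBinnedMeanSeries:
    def test_constant_series_invariant(self):
        series = [(np.arange(1, 101.0), np.full(100, 3.5)) for _ in range(5)]
        out = binned_mean_series(series, bin_width=15, window=10)
        assert np.allclose(out.mean, 3.5)

    def test_window_one_fine_bins_is_plain_mean(self):
        t = np.array([1.0, 2.0, 3.0])
        series = [(t, np.array([1.0, 2.0, 3.0])), (t, np.array([3.0, 4.0, 5.0]))]
        out = binned_mean_series(series, bin_width=1.0, window=1)
        assert np.allclose(out.mean, [2.0, 3.0, 4.0])

    def test_alternating_series_cancels(self):
        t = np.arange(1, 301.0)
        series = [(t, np.resize([1.0, -1.0], 300))]
        out = binned_mean_series(series, bin_width=1.0, window=50)
        assert np.max(np.abs(out.mean)) < 0.05


class TestDirectionalityByDistance:
    def _radial_ensemble(self, speeds):
        tracks = tuple(
            ga_traj(
                [(40 + s * t, 0) for t in range(0, 80, 3)], dt=3.0, track_id=f"s{i}"
            )
            for i, s in enumerate(speeds)
        )
        return Ensemble(tracks, Assay.GA, spheroid_radius=40.0)

    def test_straight_radial_tracks_concentrate_at_one(self):
        ens = self._radial_ensemble([0.5, 1.0, 2.0])
        groups = directionality_by_distance(ens, t_eval=75.0)
        pooled = np.concatenate([v for v in groups.values() if len(v)])
        assert np.allclose(pooled, 1.0)

    def test_inward_track_lands_in_zero_bin(self):
        inward = ga_traj([(40 - 0.4 * 3 * k, 0) for k in range(26)], dt=3.0)
        ens = Ensemble((inward,), Assay.GA, spheroid_radius=40.0)
        groups = directionality_by_distance(ens, t_eval=75.0, half_width=40.0)
        assert len(groups[0.0]) == 1  # d_r(75) = -30 um is inside [-40, 40)

    def test_unbiased_walk_stratification_mechanics(self):
        """With a single (S, P) the stratifier's bins are coupled to
        directionality mechanically: D(t) = d_r(t)/path(t) and path lengths
        are narrowly distributed, so farther bins hold straighter tracks."""
        config = SimulationConfig(
            delta=0.0, P_mean=16.6, S_mean=1.15, assay=Assay.GFA,
            n_tracks=600, d_min=0.0, seed=11,
        )
        groups = directionality_by_distance(simulate_ensemble(config), t_eval=75.0)
        a, b = groups[0.0], groups[80.0]
        assert len(a) > 20 and len(b) > 20
        assert np.all((np.concatenate([a, b]) >= 0) & (np.concatenate([a, b]) <= 1))
        assert np.median(b) > np.median(a)
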
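"""MSD computation, Fürth fitting and parameter-distribution summaries."""

import numpy as np
import pytest
from scipy import stats

from spherotrack.msd import (
    FurthFit,
    MsdCurve,
    ensemble_msd,
    fit_furth,
    furth_msd,
    msd_fit_weights,
    summarize_ensemble,
    time_avg_msd,
    trajectory_speed,
)
from spherotrack.trackdata import Assay, Ensemble

from conftest import linear_traj, make_traj


def naive_time_avg_msd(positions):
    """Brute-force windowed msd, the oracle for the FFT implementation."""
    n = len(positions)
    out = []
    for k in range(1, n):
        d = positions[k:] - positions[:-k]
        out.append(np.mean(np.sum(d * d, axis=1)))
    return np.array(out)


class TestTimeAvgMsd:
    def test_ballistic_identity(self):
        t = linear_traj(v=(3, 4), n=20, dt=2.0)  # speed 5
        c = time_avg_msd(t)
        assert np.allclose(c.values, 25.0 * c.lags**2)

    def test_stationary_is_zero(self):
        c = time_avg_msd(make_traj([(2, 2)] * 8))
        assert np.allclose(c.values, 0.0)

    def test_hand_enumerated_windows(self):
        c = time_avg_msd(make_traj([(0, 0), (1, 0), (3, 0), (6, 0)]))
        assert np.allclose(c.values, [14 / 3, 17.0, 36.0])
        assert list(c.n_contributing) == [3, 2, 1]

    def test_matches_bruteforce_oracle(self, random_walk_traj):
        c = time_avg_msd(random_walk_traj)
        assert np.allclose(c.values, naive_time_avg_msd(random_walk_traj.positions))

    def test_max_lag_fraction_truncates(self, random_walk_traj):
        c = time_avg_msd(random_walk_traj, max_lag_fraction=0.5)
        assert len(c) == (random_walk_traj.n_points - 1) // 2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            time_avg_msd(linear_traj(n=2))


class TestEnsembleMsd:
    def test_identical_linear_tracks(self):
        tracks = tuple(linear_traj(v=(2, 0), n=10, track_id=f"t{i}") for i in range(4))
        c = ensemble_msd(Ensemble(tracks, Assay.GFA))
        assert np.allclose(c.values, 4.0 * c.lags**2)
        assert np.allclose(c.sem, 0.0)

    def test_mean_of_two_tracks(self):
        a = make_traj([(0, 0), (1, 0)])  # squared displacement 1
        b = make_traj([(0, 0), (np.sqrt(3), 0)], track_id="b")  # 3
        c = ensemble_msd(Ensemble((a, b), Assay.GFA))
        assert c.values[0] == pytest.approx(2.0)
        assert c.n_contributing[0] == 2

    def test_ragged_lengths_tracked_in_counts(self):
        a = linear_traj(n=5)
        b = linear_traj(n=3, track_id="b")
        c = ensemble_msd(Ensemble((a, b), Assay.GFA))
        assert list(c.n_contributing) == [2, 2, 1, 1]
        assert np.isnan(c.sem[2])  # single-track lags flagged

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_msd(Ensemble((), Assay.GFA))


class TestFurthFormula:
    def test_closed_form_value(self):
        assert furth_msd(1, 1, 1) == pytest.approx(2 * np.exp(-1))

    def test_zero_at_zero_lag(self):
        assert furth_msd(2.0, 5.0, 0.0) == 0.0

    def test_ballistic_limit(self):
        assert furth_msd(1, 1, 0.01) == pytest.approx(9.9667e-5, rel=1e-4)

    def test_diffusive_asymptote(self):
        S, P = 1.3, 7.0
        tau = 100 * P
        assert furth_msd(S, P, tau) == pytest.approx(2 * S**2 * P * (tau - P), rel=0.01)

    @pytest.mark.parametrize("S,P", [(0, 1), (-1, 1), (1, 0)])
    def test_nonpositive_parameters_rejected(self, S, P):
        with pytest.raises(ValueError):
            furth_msd(S, P, 1.0)


class TestFitWeights:
    def _curve(self, values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        return MsdCurve(np.arange(1.0, n + 1), values, np.full(n, 5), "time_averaged")

    def test_first_point_weight_is_msd_over_A_squared(self):
        for A in (4, 7, 10):
            w = msd_fit_weights(self._curve(np.full(10, 50.0)), A)
            assert w[0] == pytest.approx(50.0 / A**2)

    def test_last_point_factor(self):
        A = 6
        w = msd_fit_weights(self._curve(np.ones(6)), A)
        assert w[-1] == pytest.approx(((2 * A**2 + 1) / (3 * A)) ** 2)

    def test_derived_example(self):
        w = msd_fit_weights(self._curve(np.full(10, 100.0)), 10)
        assert w[0] == pytest.approx(1.0)

    def test_bad_A_rejected(self):
        with pytest.raises(ValueError):
            msd_fit_weights(self._curve(np.ones(5)), 6)


class TestFitFurth:
    def _noiseless_curve(self, S, P, dt=0.5, n=200):
        lags = dt * np.arange(1, n + 1)
        return MsdCurve(lags, furth_msd(S, P, lags), np.full(n, 100), "time_averaged")

    @pytest.mark.parametrize("S,P", [(1.5, 20.0), (0.3, 5.0), (4.0, 80.0)])
    def test_noiseless_round_trip(self, S, P):
        fit = fit_furth(self._noiseless_curve(S, P))
        assert fit.accepted
        assert fit.S == pytest.approx(S, rel=1e-6)
        assert fit.P == pytest.approx(P, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_fit_uses_quarter_of_lags(self):
        fit = fit_furth(self._noiseless_curve(1, 10, n=200))
        assert fit.A == 50

    def test_ballistic_curve_flagged(self):
        lags = np.arange(1.0, 41)
        curve = MsdCurve(lags, (2.0 * lags) ** 2, np.full(40, 10), "time_averaged")
        fit = fit_furth(curve)
        assert not fit.accepted  # persistence pinned at its upper bound

    def test_short_curve_rejected(self):
        c = self._noiseless_curve(1, 5, n=3)
        with pytest.raises(ValueError, match="at least 4"):
            fit_furth(c)


class TestTrajectorySpeed:
    def test_uniform_motion_both_modes(self):
        t = linear_traj(v=(0, 2), n=6)
        assert trajectory_speed(t, "mean_speed") == pytest.approx(2.0)
        assert trajectory_speed(t, "mean_vector_magnitude") == pytest.approx(2.0)

    def test_closed_loop(self):
        square = make_traj([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert trajectory_speed(square, "mean_vector_magnitude") == pytest.approx(0.0)
        assert trajectory_speed(square, "mean_speed") == pytest.approx(1.0)

    def test_two_orthogonal_steps(self):
        t = make_traj([(0, 0), (1, 0), (1, 1)])
        assert trajectory_speed(t, "mean_vector_magnitude") == pytest.approx(np.sqrt(2) / 2)
        assert trajectory_speed(t, "mean_speed") == pytest.approx(1.0)


class TestSummarizeEnsemble:
    def _fit(self, S, P):
        return FurthFit(S, P, 0.999, 10, True)

    def test_identical_persistence(self):
        s = summarize_ensemble([self._fit(1.0, 12.0)] * 12)
        assert s.mean_P == pytest.approx(12.0)
        assert s.sd_log_P == pytest.approx(0.0)

    def test_gaussian_speed_recovery(self, rng):
        S = rng.normal(1.5, 0.1, size=1000)
        s = summarize_ensemble([self._fit(x, 10.0) for x in S])
        assert s.mean_S == pytest.approx(1.5, abs=0.01)
        assert s.ks_normality_p > 0.05

    def test_lognormal_persistence_recovery(self, rng):
        P = np.exp(rng.normal(np.log(16.6), 0.4, size=1000))
        s = summarize_ensemble([self._fit(1.0, p) for p in P])
        assert s.mean_P == pytest.approx(16.6, rel=0.05)

    def test_refuses_too_few_accepted(self):
        fits = [self._fit(1, 10)] * 5 + [FurthFit(1, 10, 0.5, 10, False)] * 20
        with pytest.raises(ValueError, match="5 accepted"):
            summarize_ensemble(fits)
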
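"""Mean-squared displacement analysis and Fürth-formula fitting.

The persistent random walk (PRW) predicts a closed-form MSD (Fürth's
formula)

    MSD(tau) = 2 S^2 P^2 (exp(-tau/P) + tau/P - 1),

with speed ``S`` (um/min) and persistence time ``P`` (min). Each track's
time-averaged msd curve is fitted by weighted nonlinear least squares to
recover a per-cell (S, P); the ensemble-averaged MSD can be fitted the same
way. Because long-lag msd points average few displacement windows, the fit
down-weights them with the variance model ``W(a)``; only the first 25% of
lag points enter the fit by default and fits with weighted R^2 below 0.99
are rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .trackdata import Ensemble, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "MsdCurve",
    "FurthFit",
    "EnsembleSummary",
    "time_avg_msd",
    "ensemble_msd",
    "furth_msd",
    "msd_fit_weights",
    "fit_furth",
    "trajectory_speed",
    "summarize_ensemble",
]


@dataclass(frozen=True)
class MsdCurve:
    """MSD values per lag time.

    ``kind`` is ``"time_averaged"`` (one track, overlapping windows) or
    ``"ensemble"`` (mean over tracks of the squared displacement from the
    start). ``sem`` is only populated for ensemble curves.
    """

    lags: np.ndarray  # minutes, strictly increasing, starting at one frame
    values: np.ndarray  # um^2
    n_contributing: np.ndarray
    kind: str
    sem: np.ndarray | None = None

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        n = np.asarray(self.n_contributing, dtype=int)
        if not (len(lags) == len(values) == len(n)):
            raise ValueError("lags, values, n_contributing must have equal length")
        if np.any(np.diff(lags) <= 0) or lags[0] <= 0:
            raise ValueError("lags must be positive and strictly increasing")
        if np.any(values < -1e-12):
            raise ValueError("msd values must be non-negative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_contributing", n)

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class FurthFit:
    """Result of fitting Fürth's formula to an msd curve."""

    S: float  # um/min
    P: float  # min
    r_squared: float
    A: int  # number of lag points used
    accepted: bool
    message: str = ""


@dataclass(frozen=True)
class EnsembleSummary:
    """Distribution summaries of per-track fitted parameters.

    ``mean_P`` is the location of a log-Gaussian fit to the persistence
    times (back-transformed to minutes); ``mean_S``/``sd_S`` come from a
    Gaussian fit to the speeds; ``ks_normality_p`` is the p-value of a
    Kolmogorov-Smirnov test of the speeds against that Gaussian.
    """

    mean_P: float
    sd_log_P: float
    mean_S: float
    sd_S: float
    ks_normality_p: float
    n_accepted: int
    n_total: int


# ---------------------------------------------------------------------------
# MSD computation
# ---------------------------------------------------------------------------


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    n = len(x)
    f = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(f * f.conjugate(), n=2 * n)[:n]
    return acf


def _msd_windowed(positions: np.ndarray) -> np.ndarray:
    """Time-averaged msd over overlapping windows for lags 1..n-1.

    FFT-based O(n log n) evaluation of
    msd(k) = mean_i |x_{i+k} - x_i|^2.
    """
    n = len(positions)
    d2 = np.einsum("ij,ij->i", positions, positions)
    s2 = sum(_autocorr_fft(positions[:, dim]) for dim in range(2))
    d2pad = np.append(d2, 0.0)
    q = 2.0 * d2.sum()
    s1 = np.empty(n)
    for m in range(n):
        q -= d2pad[m - 1] + d2pad[n - m]
        s1[m] = q
    counts = n - np.arange(n)
    msd = (s1 - 2.0 * s2) / counts
    return np.maximum(msd[1:], 0.0)  # clip FFT round-off at tiny lags


def time_avg_msd(trajectory: Trajectory, max_lag_fraction: float = 1.0) -> MsdCurve:
    """Time-averaged msd of one track over all overlapping windows.

    For each lag ``tau = k * frame_interval`` up to ``max_lag_fraction`` of
    the track duration, averages ``|x(t_i + tau) - x(t_i)|^2`` over every
    start index ``i``.
    """
    if trajectory.n_points < 3:
        raise ValueError(f"track {trajectory.track_id}: too short for msd (need >= 3 points)")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = trajectory.n_points
    k_max = max(1, int(math.floor(max_lag_fraction * (n - 1))))
    msd = _msd_windowed(trajectory.positions)[:k_max]
    lags = trajectory.frame_interval * np.arange(1, k_max + 1)
    counts = n - np.arange(1, k_max + 1)
    return MsdCurve(lags, msd, counts, kind="time_averaged")


def ensemble_msd(ensemble: Ensemble) -> MsdCurve:
    """Ensemble-averaged MSD: mean over tracks of |x(tau) - x(0)|^2.

    Tracks are aligned on their own first sample. All tracks must share a
    frame interval; the curve extends to the longest track, with per-lag
    ``sem`` (sample SD over contributing tracks / sqrt(n)) and contributing
    counts recorded. Lags with fewer than two tracks have ``sem`` = NaN.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble_msd: empty ensemble")
    intervals = {round(t.frame_interval, 9) for t in ensemble}
    if len(intervals) > 1:
        raise ValueError(f"mixed frame intervals in ensemble: {sorted(intervals)}")
    dt = next(iter(intervals))
    k_max = max(t.n_points - 1 for t in ensemble)
    sums = np.zeros(k_max)
    sq_sums = np.zeros(k_max)
    counts = np.zeros(k_max, dtype=int)
    for traj in ensemble:
        rel = traj.positions[1:] - traj.positions[0]
        sq = np.einsum("ij,ij->i", rel, rel)
        m = len(sq)
        sums[:m] += sq
        sq_sums[:m] += sq**2
        counts[:m] += 1
    mean = sums / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sq_sums - counts * mean**2) / (counts - 1)
        sem = np.sqrt(np.maximum(var, 0.0) / counts)
    sem[counts < 2] = np.nan
    lags = dt * np.arange(1, k_max + 1)
    return MsdCurve(lags, mean, counts, kind="ensemble", sem=sem)


def furth_msd(S: float, P: float, tau) -> np.ndarray | float:
    """Fürth's formula MSD(tau) = 2 S^2 P^2 (exp(-tau/P) + tau/P - 1)."""
    if S <= 0 or P <= 0:
        raise ValueError("S and P must be positive")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    u = tau / P
    # expm1 keeps the tau << P (ballistic) limit accurate
    val = 2.0 * S**2 * P**2 * (np.expm1(-u) + u)
    return val if val.ndim else float(val)


# ---------------------------------------------------------------------------
# Weighted fitting
# ---------------------------------------------------------------------------


def msd_fit_weights(curve: MsdCurve, A: int) -> np.ndarray:
    """Variance weights W(a) = MSD(tau_a) ((2a^2+1) / (3a(A-a+1)))^2, a = 1..A.

    Least-squares residuals at point ``a`` are weighted by 1/W(a): long-lag
    points, averaged over few windows, count less. Points with zero msd get
    zero fit weight (W = inf internally) and are logged.
    """
    if not 1 <= A <= len(curve):
        raise ValueError(f"A={A} outside 1..{len(curve)}")
    a = np.arange(1, A + 1, dtype=float)
    factor = ((2.0 * a**2 + 1.0) / (3.0 * a * (A - a + 1.0))) ** 2
    w = curve.values[:A] * factor
    n_zero = int(np.sum(w == 0))
    if n_zero:
        logger.info("msd_fit_weights: %d zero-msd points excluded from fit", n_zero)
    return w


def _fit_bounds(curve: MsdCurve) -> tuple[tuple[float, float], tuple[float, float]]:
    dt = curve.lags[0]
    return (1e-6, 100.0), (dt / 10.0, 10.0 * curve.lags[-1])


def _initial_guess(curve: MsdCurve) -> tuple[float, float]:
    dt = curve.lags[0]
    s0 = math.sqrt(max(curve.values[0], 1e-12)) / dt
    # lag where msd falls to half its ballistic extrapolation ~ persistence
    ballistic = curve.values[0] * (curve.lags / dt) ** 2
    below = np.nonzero(curve.values < 0.5 * ballistic)[0]
    p0 = curve.lags[below[0]] if len(below) else curve.lags[-1]
    return s0, float(p0)


def fit_furth(
    curve: MsdCurve,
    max_fit_fraction: float = 0.25,
    r2_min: float = 0.99,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> FurthFit:
    """Weighted nonlinear least-squares fit of Fürth's formula to an msd curve.

    Fits the first ``A = ceil(max_fit_fraction * len(curve))`` lag points
    (minimum 4) with residuals scaled by 1/sqrt(W(a)). The weighted
    coefficient of determination is computed on the same points with the
    same weights; fits with R^2 <= ``r2_min`` or with a parameter pinned at
    its bound are flagged not accepted. Non-convergence is reported through
    ``accepted``/``message``, never as an exception.
    """
    if len(curve) < 4:
        raise ValueError("fit_furth: need at least 4 lag points")
    A = max(4, math.ceil(max_fit_fraction * len(curve)))
    A = min(A, len(curve))
    w_var = msd_fit_weights(curve, A)
    y = curve.values[:A]
    tau = curve.lags[:A]
    good = w_var > 0
    if good.sum() < 4:
        return FurthFit(np.nan, np.nan, 0.0, A, False, "fewer than 4 usable points")
    inv_sd = np.zeros(A)
    inv_sd[good] = 1.0 / np.sqrt(w_var[good])

    (s_lo, s_hi), (p_lo, p_hi) = _fit_bounds(curve)

    def residuals(theta):
        s, p = theta
        return (furth_msd(s, p, tau) - y) * inv_sd

    s0, p0 = _initial_guess(curve)
    rng = rng or np.random.default_rng(0)
    best = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            x0 = (s0, p0)
        else:
            x0 = (s0 * rng.uniform(0.3, 3.0), p0 * rng.uniform(0.3, 3.0))
        x0 = (min(max(x0[0], s_lo * 1.01), s_hi * 0.99),
              min(max(x0[1], p_lo * 1.01), p_hi * 0.99))
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=([s_lo, p_lo], [s_hi, p_hi]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            logger.warning("fit_furth: optimizer error: %s", exc)
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return FurthFit(np.nan, np.nan, 0.0, A, False, "optimizer did not converge")

    s_fit, p_fit = best.x
    w = inv_sd**2
    y_bar = np.sum(w * y) / np.sum(w)
    ss_res = float(np.sum(w * (y - furth_msd(s_fit, p_fit, tau)) ** 2))
    ss_tot = float(np.sum(w * (y - y_bar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)

    at_bound = (
        p_fit >= p_hi * (1 - 1e-6) or p_fit <= p_lo * (1 + 1e-6)
        or s_fit >= s_hi * (1 - 1e-6)
    )
    msg = "parameter at bound" if at_bound else ""
    accepted = (r2 > r2_min) and not at_bound
    return FurthFit(float(s_fit), float(p_fit), float(r2), A, accepted, msg)


def trajectory_speed(trajectory: Trajectory, mode: str = "mean_speed") -> float:
    """Track speed in um/min.

    ``mean_speed`` (default) averages per-step speed magnitudes;
    ``mean_vector_magnitude`` is the magnitude of the time-averaged velocity
    vector, i.e. the net displacement over the duration. The two agree only
    for straight motion, so reports emit both.
    """
    v = trajectory.steps / trajectory.frame_interval
    if mode == "mean_vector_magnitude":
        return float(np.hypot(*v.mean(axis=0)))
    if mode == "mean_speed":
        return float(np.mean(np.hypot(v[:, 0], v[:, 1])))
    raise ValueError(f"unknown speed mode: {mode!r}")


def summarize_ensemble(fits: Iterable[FurthFit], min_accepted: int = 10) -> EnsembleSummary:
    """Distribution summary of accepted per-track Fürth fits.

    Persistence times are summarized by a log-Gaussian fit (reported as the
    back-transformed location, i.e. the geometric mean, and the SD of log
    values); speeds by a Gaussian fit, with a KS test of normality.
    """
    fits = list(fits)
    acc = [f for f in fits if f.accepted]
    if len(acc) < min_accepted:
        raise ValueError(
            f"summarize_ensemble: only {len(acc)} accepted fits (need >= {min_accepted})"
        )
    P = np.array([f.P for f in acc])
    S = np.array([f.S for f in acc])
    log_p = np.log(P)
    mean_P = float(np.exp(log_p.mean()))
    sd_log_P = float(log_p.std(ddof=1)) if len(acc) > 1 else 0.0
    mean_S = float(S.mean())
    sd_S = float(S.std(ddof=1)) if len(acc) > 1 else 0.0
    if sd_S > 0:
        ks_p = float(stats.kstest(S, "norm", args=(mean_S, sd_S)).pvalue)
    else:
        ks_p = 1.0
    return EnsembleSummary(mean_P, sd_log_P, mean_S, sd_S, ks_p, len(acc), len(fits))
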
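"""Direction- and radius-referenced trajectory statistics.

For each track the major axis of motion ``m`` (mean step vector) is compared
with a reference radial vector ``r``: in the spheroid assay (GA) the vector
from the spheroid centre to the track's start, in the gradient-free assay
(GFA) the first step of the track. Derived quantities are the angle ``phi``
between ``m`` and ``r``, the signed radial distance ``d_r(t)``, the
directionality ratio ``D(t)`` (net displacement over path length, in [0, 1])
and the radial velocity ``v_r(t)`` (projection of the step velocity on the
unit radial vector). Angles are reported in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trackdata import Assay, Ensemble, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "KinematicsResult",
    "AngularDisplacementDistribution",
    "BinnedSeries",
    "DegenerateGeometryError",
    "step_velocities",
    "angular_displacement",
    "major_axis",
    "radial_vector",
    "phi_angle",
    "radial_distance",
    "directionality",
    "radial_velocity",
    "compute_kinematics",
    "binned_mean_series",
    "directionality_by_distance",
]


class DegenerateGeometryError(ValueError):
    """A zero-magnitude reference vector makes an angle/projection undefined."""


@dataclass(frozen=True)
class KinematicsResult:
    """Per-track direction statistics (angles in degrees, lengths in um)."""

    track_id: str
    major_axis: np.ndarray
    radial_vector: np.ndarray
    phi: float
    d_r: np.ndarray  # per time point, including t=0
    directionality: np.ndarray  # from the first step onward
    v_r: np.ndarray  # per step


@dataclass(frozen=True)
class AngularDisplacementDistribution:
    """Angles theta(tau) between velocity pairs separated by lag tau."""

    tau: float
    angles: np.ndarray  # degrees in [0, 180]
    n_skipped: int  # pairs dropped because a velocity was zero


@dataclass(frozen=True)
class BinnedSeries:
    """Time-binned, moving-average-smoothed ensemble mean of a time series."""

    time: np.ndarray  # bin centres, minutes
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray


def step_velocities(trajectory: Trajectory) -> np.ndarray:
    """Step velocities v(t_i) = (x(t_i) - x(t_{i-1})) / dt, shape (n-1, 2)."""
    return trajectory.steps / trajectory.frame_interval


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.hypot(*u), np.hypot(*v)
    c = np.dot(u, v) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angular_displacement(trajectory: Trajectory, tau: float) -> AngularDisplacementDistribution:
    """Angles between velocity vectors separated by the lag ``tau``.

    ``tau`` must be a multiple of the frame interval. Pairs where either
    velocity is zero are skipped and counted.
    """
    dt = trajectory.frame_interval
    k = int(round(tau / dt))
    if k < 1 or abs(tau / dt - k) > 1e-9:
        raise ValueError(f"tau={tau} is not a positive multiple of the frame interval {dt}")
    v = step_velocities(trajectory)
    if len(v) <= k:
        raise ValueError(f"track {trajectory.track_id}: too short for lag {tau} min")
    v1, v2 = v[:-k], v[k:]
    n1 = np.hypot(v1[:, 0], v1[:, 1])
    n2 = np.hypot(v2[:, 0], v2[:, 1])
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return AngularDisplacementDistribution(float(tau), angles, int((~ok).sum()))


def major_axis(trajectory: Trajectory) -> np.ndarray:
    """Mean step displacement vector m = <x(t_i) - x(t_{i-1})>_t."""
    return trajectory.steps.mean(axis=0)


def radial_vector(trajectory: Trajectory, assay: Assay | str | None = None) -> np.ndarray:
    """Reference radial vector r.

    GA: the start position (the spheroid centre is the origin);
    GFA: the first step displacement. A zero-magnitude result raises
    :class:`DegenerateGeometryError` so callers can exclude the track.
    """
    assay = Assay(assay) if assay is not None else trajectory.assay
    if assay is Assay.GA:
        r = trajectory.positions[0].copy()
    else:
        r = trajectory.positions[1] - trajectory.positions[0]
    if np.hypot(*r) == 0:
        raise DegenerateGeometryError(
            f"track {trajectory.track_id}: zero radial vector ({assay.value})"
        )
    return r


def phi_angle(trajectory: Trajectory, assay: Assay | str | None = None) -> float:
    """Unsigned angle (degrees, [0, 180]) between the major axis and r."""
    m = major_axis(trajectory)
    if np.hypot(*m) == 0:
        raise DegenerateGeometryError(
            f"track {trajectory.track_id}: zero major axis (closed loop)"
        )
    return _angle_between_deg(m, radial_vector(trajectory, assay))


def radial_distance(trajectory: Trajectory, assay: Assay | str | None = None) -> np.ndarray:
    """Radial distance series d_r(t_i).

    GA: |x(t_i)| - |x(0)| (signed, negative when the cell moves inward);
    GFA: |x(t_i) - x(0)| (always >= 0).
    """
    assay = Assay(assay) if assay is not None else trajectory.assay
    pos = trajectory.positions
    if assay is Assay.GA:
        return np.hypot(pos[:, 0], pos[:, 1]) - np.hypot(*pos[0])
    rel = pos - pos[0]
    return np.hypot(rel[:, 0], rel[:, 1])


def directionality(trajectory: Trajectory) -> np.ndarray:
    """Directionality ratio D(t_i) = |x(t_i) - x(0)| / path length up to t_i.

    Defined from the first step onward (length n-1); 1 for straight motion,
    tending to 0 for tortuous paths.
    """
    rel = trajectory.positions[1:] - trajectory.positions[0]
    net = np.hypot(rel[:, 0], rel[:, 1])
    seg = np.hypot(trajectory.steps[:, 0], trajectory.steps[:, 1])
    path = np.cumsum(seg)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(path > 0, net / path, 0.0)
    return np.clip(d, 0.0, 1.0)


def radial_velocity(trajectory: Trajectory, assay: Assay | str | None = None) -> np.ndarray:
    """Signed projection v_r(t_i) = v(t_i) . r/|r| of each step velocity."""
    r = radial_vector(trajectory, assay)
    r_hat = r / np.hypot(*r)
    return step_velocities(trajectory) @ r_hat


def compute_kinematics(trajectory: Trajectory, assay: Assay | str | None = None) -> KinematicsResult:
    """All per-track direction statistics in one pass."""
    return KinematicsResult(
        track_id=trajectory.track_id,
        major_axis=major_axis(trajectory),
        radial_vector=radial_vector(trajectory, assay),
        phi=phi_angle(trajectory, assay),
        d_r=radial_distance(trajectory, assay),
        directionality=directionality(trajectory),
        v_r=radial_velocity(trajectory, assay),
    )


# ---------------------------------------------------------------------------
# Ensemble summaries
# ---------------------------------------------------------------------------


def binned_mean_series(
    series_collection,
    bin_width: float = 15.0,
    window: int = 10,
) -> BinnedSeries:
    """Ensemble mean of per-track time series, binned and smoothed.

    ``series_collection`` is a sequence of ``(times, values)`` pairs, each
    track on its own relative clock. The pointwise ensemble mean is taken at
    every distinct sample time, aggregated into ``bin_width``-minute bins
    (labelled by bin centre), then smoothed by a centred moving average of
    ``window`` bins, truncated at the edges.
    """
    series_collection = list(series_collection)
    if not series_collection:
        raise ValueError("binned_mean_series: empty collection")
    all_t = np.concatenate([np.asarray(t, dtype=float) for t, _ in series_collection])
    all_v = np.concatenate([np.asarray(v, dtype=float) for _, v in series_collection])
    # pointwise ensemble mean over tracks alive at each distinct time
    times, inv = np.unique(np.round(all_t, 9), return_inverse=True)
    sums = np.bincount(inv, weights=all_v)
    counts = np.bincount(inv)
    point_mean = sums / counts

    bins = np.floor(times / bin_width).astype(int)
    uniq, binv = np.unique(bins, return_inverse=True)
    bin_mean = np.bincount(binv, weights=point_mean) / np.bincount(binv)
    bin_n = np.bincount(binv, weights=counts).astype(int)
    # spread of the pointwise means inside each bin
    bin_sq = np.bincount(binv, weights=point_mean**2) / np.bincount(binv)
    with np.errstate(invalid="ignore"):
        bin_sem = np.sqrt(np.maximum(bin_sq - bin_mean**2, 0.0) / np.bincount(binv))
    centers = (uniq + 0.5) * bin_width

    if window > 1:
        kernel = np.ones(window)
        smooth = np.convolve(bin_mean, kernel, mode="same") / np.convolve(
            np.ones_like(bin_mean), kernel, mode="same"
        )
    else:
        smooth = bin_mean
    return BinnedSeries(centers, smooth, bin_sem, bin_n)


def directionality_by_distance(
    ensemble: Ensemble,
    t_eval: float = 75.0,
    centers=(0.0, 80.0, 160.0),
    half_width: float = 40.0,
) -> dict[float, np.ndarray]:
    """Distributions of D(t_eval) stratified by radial distance d_r(t_eval).

    Tracks long enough to reach ``t_eval`` are grouped by whether
    ``d_r(t_eval)`` falls in ``[center - half_width, center + half_width)``;
    the directionality values per group are returned (possibly empty).
    """
    out: dict[float, list[float]] = {float(c): [] for c in centers}
    for traj in ensemble:
        idx = int(round(t_eval / traj.frame_interval))
        if abs(idx * traj.frame_interval - t_eval) > 1e-6 or idx >= traj.n_points:
            continue
        if idx < 1:
            continue
        d_r = radial_distance(traj)[idx]
        d_val = directionality(traj)[idx - 1]
        for c in centers:
            if c - half_width <= d_r < c + half_width:
                out[float(c)].append(d_val)
    return {c: np.asarray(v) for c, v in out.items()}
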
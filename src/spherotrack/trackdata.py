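"""Trajectory data model, CSV I/O and track-level filters.

Positions are 2D Cartesian coordinates in micrometres, times in minutes.
For spheroid (GA) ensembles the spheroid centre is fixed at the origin;
tracks recorded in another frame are translated at load time.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Assay",
    "Trajectory",
    "Ensemble",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "filter_min_displacement",
    "resample",
]

#: absolute tolerance (min) on deviations from uniform frame spacing
_SPACING_TOL = 1e-9


class Assay(str, enum.Enum):
    """Assay geometry: spheroid gradient assay or gradient-free assay."""

    GA = "GA"
    GFA = "GFA"


class TrackFormatError(ValueError):
    """Raised for malformed trajectory files."""


@dataclass(frozen=True)
class Trajectory:
    """One cell's 2D track: positions ``x(t_i)`` sampled at uniform intervals.

    Parameters
    ----------
    track_id : str
        Identifier unique within an ensemble.
    times : array, minutes
        Strictly increasing, uniformly spaced sample times. By convention
        ``times[0]`` is the track's own t = 0.
    positions : array of shape (n, 2), micrometres
        Cell centre-of-mass coordinates.
    assay : Assay
        Geometry the track was recorded in.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    assay: Assay

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError(f"track {self.track_id}: need >= 2 time points")
        if positions.shape != (len(times), 2):
            raise ValueError(
                f"track {self.track_id}: positions shape {positions.shape} "
                f"does not match {len(times)} times"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(positions))):
            raise ValueError(f"track {self.track_id}: non-finite coordinates")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError(f"track {self.track_id}: times not strictly increasing")
        tol = max(_SPACING_TOL, _SPACING_TOL * dt[0])
        if np.max(np.abs(dt - dt[0])) > tol:
            raise ValueError(f"track {self.track_id}: non-uniform sampling")
        times.setflags(write=False)
        positions.setflags(write=False)

    @property
    def frame_interval(self) -> float:
        """Sampling interval in minutes."""
        return float(self.times[1] - self.times[0])

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Track duration in minutes (relative to its first point)."""
        return float(self.times[-1] - self.times[0])

    @property
    def steps(self) -> np.ndarray:
        """Step displacement vectors dx(t_i) = x(t_i) - x(t_{i-1}), shape (n-1, 2)."""
        return np.diff(self.positions, axis=0)

    def displacement(self, criterion: str = "max_from_start") -> float:
        """Scalar displacement summary used by the immobile-cell filter.

        ``max_from_start``: max_i |x(t_i) - x(0)|; ``net``: |x(t_n) - x(0)|;
        ``path_length``: total contour length.
        """
        rel = self.positions - self.positions[0]
        if criterion == "max_from_start":
            return float(np.max(np.hypot(rel[:, 0], rel[:, 1])))
        if criterion == "net":
            return float(np.hypot(*rel[-1]))
        if criterion == "path_length":
            seg = np.diff(self.positions, axis=0)
            return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
        raise ValueError(f"unknown displacement criterion: {criterion!r}")


@dataclass(frozen=True)
class Ensemble:
    """A collection of trajectories recorded in one assay geometry.

    GA ensembles carry the spheroid radius (``R0``, micrometres); the spheroid
    centre is the coordinate origin.
    """

    trajectories: tuple[Trajectory, ...]
    assay: Assay
    spheroid_center: tuple[float, float] = (0.0, 0.0)
    spheroid_radius: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        for t in self.trajectories:
            if t.assay != self.assay:
                raise ValueError(
                    f"track {t.track_id} assay {t.assay} != ensemble assay {self.assay}"
                )
        if self.assay is Assay.GA:
            if self.spheroid_radius is None or self.spheroid_radius <= 0:
                raise ValueError("GA ensembles require a positive spheroid_radius")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

# canonical column -> accepted (lower-cased) aliases
_ALIASES = {
    "track": ("track_id", "track", "trackid", "id"),
    "x": ("position_x", "x"),
    "y": ("position_y", "y"),
    "t": ("position_t", "t", "time"),
    "frame": ("frame",),
}


def _map_columns(columns: Iterable[str]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    out = {}
    for canon, aliases in _ALIASES.items():
        for a in aliases:
            if a in lower:
                out[canon] = lower[a]
                break
    return out


def read_tracks(
    path: str | Path,
    dialect: str = "auto",
    *,
    assay: Assay | str = Assay.GFA,
    frame_interval: float | None = None,
    spheroid_center: tuple[float, float] | None = None,
    spheroid_radius: float | None = None,
) -> Ensemble:
    """Read a trajectory CSV into an :class:`Ensemble`.

    Accepts TrackMate-export column names (``TRACK_ID, POSITION_X, POSITION_Y,
    POSITION_T`` or ``FRAME``) case-insensitively, as well as a plain
    ``track,x,y,t`` dialect. When only a ``FRAME`` column is present,
    ``frame_interval`` (minutes) is required to build times.

    If ``spheroid_center`` is given, positions are translated so the spheroid
    centre sits at the origin. Each track's clock is reset to its first sample.
    """
    assay = Assay(assay)
    df = pd.read_csv(path)
    if dialect not in ("auto", "trackmate", "plain"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    cols = _map_columns(df.columns)
    for needed in ("track", "x", "y"):
        if needed not in cols:
            raise TrackFormatError(
                f"{path}: missing required column {needed!r} "
                f"(accepted names: {_ALIASES[needed]})"
            )
    if "t" in cols:
        df["_t"] = df[cols["t"]].astype(float)
    elif "frame" in cols:
        if frame_interval is None:
            raise TrackFormatError(
                f"{path}: FRAME column requires an explicit frame_interval"
            )
        df["_t"] = df[cols["frame"]].astype(float) * float(frame_interval)
    else:
        raise TrackFormatError(
            f"{path}: missing required column 't' "
            "(accepted names: POSITION_T, t, time, or FRAME + frame_interval)"
        )

    offset = np.zeros(2)
    if spheroid_center is not None:
        offset = np.asarray(spheroid_center, dtype=float)

    trajectories = []
    bad: list[str] = []
    for track_id, grp in df.groupby(cols["track"], sort=True):
        grp = grp.sort_values("_t")
        times = grp["_t"].to_numpy(dtype=float)
        pos = grp[[cols["x"], cols["y"]]].to_numpy(dtype=float) - offset
        try:
            trajectories.append(
                Trajectory(str(track_id), times - times[0], pos, assay)
            )
        except ValueError as exc:
            bad.append(str(track_id))
            logger.warning("rejecting track %s: %s", track_id, exc)
    if bad:
        raise TrackFormatError(
            f"{path}: non-uniform or invalid sampling in tracks: {', '.join(bad)}"
        )
    return Ensemble(
        tuple(trajectories),
        assay,
        spheroid_radius=spheroid_radius,
    )


def write_tracks(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as CSV with header TRACK_ID,POSITION_X,POSITION_Y,POSITION_T.

    Rows are ordered by track id then time, so repeated writes are
    byte-identical.
    """
    rows = []
    for traj in sorted(ensemble, key=lambda t: t.track_id):
        for t, (x, y) in zip(traj.times, traj.positions):
            rows.append((traj.track_id, x, y, t))
    df = pd.DataFrame(rows, columns=["TRACK_ID", "POSITION_X", "POSITION_Y", "POSITION_T"])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters and resampling
# ---------------------------------------------------------------------------


def filter_min_displacement(
    ensemble: Ensemble,
    d_min: float = 50.0,
    criterion: str = "max_from_start",
) -> Ensemble:
    """Drop immobile/dead-cell tracks moving less than ``d_min`` micrometres.

    A track is retained when its displacement summary (default: the maximum
    distance from the start position reached anywhere along the track) is at
    least ``d_min``. The input ensemble is left untouched.
    """
    if d_min < 0:
        raise ValueError("d_min must be >= 0")
    kept = tuple(
        t for t in ensemble.trajectories if t.displacement(criterion) >= d_min
    )
    logger.info(
        "min-displacement filter (%s >= %g um): kept %d / %d tracks",
        criterion, d_min, len(kept), len(ensemble),
    )
    return replace(ensemble, trajectories=kept)


def resample(trajectory: Trajectory, interval: float) -> Trajectory:
    """Down-sample a track to a coarser frame interval.

    ``interval`` must be an integer multiple of the source interval; every
    k-th sample is kept, starting from the first.
    """
    src = trajectory.frame_interval
    ratio = interval / src
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"interval {interval} is not an integer multiple of the "
            f"source frame interval {src}"
        )
    if k == 1:
        return trajectory
    if (trajectory.n_points - 1) // k + 1 < 2:
        raise ValueError(
            f"resampling at {interval} min leaves fewer than 2 points"
        )
    return replace(
        trajectory,
        times=trajectory.times[::k].copy(),
        positions=trajectory.positions[::k].copy(),
    )
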
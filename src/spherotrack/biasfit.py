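"""Grid-search estimation of the bias responsiveness ``delta``.

The spheroid drift amplitude is inferred by matching the ensemble-averaged
radial-velocity curve <v_r(t)> of a reference ensemble (tracked cells or a
simulation) against candidate BPRW simulations over a grid of ``delta``
values, scoring each candidate by the range-normalized root-mean-squared
error between the two binned curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .kinematics import BinnedSeries, binned_mean_series, radial_velocity
from .kinematics import DegenerateGeometryError
from .simulate import SimulationConfig, SimulationError, simulate_ensemble
from .trackdata import Ensemble

logger = logging.getLogger(__name__)

__all__ = ["BiasEstimate", "vr_reference_curve", "nrmse", "estimate_delta"]


@dataclass(frozen=True)
class BiasEstimate:
    """NRMSE profile over the delta grid and its arg-min."""

    grid: np.ndarray
    nrmse: np.ndarray
    best_delta: float
    n_reference: int
    n_sim_per_candidate: int


def vr_reference_curve(
    ensemble: Ensemble,
    bin_width: float = 15.0,
    window: int = 10,
    min_tracks: int = 10,
) -> BinnedSeries:
    """Ensemble-averaged radial velocity <v_r(t)>, binned and smoothed.

    Tracks whose radial vector is degenerate (start at the spheroid centre,
    or a zero first step) are excluded with a logged count.
    """
    series = []
    n_excluded = 0
    for traj in ensemble:
        try:
            vr = radial_velocity(traj)
        except DegenerateGeometryError:
            n_excluded += 1
            continue
        series.append((traj.times[1:], vr))
    if n_excluded:
        logger.info("vr_reference_curve: excluded %d degenerate tracks", n_excluded)
    if len(series) < min_tracks:
        raise ValueError(
            f"vr_reference_curve: only {len(series)} usable tracks (need >= {min_tracks})"
        )
    return binned_mean_series(series, bin_width=bin_width, window=window)


def nrmse(
    reference: BinnedSeries,
    candidate: BinnedSeries,
    normalization: str = "range",
    min_points: int = 5,
) -> float:
    """Normalized RMSE between two binned curves over their common times.

    The RMSE over common time points is divided by the reference curve's
    range (max - min); ``normalization="mean"`` divides by |mean| instead.
    A degenerate normalizer falls back to the plain RMSE with a warning.
    """
    _, ref_idx, cand_idx = np.intersect1d(
        np.round(reference.time, 6), np.round(candidate.time, 6), return_indices=True
    )
    if len(ref_idx) < min_points:
        raise ValueError(
            f"nrmse: only {len(ref_idx)} common time points (need >= {min_points})"
        )
    r = reference.mean[ref_idx]
    c = candidate.mean[cand_idx]
    rmse = float(np.sqrt(np.mean((r - c) ** 2)))
    if normalization == "range":
        denom = float(r.max() - r.min())
    elif normalization == "mean":
        denom = abs(float(r.mean()))
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    if denom <= 0:
        warnings.warn("nrmse: degenerate reference curve; returning unnormalized RMSE")
        return rmse
    return rmse / denom


def _restrict(series: BinnedSeries, t_window: tuple[float, float]) -> BinnedSeries:
    m = (series.time >= t_window[0]) & (series.time <= t_window[1])
    return BinnedSeries(series.time[m], series.mean[m], series.sem[m], series.n[m])


def estimate_delta(
    reference: Ensemble,
    base_config: SimulationConfig,
    grid=np.arange(0.0, 6.5, 0.5),
    n_sim: int = 1000,
    seed: int | None = None,
    t_window: tuple[float, float] = (15.0, 400.0),
    bin_width: float = 15.0,
    window: int = 10,
    normalization: str = "range",
) -> BiasEstimate:
    """Estimate ``delta`` by NRMSE minimization over a candidate grid.

    For each grid value, ``n_sim`` BPRW tracks are simulated with fresh
    seeds, the binned <v_r(t)> curve is computed and scored against the
    reference curve inside ``t_window`` (minutes). Ties and the arg-min
    resolve to the smallest delta; failed candidates score +inf.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if len(grid) == 0:
        raise ValueError("estimate_delta: empty grid")
    ref_curve = _restrict(
        vr_reference_curve(reference, bin_width=bin_width, window=window), t_window
    )
    master = np.random.SeedSequence(seed if seed is not None else base_config.seed)
    candidate_seeds = master.generate_state(len(grid))
    scores = np.empty(len(grid))
    for i, (delta, cseed) in enumerate(zip(grid, candidate_seeds)):
        config = replace(
            base_config, delta=float(delta), n_tracks=n_sim, seed=int(cseed % (2**31))
        )
        try:
            sim = simulate_ensemble(config)
            curve = _restrict(
                vr_reference_curve(sim, bin_width=bin_width, window=window), t_window
            )
            scores[i] = nrmse(ref_curve, curve, normalization=normalization)
        except (SimulationError, ValueError) as exc:
            logger.warning("estimate_delta: candidate delta=%g failed: %s", delta, exc)
            scores[i] = np.inf
        logger.info("estimate_delta: delta=%g -> nrmse=%g", delta, scores[i])
    best = float(grid[int(np.argmin(scores))])
    return BiasEstimate(grid, scores, best, len(reference), n_sim)
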
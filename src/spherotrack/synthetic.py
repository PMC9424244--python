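"""Synthetic tracked-cell datasets emulating the two invasion assays.

Generates ensembles that look like microscope-derived tracks: BPRW/PRW
motion sampled at the acquisition frame interval (3 min for the spheroid
assay, 5 min for isolated cells), random track durations (divisions and
cells leaving the field end real tracks early), isotropic Gaussian
localization noise, and a fraction of immobile/dead cells. Ground-truth
labels accompany every dataset so recovery pipelines can be validated
end to end. Stationary "phantom bead" ensembles emulate the
vibration-noise control: pure localization noise around a fixed point,
which a correct pipeline must classify as immobile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import SimulationConfig, simulate_ensemble
from .trackdata import Assay, Ensemble, Trajectory, resample

logger = logging.getLogger(__name__)

__all__ = ["ExperimentRecipe", "make_experiment", "make_phantom_beads"]


@dataclass(frozen=True)
class ExperimentRecipe:
    """Recipe for one synthetic tracking experiment.

    ``frame_interval`` must be an integer multiple of the simulation step
    ``sim.dt``; ``immobile_fraction`` of the tracks are stationary plus
    noise; mobile track durations are drawn uniformly in ``duration_range``
    (minutes). ``localization_sd`` (um) is the per-frame, per-axis tracking
    noise.
    """

    sim: SimulationConfig
    frame_interval: float | None = None  # default: 3 min GA, 5 min GFA
    localization_sd: float = 1.0
    immobile_fraction: float = 0.1
    duration_range: tuple[float, float] = (150.0, 400.0)
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval is None:
            default = 3.0 if self.sim.assay is Assay.GA else 5.0
            object.__setattr__(self, "frame_interval", default)
        ratio = self.frame_interval / self.sim.dt
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                f"frame_interval {self.frame_interval} must be an integer "
                f"multiple of sim.dt {self.sim.dt}"
            )
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must be in [0, 1]")
        lo, hi = self.duration_range
        if lo > hi or lo < 2 * self.frame_interval:
            raise ValueError("duration_range must satisfy 2*frame_interval <= lo <= hi")

    @property
    def assay(self) -> Assay:
        return self.sim.assay


def _truncate(traj: Trajectory, duration: float) -> Trajectory:
    n_keep = int(duration / traj.frame_interval) + 1
    n_keep = max(2, min(n_keep, traj.n_points))
    return replace(
        traj, times=traj.times[:n_keep].copy(), positions=traj.positions[:n_keep].copy()
    )


def _add_noise(traj: Trajectory, sd: float, rng: np.random.Generator) -> Trajectory:
    if sd == 0:
        return traj
    noisy = traj.positions + sd * rng.standard_normal(traj.positions.shape)
    return replace(traj, positions=noisy)


def make_experiment(recipe: ExperimentRecipe) -> tuple[Ensemble, dict]:
    """Generate a synthetic tracked-cell ensemble plus ground truth.

    No displacement filtering is applied — filtering is the analysis
    pipeline's job. Returns ``(ensemble, truth)`` where ``truth`` records the
    generator parameters and the mobile/immobile label of every track id.
    """
    rng = np.random.default_rng(np.random.SeedSequence(recipe.seed))
    n_total = recipe.sim.n_tracks
    n_immobile = int(round(recipe.immobile_fraction * n_total))
    n_mobile = n_total - n_immobile

    tracks: list[Trajectory] = []
    mobile_ids: list[str] = []
    immobile_ids: list[str] = []

    if n_mobile > 0:
        sim_config = replace(
            recipe.sim, n_tracks=n_mobile, d_min=0.0,
            seed=int(rng.integers(2**31)),
        )
        raw = simulate_ensemble(sim_config)
        for traj in raw:
            coarse = resample(traj, recipe.frame_interval)
            duration = rng.uniform(*recipe.duration_range)
            cut = _truncate(coarse, duration)
            noisy = _add_noise(cut, recipe.localization_sd, rng)
            tid = f"cell{len(tracks):05d}"
            tracks.append(replace(noisy, track_id=tid))
            mobile_ids.append(tid)

    for _ in range(n_immobile):
        if recipe.assay is Assay.GA:
            angle = rng.uniform(0, 2 * np.pi)
            start = recipe.sim.R0 * np.array([np.cos(angle), np.sin(angle)])
        else:
            start = rng.uniform(-200.0, 200.0, size=2)
        duration = rng.uniform(*recipe.duration_range)
        n_pts = max(2, int(duration / recipe.frame_interval) + 1)
        times = recipe.frame_interval * np.arange(n_pts)
        pos = np.tile(start, (n_pts, 1))
        pos = pos + recipe.localization_sd * rng.standard_normal(pos.shape)
        tid = f"cell{len(tracks):05d}"
        tracks.append(Trajectory(tid, times, pos, recipe.assay))
        immobile_ids.append(tid)

    ensemble = Ensemble(
        tuple(tracks),
        recipe.assay,
        spheroid_radius=recipe.sim.R0 if recipe.assay is Assay.GA else None,
    )
    truth = {
        "assay": recipe.assay.value,
        "delta": recipe.sim.delta,
        "P_mean": recipe.sim.P_mean,
        "S_mean": recipe.sim.S_mean,
        "R0": recipe.sim.R0,
        "frame_interval": recipe.frame_interval,
        "localization_sd": recipe.localization_sd,
        "duration_range": list(recipe.duration_range),
        "mobile": mobile_ids,
        "immobile": immobile_ids,
        "seed": recipe.seed,
    }
    logger.info(
        "make_experiment: %d mobile + %d immobile tracks (%s)",
        n_mobile, n_immobile, recipe.assay.value,
    )
    return ensemble, truth


def make_phantom_beads(
    n: int,
    localization_sd: float = 1.0,
    duration: float = 1440.0,
    frame_interval: float = 5.0,
    seed: int = 0,
) -> Ensemble:
    """Stationary phantom-bead tracks: pure localization noise.

    Emulates the vibration-noise control of embedding plastic beads in the
    matrix; a correct pipeline removes all of them with the minimum-
    displacement filter and never accepts a persistent-motion fit on them.
    """
    if n < 1:
        raise ValueError("need n >= 1 beads")
    rng = np.random.default_rng(seed)
    n_pts = int(duration / frame_interval) + 1
    times = frame_interval * np.arange(n_pts)
    tracks = []
    for i in range(n):
        start = rng.uniform(-200.0, 200.0, size=2)
        pos = np.tile(start, (n_pts, 1))
        if localization_sd > 0:
            pos = pos + localization_sd * rng.standard_normal(pos.shape)
        tracks.append(Trajectory(f"bead{i:04d}", times, pos, Assay.GFA))
    return Ensemble(tuple(tracks), Assay.GFA)
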
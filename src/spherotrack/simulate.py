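"""Biased persistent random walk (BPRW) trajectory simulator.

Cell motion is modelled as a discrete Ornstein-Uhlenbeck process on the
velocity, written in normalized units: positions are scaled by <P><S> and
times by <P>, so that the simulated walk has unit speed and unit persistence
time and Fürth's formula holds with S = P = 1. Per step,

    v[i] = (1 - dt~) v[i-1] + Psi(x[i-1], v[i-1]) dt~ + sqrt(dt~) eta[i]
    x[i] = x[i-1] + v[i] dt~

with one independent standard-normal draw per Cartesian component of
``eta``. The spheroid bias is a purely repulsive radial drift

    Psi = delta * R~ / |r|^2 * sin(|rho| / 2) * r_hat,

where ``r`` is the (normalized) vector from the spheroid centre to the
cell, ``R~ = R0 / (<P><S>)`` the normalized spheroid radius, ``rho`` the
angle between ``r`` and the previous step, and ``delta`` a dimensionless
responsiveness. The bias vanishes when the cell moves straight outward
(rho = 0) and is maximal moving inward (rho = 180 deg); with delta = 0 the
model reduces to an unbiased PRW. All state entering the bias is taken at
the previous step, so the update stays explicit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trackdata import Assay, Ensemble, Trajectory, filter_min_displacement

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "NormalizedConfig",
    "SimState",
    "SimulationError",
    "normalize_config",
    "stationary_velocity_sd",
    "bias",
    "step",
    "simulate_trajectory",
    "simulate_ensemble",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot proceed or yields no usable tracks."""


@dataclass(frozen=True)
class SimulationConfig:
    """Physical parameters of one simulated assay.

    ``delta`` is the dimensionless bias responsiveness (0 for a pure PRW;
    required 0 in the gradient-free assay), ``P_mean``/``S_mean`` the target
    persistence time (min) and speed (um/min), ``R0`` the spheroid radius in
    um (GA only). ``n_steps`` steps of ``dt`` minutes give tracks of
    ``n_steps + 1`` points; ensembles are post-filtered at ``d_min`` um
    minimum displacement.
    """

    delta: float
    P_mean: float
    S_mean: float
    assay: Assay
    R0: float = 40.0
    dt: float = 0.5
    n_steps: int = 800
    n_tracks: int = 1
    d_min: float = 50.0
    seed: int = 0
    filter_criterion: str = "max_from_start"
    burn_in: int = 0

    def __post_init__(self):
        object.__setattr__(self, "assay", Assay(self.assay))
        if self.dt <= 0 or self.n_steps < 2 or self.P_mean <= 0 or self.S_mean <= 0:
            raise ValueError("dt, P_mean, S_mean must be positive and n_steps >= 2")
        if self.assay is Assay.GFA and self.delta != 0:
            raise ValueError("GFA simulations are unbiased: delta must be 0")
        if self.assay is Assay.GA and self.R0 <= 0:
            raise ValueError("GA simulations require a positive spheroid radius R0")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must be in [0, n_steps)")


@dataclass(frozen=True)
class NormalizedConfig:
    """Dimensionless simulation scales: dt~ = dt/<P>, R~ = R0/(<P><S>)."""

    dt_tilde: float
    R_tilde: float
    length_scale: float  # um per normalized length unit, = P_mean * S_mean
    time_scale: float  # minutes per normalized time unit, = P_mean


@dataclass(frozen=True)
class SimState:
    """Simulator state: normalized position, previous normalized step velocity."""

    position_tilde: np.ndarray
    prev_step_tilde: np.ndarray
    step_index: int = 0


def normalize_config(config: SimulationConfig) -> NormalizedConfig:
    """Dimensionless scales for the normalized Langevin update."""
    length = config.P_mean * config.S_mean
    return NormalizedConfig(
        dt_tilde=config.dt / config.P_mean,
        R_tilde=config.R0 / length,
        length_scale=length,
        time_scale=config.P_mean,
    )


def stationary_velocity_sd(norm: NormalizedConfig) -> float:
    """Stationary per-component SD of the normalized velocity.

    The unbiased update is an AR(1) process with variance
    dt~ / (1 - (1 - dt~)^2) per component, ~1/2 for small dt~, so the RMS
     2D speed is ~1 in normalized units.
    """
    a = 1.0 - norm.dt_tilde
    return math.sqrt(norm.dt_tilde / (1.0 - a * a))


def _bias_arrays(
    pos: np.ndarray, vel: np.ndarray, norm: NormalizedConfig, delta: float
) -> np.ndarray:
    """Vectorized repulsive drift Psi for positions/velocities of shape (N, 2)."""
    r2 = np.einsum("ij,ij->i", pos, pos)
    if np.any(r2 == 0):
        raise SimulationError("bias undefined: cell at the exact spheroid centre")
    rnorm = np.sqrt(r2)
    vnorm = np.hypot(vel[:, 0], vel[:, 1])
    ok = vnorm > 0
    cos_rho = np.zeros(len(pos))
    np.divide(
        np.einsum("ij,ij->i", pos, vel), rnorm * vnorm, out=cos_rho, where=ok
    )
    # sin|rho/2| via half-angle identity; 0 when moving straight outward
    sin_half = np.sqrt(np.clip((1.0 - cos_rho) / 2.0, 0.0, 1.0))
    mag = np.where(ok, delta * norm.R_tilde / r2 * sin_half, 0.0)
    return (mag / rnorm)[:, None] * pos


def bias(state: SimState, norm: NormalizedConfig, delta: float) -> np.ndarray:
    """Spheroid drift Psi at the current state (normalized units)."""
    if delta == 0:
        return np.zeros(2)
    return _bias_arrays(
        state.position_tilde[None, :], state.prev_step_tilde[None, :], norm, delta
    )[0]


def step(
    state: SimState,
    norm: NormalizedConfig,
    delta: float,
    rng: np.random.Generator,
    noise: np.ndarray | None = None,
) -> SimState:
    """One Langevin update. ``noise`` overrides the random kick (test hook)."""
    eta = rng.standard_normal(2) if noise is None else np.asarray(noise, dtype=float)
    dt = norm.dt_tilde
    v = (1.0 - dt) * state.prev_step_tilde + math.sqrt(dt) * eta
    if delta != 0:
        v = v + bias(state, norm, delta) * dt
    x = state.position_tilde + v * dt
    return SimState(x, v, state.step_index + 1)


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------


def _draw_initial(rng: np.random.Generator, norm: NormalizedConfig, config: SimulationConfig):
    """Initial normalized position and velocity for one track.

    GA tracks start on the spheroid surface at a uniform random angle, moving
    radially outward with a speed drawn from the stationary distribution
    (cells emerge from invasion strands heading outward); GFA tracks start at
    the origin with an isotropic stationary velocity draw.
    """
    sd = stationary_velocity_sd(norm)
    if config.assay is Assay.GA:
        angle = rng.uniform(0.0, 2.0 * math.pi)
        r_hat = np.array([math.cos(angle), math.sin(angle)])
        x0 = norm.R_tilde * r_hat
        speed = sd * float(np.hypot(*rng.standard_normal(2)))
        v0 = speed * r_hat
    else:
        x0 = np.zeros(2)
        v0 = sd * rng.standard_normal(2)
    return x0, v0


def _draw_noise(rng: np.random.Generator, n_steps: int) -> np.ndarray:
    return rng.standard_normal((n_steps, 2))


def _run_biased(
    x0: np.ndarray,
    v0: np.ndarray,
    noise: np.ndarray,
    norm: NormalizedConfig,
    delta: float,
) -> np.ndarray:
    """Vectorized Langevin recursion for N tracks; returns (n_steps+1, N, 2)."""
    n_steps, n_tracks = noise.shape[:2]
    dt = norm.dt_tilde
    sq = math.sqrt(dt)
    out = np.empty((n_steps + 1, n_tracks, 2))
    out[0] = x0
    x = x0.copy()
    v = v0.copy()
    for i in range(n_steps):
        v_new = (1.0 - dt) * v + sq * noise[i]
        if delta != 0:
            v_new += _bias_arrays(x, v, norm, delta) * dt
        v = v_new
        x = x + v * dt
        out[i + 1] = x
    return out


def _positions_to_trajectory(
    pos_tilde: np.ndarray, config: SimulationConfig, norm: NormalizedConfig, track_id: str
) -> Trajectory:
    pos = pos_tilde * norm.length_scale
    if config.burn_in:
        pos = pos[config.burn_in:]
    times = config.dt * np.arange(len(pos))
    return Trajectory(track_id, times, pos, config.assay)


def simulate_trajectory(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Trajectory:
    """Simulate one track and return it in physical units (um, min)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    norm = normalize_config(config)
    x0, v0 = _draw_initial(rng, norm, config)
    noise = _draw_noise(rng, config.n_steps)
    pos = _run_biased(x0[None, :], v0[None, :], noise[:, None, :], norm, config.delta)
    return _positions_to_trajectory(pos[:, 0, :], config, norm, "sim00000")


def simulate_ensemble(config: SimulationConfig) -> Ensemble:
    """Simulate ``n_tracks`` independent tracks and apply the d_min filter.

    Each track consumes its own random substream spawned from the master
    seed, so the ensemble is bit-reproducible and any single track can be
    regenerated in isolation.
    """
    if config.n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    norm = normalize_config(config)
    children = np.random.SeedSequence(config.seed).spawn(config.n_tracks)
    x0 = np.empty((config.n_tracks, 2))
    v0 = np.empty((config.n_tracks, 2))
    noise = np.empty((config.n_steps, config.n_tracks, 2))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        x0[i], v0[i] = _draw_initial(rng, norm, config)
        noise[:, i, :] = _draw_noise(rng, config.n_steps)
    pos = _run_biased(x0, v0, noise, norm, config.delta)
    trajectories = tuple(
        _positions_to_trajectory(pos[:, i, :], config, norm, f"sim{i:05d}")
        for i in range(config.n_tracks)
    )
    ensemble = Ensemble(
        trajectories,
        config.assay,
        spheroid_radius=config.R0 if config.assay is Assay.GA else None,
    )
    if config.d_min > 0:
        filtered = filter_min_displacement(ensemble, config.d_min, config.filter_criterion)
        if len(filtered) == 0:
            raise SimulationError(
                f"all {config.n_tracks} simulated tracks fell below the "
                f"{config.d_min} um displacement filter"
            )
        logger.info(
            "simulate_ensemble: %d/%d tracks pass the %g um filter",
            len(filtered), config.n_tracks, config.d_min,
        )
        return filtered
    return ensemble
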
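"""Self-consistency reproduction experiments.

Each experiment simulates ensembles at the published model parameters and
pushes them through the same estimation pipeline used on tracked cells,
checking that the pipeline recovers what the generator put in: the
speed/persistence pairs of both assays, the median escape angle of the
biased walk, the bias amplitude by NRMSE grid search, and the quality of
the ensemble-MSD Fürth fit.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from . import msd
from .biasfit import BiasEstimate, estimate_delta
from .kinematics import DegenerateGeometryError, phi_angle
from .simulate import SimulationConfig, simulate_ensemble
from .trackdata import Assay, Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "PUBLISHED_PARAMS",
    "recover_prw_parameters",
    "phi_median_contrast",
    "recover_delta",
    "run_reproduction",
]

#: Fitted model parameters of the two assays (bias responsiveness,
#: persistence time in min, speed in um/min).
PUBLISHED_PARAMS = {
    "GA": {"delta": 3.0, "P_mean": 12.7, "S_mean": 1.81},
    "GFA": {"delta": 0.0, "P_mean": 16.6, "S_mean": 1.15},
}


def _substream(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(index + 1)[index] % (2**31))


def recover_prw_parameters(
    P_mean: float,
    S_mean: float,
    n_tracks: int = 1500,
    seed: int = 0,
) -> dict:
    """Simulate an unbiased PRW ensemble and recover (P, S) per track.

    Runs the full estimator chain: 50-um displacement filter, per-track
    time-averaged msd, weighted Fürth fit over the first 25% of lags with
    R^2 > 0.99 acceptance, then log-Gaussian (P) and Gaussian (S)
    distribution fits. Also fits the ensemble-averaged MSD once.
    """
    config = SimulationConfig(
        delta=0.0, P_mean=P_mean, S_mean=S_mean, assay=Assay.GFA,
        dt=0.5, n_steps=800, n_tracks=n_tracks, d_min=50.0, seed=seed,
    )
    ensemble = simulate_ensemble(config)
    fits = [msd.fit_furth(msd.time_avg_msd(t)) for t in ensemble]
    summary = msd.summarize_ensemble(fits)
    ens_fit = msd.fit_furth(msd.ensemble_msd(ensemble))
    logger.info(
        "PRW recovery (P=%g, S=%g): mean_P=%.3f, mean_S=%.3f from %d/%d fits; "
        "ensemble fit R^2=%.5f",
        P_mean, S_mean, summary.mean_P, summary.mean_S,
        summary.n_accepted, len(ensemble), ens_fit.r_squared,
    )
    return {
        "mean_P": summary.mean_P,
        "mean_S": summary.mean_S,
        "sd_log_P": summary.sd_log_P,
        "sd_S": summary.sd_S,
        "n_tracks": n_tracks,
        "n_after_filter": len(ensemble),
        "n_accepted": summary.n_accepted,
        "ensemble_fit": ens_fit,
    }


def _median_phi(ensemble: Ensemble) -> float:
    phis = []
    for traj in ensemble:
        try:
            phis.append(phi_angle(traj))
        except DegenerateGeometryError:
            continue
    return float(np.median(phis))


def phi_median_contrast(n_tracks: int = 1500, seed: int = 0) -> dict:
    """Median escape angle phi for a biased vs unbiased spheroid ensemble.

    Both ensembles start on the spheroid surface with the published GA
    persistence/speed; only the biased one feels the repulsive drift. The
    bias pulls the major axis toward the radial direction, so its median
    phi is far below the unbiased one.
    """
    params = PUBLISHED_PARAMS["GA"]
    base = SimulationConfig(
        delta=params["delta"], P_mean=params["P_mean"], S_mean=params["S_mean"],
        assay=Assay.GA, R0=40.0, dt=0.5, n_steps=800,
        n_tracks=n_tracks, d_min=50.0, seed=seed,
    )
    bprw = simulate_ensemble(base)
    prw = simulate_ensemble(replace(base, delta=0.0, seed=_substream(seed, 1)))
    out = {
        "median_phi_bprw": _median_phi(bprw),
        "median_phi_prw": _median_phi(prw),
        "n_tracks": n_tracks,
    }
    logger.info(
        "phi medians: BPRW %.1f deg, PRW %.1f deg",
        out["median_phi_bprw"], out["median_phi_prw"],
    )
    return out


def recover_delta(
    seed: int = 0,
    n_reference: int = 1000,
    n_sim: int = 1000,
    grid=np.arange(0.0, 6.5, 0.5),
) -> BiasEstimate:
    """Recover the bias amplitude from a reference biased ensemble.

    The reference is simulated at the published GA parameters; candidates on
    the grid are scored by range-normalized RMSE between binned
    radial-velocity curves over t in [15, 400] min.
    """
    params = PUBLISHED_PARAMS["GA"]
    base = SimulationConfig(
        delta=params["delta"], P_mean=params["P_mean"], S_mean=params["S_mean"],
        assay=Assay.GA, R0=40.0, dt=0.5, n_steps=800,
        n_tracks=n_reference, d_min=50.0, seed=_substream(seed, 0),
    )
    reference = simulate_ensemble(base)
    estimate = estimate_delta(
        reference, base, grid=grid, n_sim=n_sim, seed=_substream(seed, 1)
    )
    logger.info("delta recovery: best_delta=%g", estimate.best_delta)
    return estimate


def run_reproduction(
    seed: int = 0,
    n_tracks: int = 1500,
    n_delta: int = 1000,
) -> dict:
    """Run every reproduction experiment; returns observed values keyed by name."""
    gfa = PUBLISHED_PARAMS["GFA"]
    ga = PUBLISHED_PARAMS["GA"]
    rec_gfa = recover_prw_parameters(
        gfa["P_mean"], gfa["S_mean"], n_tracks, seed=_substream(seed, 0)
    )
    rec_ga = recover_prw_parameters(
        ga["P_mean"], ga["S_mean"], n_tracks, seed=_substream(seed, 1)
    )
    phi = phi_median_contrast(n_tracks, seed=_substream(seed, 2))
    delta = recover_delta(seed=_substream(seed, 3), n_reference=n_delta, n_sim=n_delta)
    return {
        "mean_P_gfa": {"value": rec_gfa["mean_P"], "expected": gfa["P_mean"],
                       "rtol": 0.15, "n": n_tracks},
        "mean_S_gfa": {"value": rec_gfa["mean_S"], "expected": gfa["S_mean"],
                       "rtol": 0.10, "n": n_tracks},
        "mean_P_ga": {"value": rec_ga["mean_P"], "expected": ga["P_mean"],
                      "rtol": 0.15, "n": n_tracks},
        "mean_S_ga": {"value": rec_ga["mean_S"], "expected": ga["S_mean"],
                      "rtol": 0.10, "n": n_tracks},
        "median_phi_ga": {"value": phi["median_phi_bprw"], "expected": 35.0,
                          "atol": 10.0, "n": n_tracks,
                          "prw_median": phi["median_phi_prw"]},
        "delta_estimate": {"value": delta.best_delta, "expected": ga["delta"],
                           "atol": 0.25, "n": n_delta},
        "ensemble_fit_r2": {"value": rec_gfa["ensemble_fit"].r_squared,
                            "expected": 0.99, "bound": "ge", "n": n_tracks},
    }


def format_report(results: dict) -> str:
    """Human-readable pass/fail table for :func:`run_reproduction` output."""
    lines = [f"{'quantity':<18}{'observed':>12}{'expected':>12}{'tolerance':>14}{'status':>9}"]
    for name, r in results.items():
        if r.get("bound") == "ge":
            ok = r["value"] >= r["expected"]
            tol = f">= {r['expected']}"
        elif "rtol" in r:
            ok = abs(r["value"] - r["expected"]) <= r["rtol"] * r["expected"]
            tol = f"+/-{r['rtol']:.0%}"
        else:
            ok = abs(r["value"] - r["expected"]) <= r["atol"]
            tol = f"+/-{r['atol']:g}"
        lines.append(
            f"{name:<18}{r['value']:>12.4g}{r['expected']:>12.4g}{tol:>14}"
            f"{'pass' if ok else 'FAIL':>9}"
        )
    return "\n".join(lines)
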
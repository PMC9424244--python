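# spherotrack

Trajectory statistics and biased-persistent-random-walk modelling of tumor
spheroid cell invasion.

Glioblastoma cells escaping a matrix-embedded tumor spheroid migrate faster,
straighter and radially outward compared with identical cells embedded alone
in the same extracellular matrix. `spherotrack` packages the quantitative
analysis behind that observation for anyone working with 2D tracks of
migrating cells: it computes per-track and ensemble mean-squared
displacements, fits Fürth's persistent-random-walk formula, measures
direction-referenced statistics against the spheroid geometry, simulates the
biased persistent random walk (BPRW) that explains the escape, and estimates
the strength of the spheroid's repulsive bias from radial-velocity curves.

## The model

A persistently migrating cell with speed *S* (μm/min) and persistence time
*P* (min) has the closed-form mean-squared displacement (Fürth's formula)

    MSD(τ) = 2 S² P² ( e^(−τ/P) + τ/P − 1 ),

ballistic (∝ τ²) for τ ≪ P and diffusive (∝ τ) for τ ≫ P. Each track's
time-averaged msd is fitted by weighted nonlinear least squares over the
first 25% of lag points, weighting point *a* of *A* by the variance model

    W(a) = MSD(τ_a) · ( (2a² + 1) / (3a(A − a + 1)) )²,

and fits with weighted R² ≤ 0.99 are discarded. Per-cell parameters are
summarized by a log-Gaussian fit to the *P* distribution and a Gaussian fit
to the *S* distribution.

Trajectories are modelled as a discrete Ornstein–Uhlenbeck (persistent
random walk) process written in normalized units (lengths over ⟨P⟩⟨S⟩, times
over ⟨P⟩), with an optional repulsive spheroid drift:

    v[i] = (1 − dt̃) v[i−1] + Ψ dt̃ + √dt̃ · η[i],      x[i] = x[i−1] + v[i] dt̃,
    Ψ    = δ R̃ / |r|² · sin(|ρ|/2) · r̂,

where η is a standard-normal kick per component, r the vector from the
spheroid centre to the cell, R̃ the normalized spheroid radius, ρ the angle
between r and the previous step, and δ a dimensionless bias responsiveness.
δ = 0 recovers the unbiased walk of isolated cells; δ is estimated by
grid-search minimization of the normalized RMSE between binned
ensemble-averaged radial-velocity curves ⟨v_r(t)⟩ of a reference ensemble
and candidate simulations.

Direction-referenced per-track statistics: the major axis **m** (mean step
vector), the radial reference **r** (start position for spheroid assays, the
first step for isolated cells), the escape angle φ = ∠(**m**, **r**), the
radial distance d_r(t), the directionality ratio 𝒟(t) = net displacement /
path length ∈ [0, 1], and the radial velocity v_r(t) = **v**(t)·r̂.

## Worked example

Simulate 300 unbiased tracks at the gradient-free parameters
(P = 16.6 min, S = 1.15 μm/min, 0.5-min steps, 400 min) and push them
through the full analysis (50-μm immobile filter, weighted Fürth fits,
distribution summaries, kinematics):

```sh
spherotrack simulate --assay gfa --delta 0 --p-mean 16.6 --s-mean 1.15 \
    --tracks 300 --seed 7 --out demo_tracks.csv
spherotrack analyze --tracks demo_tracks.csv --assay gfa --out demo_report
```

prints (abridged):

```json
{
  "n_tracks_in": 298,
  "n_after_filter": 298,
  "n_fits_accepted": 297,
  "mean_P": 15.869748251073394,
  "mean_S": 1.1495842168723565,
  "sd_S": 0.11592002769309238,
  "ks_normality_p": 0.3095945630231902,
  "median_phi": 76.4823214440468
}
```

The per-track fits recover the generator parameters: the log-Gaussian
location of the persistence times is 15.9 min (generator: 16.6 min, the
small deficit being finite-track fitting scatter) and the mean fitted speed
is 1.150 μm/min (generator: 1.15). With no bias the escape angle φ is
uninformative — its median sits near 76°, close to the 90° of a fully
isotropic null. `demo_report/` additionally contains `fits.csv` (per-track
S, P, R²), `kinematics.csv`, binned `curve_*.csv` ensemble series, and a
`manifest.json` that reproduces the run.

The same workflow in Python:

```python
from spherotrack import SimulationConfig, simulate_ensemble, time_avg_msd, fit_furth

config = SimulationConfig(delta=0.0, P_mean=16.6, S_mean=1.15,
                          assay="GFA", n_tracks=300, seed=7)
ensemble = simulate_ensemble(config)
fits = [fit_furth(time_avg_msd(t)) for t in ensemble]
```

Other subcommands: `spherotrack synth` (synthetic tracked-cell datasets with
ground-truth labels, localization noise and immobile cells),
`spherotrack estimate-bias` (δ grid search against a reference track CSV)
and `spherotrack reproduce` (the full self-consistency table).

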
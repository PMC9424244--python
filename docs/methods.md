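# Methods

This note records the modelling conventions, numerical choices and known
limitations of `spherotrack`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Data model and conventions

Tracks are 2D position time series in micrometres, sampled at a uniform
frame interval in minutes; they are 2D projections of cells migrating in a
3D matrix. Each track's clock starts at its own first sample (cells enter
the field at different absolute times). For spheroid (gradient assay, GA)
ensembles the spheroid centre is the coordinate origin and the spheroid
radius defaults to 40 μm (an ~80 μm diameter spheroid); input files recorded
in another frame are translated at load time. Isolated-cell (gradient-free
assay, GFA) ensembles carry no geometry.

The acquisition emulated by the synthetic-data generator uses 3-min frames
for GA and 5-min frames for GFA.

**Immobile-cell filter.** Tracks moving "less than 50 μm over their entire
trajectory" are removed before analysis. Three readings of that phrase are
implemented — maximum displacement from the start, net end-to-end
displacement, and total path length — and the default is the maximum
displacement from the start, `max_i |x(t_i) − x(0)| ≥ d_min`: it removes
immobile/dead cells without penalizing motile cells that make U-turns
(which a net-displacement criterion would discard) and without letting a
jittering dead cell accumulate path length past the threshold.

## MSD computation and Fürth fitting

The time-averaged msd of one track uses all overlapping windows at each lag
(an FFT-based O(n log n) evaluation, validated in the tests against direct
window enumeration); the ensemble MSD averages squared displacements from
each track's start, with per-lag SEM and contributing-track counts.

The weighted fit minimizes Σ_a (msd(τ_a) − MSD_model(τ_a))² / W(a) over the
first A lag points. The weighting formula W(a) is treated as the variance
of the msd at point a — it grows steeply at large lags, where few windows
contribute — which is what makes per-track fits usable at all beyond the
first few lags. Choices:

- A = ⌈0.25 · (number of available lags)⌉, minimum 4. "25% of the
  trajectory length" is read as 25% of the msd curve's lag points.
- Weighted R² = 1 − SS_res/SS_tot with the same 1/W(a) weights in both
  sums; acceptance requires R² > 0.99.
- Initialization: S₀ from the first msd point's ballistic slope, P₀ from
  the lag where the msd falls to half its ballistic extrapolation; up to 3
  restarts with perturbed initials. Bounds S ∈ (0, 100] μm/min,
  P ∈ (Δ/10, 10·τ_max]. A fit that converges onto a bound (e.g. P pinned
  at its ceiling for a purely ballistic curve) is flagged not accepted even
  if R² is high. Non-convergence is reported, never raised.
- Zero-msd points receive zero fit weight.

Per-cell parameters are summarized by exp(mean(log P)) with the SD of log
values (log-Gaussian location and width), and mean/SD of S (Gaussian) with
a Kolmogorov–Smirnov p-value for normality of S. Trajectory speed is
reported both as the mean per-step speed (default) and as the magnitude of
the time-averaged velocity vector; the two differ for any curved track, so
exports carry both columns rather than silently preferring one.

## Kinematics

Angles are reported in degrees. Degenerate geometry (a track starting at
the spheroid centre, a zero first step, a perfectly closed loop) makes the
radial reference or major axis undefined; such tracks are excluded from
angle and radial-velocity statistics with logged counts rather than being
assigned arbitrary values. Ensemble time series align tracks on their own
t = 0 and weight tracks equally at each time point while alive. Binned
curves use 15-min bins labelled by bin centre, then a centred moving
average of 10 bins truncated at the edges. Directionality stratification
groups tracks by d_r(75 min) around centres {0, 80, 160} μm with a ±40 μm
half-width (half the centre spacing; the bin width is configurable because
the source analysis does not state one).

## The BPRW simulator

The update written in the normalized variables x̃ = x/(⟨P⟩⟨S⟩), t̃ = t/⟨P⟩
is the standard discrete Ornstein–Uhlenbeck velocity process

    ṽ[i] = (1 − dt̃) ṽ[i−1] + Ψ dt̃ + √dt̃ η[i],    x̃[i] = x̃[i−1] + ṽ[i] dt̃,

with one independent N(0,1) draw per Cartesian component (a shared scalar
would collapse motion onto a diagonal). In this form the walk has unit RMS
speed and unit persistence time, so Fürth's formula holds with S = P = 1 in
normalized units and denormalization is multiplication by the physical
scales. The stationary per-component velocity variance is the AR(1) closed
form dt̃/(1 − (1 − dt̃)²) → 1/2 as dt̃ → 0, which the tests verify to 2%.

The bias Ψ = δR̃/|r|² · sin(|ρ|/2) · r̂ is evaluated entirely at the previous
step (position and step direction), keeping the update explicit; |r| is in
normalized units, as is the whole equation. It vanishes for motion straight
outward (ρ = 0), is maximal moving inward, never points inward, and decays
with the inverse square of the distance from the spheroid centre. On the
first step of a track, and whenever the previous step is zero, the bias is
zero. A cell exactly at the centre makes the bias undefined and aborts with
a diagnostic rather than guessing a direction.

Initial conditions are not stated by the source analysis and are package
choices, exposed in the configuration: GA tracks start on the spheroid
surface at a uniform random angle, moving radially outward at a speed drawn
from the stationary distribution (cells emerge from invasion strands
heading outward); GFA tracks start at the origin with an isotropic
stationary velocity draw. Both assays therefore need no burn-in, though a
burn-in option exists. Defaults follow the study conditions: dt = 0.5 min,
n = 800 steps (400-min tracks), 50-μm minimum displacement filter, and the
published parameter pairs (GA: δ = 3, P = 12.7 min, S = 1.81 μm/min;
GFA: δ = 0, P = 16.6 min, S = 1.15 μm/min).

Ensembles draw one random substream per track from the master seed
(NumPy `SeedSequence.spawn`), so runs are bit-reproducible and any single
track can be regenerated in isolation; the step recursion itself is
vectorized across tracks.

## Bias-amplitude estimation

δ is estimated by simulating candidate ensembles over a grid (default 0–6
in steps of 0.5, bracketing the working value 3 symmetrically), computing
each candidate's binned ⟨v_r(t)⟩ curve, and scoring it against the
reference curve by RMSE divided by the reference curve's range. Range
normalization is chosen over mean normalization because these curves decay
toward zero, where a mean normalizer becomes unstable; mean normalization
remains available. Curves are compared on common bin centres within
t ∈ [15, 400] min, excluding the sparse long-time tail. Ties resolve to the
smallest δ; a failed candidate scores +∞. The comparison is done in the
time domain; a distance-domain comparison is not implemented.

At the default sizes (N = 1000 reference, N = 1000 per candidate, fresh
seeds per candidate) the grid search recovers the generating δ = 3 exactly
in roughly 7 of 10 seeds and within one 0.5-step otherwise: the NRMSE gap
between adjacent-δ curves (~0.04) is only about three times the N = 1000
Monte-Carlo noise floor (~0.012), so one-step flips are intrinsic to the
procedure at this ensemble size, and ±0.5 should be regarded as the
method's resolution.

## What the synthetic data does and does not emulate

`make_experiment` layers tracking imperfections onto simulated motion:
resampling to the acquisition frame interval, random track truncation
(uniform in 150–400 min, standing in for divisions, merges and cells
leaving the field or focus, whose causes are not modelled), isotropic
per-frame Gaussian localization noise, and a fraction of immobile cells.
The 1-μm localization SD is an assumption — the source imaging description
gives no usable noise magnitude — and matters: at 5-min frames it inflates
short-lag msd values and deflates the recovered ⟨P⟩ by roughly 15%
(measured in the tests), which is the documented noise floor of the
pipeline. No static-error correction is applied, matching the analysis
being emulated. Phantom-bead ensembles (pure localization noise around a
fixed point) emulate the stage-vibration control; the pipeline must remove
all of them with the 50-μm filter and never accept a persistent-motion fit
on them.

What passing tests on synthetic data do **not** show about real data: the
generator draws every cell from a single (S, P) pair, so cell-to-cell
heterogeneity (the right-skewed speed distributions, the highly persistent
outliers, and the overlap of directionality distributions across distance
bins that heterogeneous speeds produce) is absent; the matrix is implicitly
homogeneous and memory-free (no degraded-tunnel reuse, which in real data
produces the 180° peak in turning angles); and there are no cell–cell
interactions.

## Reproduction experiments and problem sizes

`scripts/acceptance.py` and `spherotrack reproduce` run: (1, 2) PRW
parameter recovery at N = 1500 for both published (P, S) pairs through the
full filter–fit–summarize chain; (3) the median escape angle φ of the full
N = 1500 BPRW spheroid ensemble against its unbiased counterpart; (4) δ
recovery at N = 1000; (5) the weighted Fürth fit of the N = 1500 ensemble
MSD. Typical recovered values: ⟨P⟩ within ~7% (the residual deficit is
finite-track fitting bias), ⟨S⟩ within ~1%, ensemble-fit R² > 0.999.

The simulated median φ deserves a caveat: at the full 400-min track length
it sits near 48–50°, not at the 35° measured on real spheroid-escaping
cells. The major axis of a simulated track dilutes as the cell leaves the
bias field and wanders isotropically, and shorter tracks (as dominate real
data, where tracks end early) give correspondingly smaller medians —
50-min tracks give ~34°. The qualitative contrast is robust: the unbiased
ensemble's median exceeds the biased one by ~30° under all conditions
tested.

## Known limitations

- Isotropic PRW only; no anisotropic (APRW) variant, no 3D.
- The bias is purely repulsive; an attractant variant is out of scope.
- One (S, P) per ensemble; no population heterogeneity.
- Ensemble-level and track-level Fürth fits yield slightly different
  (S, P); no reconciliation is attempted — reports state which was used.
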
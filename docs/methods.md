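# Methods

This note documents the models implemented in `aurbt`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Observation model and segmentation

A rotor-bead angle trace within one R-loop state is modeled as a stationary
Ornstein–Uhlenbeck (OU) process around a state-dependent mean: relaxation
time `τ_c` (s) and stationary standard deviation `σ` (turns) are global
properties of the bead/tether and are fixed once — in real experiments from
a baseline segment recorded before protein is introduced
(`estimate_ou_params`, which uses the stationary variance and the lag-1
autocorrelation of the exact AR(1) discretization). The only free
parameters during segmentation are the per-segment mean and the change-point
times.

The exact discretization turns the likelihood into independent Gaussian
innovations `z_n = y_n − a y_{n−1}`, `a = e^{−Δt/τ_c}`, with
`E[z] = μ(1−a)` and `Var[z] = σ²(1−a²)`. Segment costs are therefore
within-segment sums of squares of innovations, evaluated in O(1) from
cumulative sums. Numerical conventions:

- The innovation that straddles a change point is assigned to the **later**
  segment (a tie-break; it is also exactly the generative behaviour of a
  bead that starts relaxing toward the new mean at the switch).
- The reported dwell mean is the conditional ML mean from the segment's
  *interior* innovations, `μ̂ = z̄/(1−a)`, so a noiseless step yields exact
  means; a length-1 segment falls back to the sample value.
- In the noiseless limit (`σ = 0`) costs are scaled by the empirical
  innovation variance so the penalty keeps its meaning; an exactly constant
  series stays a single dwell.

Search is optimal partitioning with pruning (PELT, numba-compiled), with a
conservative pruning slack equal to the penalty so the minimum-dwell
constraint cannot prune the optimum. An exact dynamic program over
(position, number of change points) — `oracle_segment`, itself validated
against literal enumeration on tiny inputs — provides an independent global
optimum for instances up to a few thousand samples; the test suite checks
that PELT attains the oracle's penalized objective on every seeded instance.

**Penalty.** No threshold is inherited from any external tool; the default
is BIC-style, `2 ln n` per change point (one mean plus one breakpoint per
extra segment), exposed in the configuration. At this default, fewer than
5% of pure-noise traces of 2,000 samples acquire a spurious change point.
**Minimum dwell** defaults to 5 samples, preventing single-sample spikes
from becoming segments. **Decimation** keeps every k-th sample; because
`(τ_c, σ)` are expressed in seconds they remain exact at the decimated
sampling interval.

## State scoring

Dwell mean levels are converted turns → bp via the helical repeat
(h = 10.5 bp/turn) and clustered by a lifetime-weighted Lloyd iteration:
assignment to the nearest center, centers recomputed as lifetime-weighted
mean unwinding, iterated to a fixed point. The states are known a priori
(C/I/O near 0/7/14 bp), so user-supplied initial centers are preferred;
quantile initialization exists for blind use. Boundaries are arithmetic
means of adjacent centers; a dwell exactly on a boundary goes to the lower
state. Adjacent same-state dwells are merged (lifetime-weighted mean;
merging conserves total lifetime and weighted mean exactly), and all levels
are shifted so the lifetime-weighted mean of the predominant closed state
is 0 bp. If the most-occupied state is not the lowest-center state, the
zero still goes to the lowest-center state and a warning is raised.
Short-lived excursions beyond the open state (O′) can be captured by an
optional extra threshold (one boundary-width above the top center); by
default they are not split out. Occupancy histograms assign each dwell's
lifetime to the 0.5-bp bin containing its mean and normalize to unit mass.

## Equilibrium kinetics and landscape

`k_ij = N_ij / T_i` with Poisson standard error `√N_ij / T_i`. Counting
starts **after the first transition event**: the initial dwell (recorded
before the first R-loop event) is excluded from both counts and occupancy.
The final, right-censored dwell contributes occupancy but no exit; no
censoring correction is applied (the bias is second order when many events
are observed, and the convention is switchable). `K_ij = k_ij/k_ji`,
`ΔG_ij = −ln K_ij` in kBT, and barrier heights `ΔG‡_ij = −ln k_ij` against
an implicit unit (1 s⁻¹) attempt frequency — a display-level convention,
not an absolute activation energy. The landscape walks adjacent pairs
(C–I–O) cumulatively from C at 0; direct C↔O events, if ever observed, are
reported in the rate table but excluded from the landscape path. At the
equilibrium stage barriers are drawn midway between wells; the torque-driven
analysis refines their fractional position.

## Torque-driven analysis

Torque is read from the transducer deflection, `τ = κ_t,turn (θ − ψ)` with
`κ_t,turn = 2π · 0.26 pN·nm/rad`, after subtracting a supplied zero-offset
magnet position (the experimental zero calibration from maximum tether
extension is hardware-specific and out of scope). The tether stiffness κ is
the slope of τ versus θ on closed-state spans; unwinding is
`Δθ₀(bp) = h (τ − τ_B)/(2π κ_rad)` with `τ_B` the B-DNA line. On noiseless
synthetic data this chain inverts the generator to machine precision; with
OU noise the per-sample error is the rotor noise scaled by
`h κ_t/κ` (≈ 11.4 bp/turn at the defaults).

**Stiffness conventions.** Angles are kept in turns. Torque per turn uses
`κ_turn = 2π κ_rad`. The twist-dependence of *energies and rates* uses the
torsional *energy* stiffness per turn², `κ_E = 4π² κ_rad` (since
`E = ½ κ_rad φ²` with φ in radians), so the ln K slope is
`β κ_E Δθ` per turn. The fractional barrier position `Δθ‡/Δθ` is a ratio of
fitted slopes and is independent of this convention.

Kinetics are binned by the instantaneous imposed twist (default bin width
0.5 turns, configurable — no published value exists): each dwell's lifetime
is spread over the bins its θ(t) visits by midpoint sampling whose total is
exactly the dwell duration, and each transition is counted in the bin of θ
at the transition time (θ at dwell onset is also recorded for display
coloring). Pairs with fewer than 3 transitions in a bin are excluded.
`ln K` versus θ is fit by weighted least squares with weights from the
propagated Poisson error `√(1/N_ij + 1/N_ji)`; `ln k` fits run over a
configured twist window or an automatically selected largest contiguous bin
run with weighted R² ≥ 0.8 (the generative law is exactly linear, so on
synthetic data this is the full range). Landscapes at a chosen θ cumulate
`ΔG_ij(θ) = ΔG_ij(0) − slope·θ` kBT along the state order; well positions
come from lifetime-weighted Δθ₀ (fitted Δθ values are used only for
energies), barriers sit at fractional position Δθ‡/Δθ between wells at
energy `well_i − ln k_ij(θ)`.

A known small bias: rates vary exponentially *within* a 0.5-turn bin, so a
binned rate attributed to the bin center slightly flattens the fitted
slopes (a few percent at the defaults) — visible in recovery tests as Δθ
estimates ~5% below truth, well inside the stated tolerances. Narrower bins
trade this bias against Poisson noise.

## Cleavage kinetics

Fraction cleaved = product / total lane signal. Each replicate time course
is fit to `Y = A (1 − e^{−k_obs t})` (t in minutes) by bounded nonlinear
least squares: A ∈ (0, 1.05] (slightly above 1 to tolerate noise at
saturation), k_obs ≥ 0; initial guesses are A₀ = max fraction and
k₀ = ln 2 / t_half from the first half-max crossing. Whether A should be
fixed to 1 for weakly-cleaving samples is an open choice; A is left free
and reported. Replicates that never rise above the noise floor are flagged
(k_obs unidentifiable) and excluded from the mean; results are mean ± SD
across replicates. Fold-changes propagate the standard errors of the two
mean rates to first order.

## Synthetic data generator

The generator's defaults are the study conditions: 5 kHz sampling at 5 pN,
states at 0/7/14 bp, ramps between +7.5 and −5 turns at 3 RPM, transducer
stiffness 0.26 pN·nm/rad, 10.5 bp/turn, cleavage quench grid
(0.5, 1, 5, 10, 30, 60, 120) min with 3 replicates and gel noise SD 0.02
clipped to [0, 1]. Values no protocol states were chosen once as realistic
for an 80-nm gold rotor on a ~5-kb tether and are configurable: OU
relaxation τ_c = 5 ms and σ = 0.05 turns (≈ 0.5 bp); tether torsional
stiffness κ_rad = 0.24 pN·nm/rad (torsional persistence ≈ 100 nm over a
1.7 µm contour); equilibrium base rates 0.2/0.5/0.1/0.3 s⁻¹ for
C→I/I→C/I→O/O→I (order 0.05–1 s⁻¹, closed state predominant); barrier twist
at 0.4 of the transition twist change.

Hidden-state switching is a continuous-time Markov chain: exact Gillespie
at constant twist; under a ramp, exact thinning against per-window,
per-state upper bounds of the exit rates (rates are monotone-exponential in
θ, so window bounds come from the window's twist extremes; bounds from
sampled generic θ(t) callables carry a 5% safety factor). The generative
rate law is exactly the linear-in-log model — fit recovery is exact in
expectation, and a quadratic twist-tilt is deliberately out of scope. The
observable adds OU noise that mean-reverts toward the state mean (the bead
relaxes through τ_c after a switch rather than teleporting), generated by
the exact discretization with a stationary start. Identical seeds give
bit-identical traces; path and noise use independently spawned streams.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: bead-tracking localization error and camera
discretization, slow instrumental drift, tether heterogeneity and
plectoneme/buckling mechanics at high torque, torque-dependent extension,
the zero-torque magnet calibration, state-dependent noise amplitude, and
any deviation of real R-loop kinetics from Markovian exponential dwells.

## Problem sizes used in the automated checks

The end-to-end recovery checks run on sizes chosen to give comfortable
statistics per quantity: 2,000 s of relaxed trace at 5 kHz (decimated ×10
for segmentation, ~600 transitions), five ramp cycles (2,500 s) for
twist-dependence fits, 50 instances of ≤ 2,000 samples for the
segmentation-vs-oracle comparison, and three seeded reaction triplicates
per cleavage rate (averaging the recovered rate over independent
triplicates; a single triplicate of the slowest rate has ~5% sampling
scatter). These are the package's own choices of statistically sufficient
problem sizes.

## Known limitations

- Dwells shorter than the minimum dwell (10 ms at the default decimated
  sampling) are missed, undercounting rates by ~1% at exit rates ≈ 1 s⁻¹;
  negligible against Poisson errors at realistic event counts but
  systematic.
- Occupancy in twist bins is accrued by midpoint sampling (default 10 ms
  resolution), not exact interval intersection.
- The barrier-height convention (unit attempt frequency) makes barrier
  energies comparable within a dataset, not absolute.
- `oracle_segment` is quadratic in trace length and capped at 4,000
  samples and 3 change points; it is a validation tool, not a production
  path.
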
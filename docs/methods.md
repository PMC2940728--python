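# Methods

## Model and conventions

All free energies are in units of kT (kT = 1); time is measured in saved-frame
units, with the physical spacing recorded in series metadata. A reaction
coordinate is any scalar function of configuration; the package analyzes its
uniformly sampled time series x(t).

**Cut partition function.** Z_C(x; k) counts, with a factor ½, the index
pairs (t, t+k) whose values straddle the level x. The ½ makes the ballistic
plateau of Z_C at the transition state equal the number of folding events
(each event contributes one up- and one down-crossing pair at large
sampling intervals); raw alternation counts are also exposed. By default all
k phase offsets are used and the count is divided by k (`offset_mode=
"average"`), which uses every frame and has the same k-scaling as the
single-phase definition (kept as `"single"`); a frame exactly at a level is
assigned to the left side, and levels are placed at histogram bin midpoints
so ties have measure zero for continuous data. Empty bins and zero-crossing
levels are masked, never set to ±∞.

**Diffusion profile and natural coordinate.** The mean absolute displacement
per sampling interval is ⟨|Δx|⟩ = 2 Z_C/Z̃_H with Z̃_H the frames-per-length
of the sampled series (the full-trajectory histogram divided by the stride,
consistent with the per-phase normalization of Z_C). For diffusive dynamics
⟨|Δx|⟩ = √(4DΔt/π), giving D(x); y(x) = ∫dx/√D (trapezoid over level
midpoints; interior masked levels bridged by linear interpolation of 1/√D,
terminal ones truncated) maps to the natural coordinate with D ≡ 1. The map
is piecewise linear with edge-slope extrapolation; a non-monotone image
raises an internal-consistency error rather than being silently repaired.

**Anomalous exponent.** α(x) = 1 + [ln Z_C(x;k₂) − ln Z_C(x;k₁)]/ln(k₂/k₁).
Standard errors come from a circular block bootstrap over 20 contiguous
blocks of per-block crossing counts, since crossings are serially dependent.
The default stride pair is (4, 8): strides must be large enough that the
displacement over kΔt exceeds the level-grid spacing and (for the atomistic
generator) sits at or above the positional-noise correlation time, and small
enough that the barrier drift is still negligible against the noise
displacement — at the generators' default time resolution both conditions
hold at (4, 8). `alpha_pooled` sums crossing counts over a central quantile
band of levels before taking the ratio; on exact fBm at n = 2¹⁸ it recovers
the Hurst exponent to ±0.015, where a single median-level estimate scatters
by ±0.07 across seeds.

**Two-line ballistic model.** ln Z_C at the transition state versus ln k is
fit by a sloped line joined continuously to a plateau (ln Z_bal) at the
knee t_bal, by least squares with three knee initializations; strides beyond
the dwell-time rolloff (Z_C more than 20% below the running plateau median)
are excluded because at sampling intervals comparable to the basin dwell
time whole transitions go undetected. A scan explained by a flat or single
sloped line is flagged `plateau_only`/`slope_only` instead of forcing a
knee. The closed form α = 1 − [(−F_TS) − ln Z_bal]/ln(t_bal/Δt₀) inverts the
same geometry; α > 1 signals an over-fit coordinate and warns.

**Kramers kinetics.** mfpt(a→b) = ∫ab Φ(y)/(D(y)ρ(y)) dy with reflecting
boundary at the data edge on the source side, by a per-bin midpoint rule
accumulated at bin edges (exact for linear integrands; the flat-profile
closed form L²/2 is reproduced to sampling noise). Interior masked bins are
bridged by interpolation; gaps wider than 3 bins are an error. Passage
endpoints are the *basin bottoms*, not the data-range edges — the
vanishing-density outermost bins otherwise dominate the integral (measured
~50× inflation). Basins are located from the histogram: the two most
populated density peaks whose inter-peak density dips below 75% of the
smaller peak (plain F_C minima fail for integer-valued contact coordinates,
which concentrate a basin on one level where F_C has no minimum); the
transition state is the F_C maximum between them, ties resolved to the
plateau midpoint. `estimate_event_count` applies the round-trip identity
with basin-equilibrium-averaged mfpts (single-point starts are also
exposed).

## Coordinate families and optimizer

Q1 ("contacts"): R = Σ s_p·step(r0_p − d_p) with s ∈ {−1,+1}, step(0) = 1
(fixed convention; measure-zero for real data). Q2 ("distances"):
R = Σ c_p·d_p. Native-contact initialization takes all pairs within a
cutoff (sequence-separation filter configurable, 0 for the toy fixtures),
with constant or native-proportional thresholds.

The optimizer draws a random pair, scans its parameter on a grid (Q1: both
signs × 12 thresholds between the 5th and 95th percentile of that pair's
distances; Q2: 21 weights on [−w, w] including 0, with ‖c‖₂ renormalized
after each acceptance — the coordinate's scale is physically meaningless and
the mfpt objective is reparametrization-invariant), re-evaluates the
coordinate incrementally, and accepts only strict improvements, so the
accepted-objective sequence is strictly increasing by construction and every
run replays exactly from its seed. The objective pipeline is equal-width
histogram → cut profile → diffusion profile → Kramers mfpt between basin
bottoms on the raw coordinate (no explicit natural transform is needed:
the quadrature is invariant). Equal-width bins were chosen over
equal-population bins after measuring that the latter under-resolve the
barrier top, where the Kramers integrand peaks, biasing event estimates ~2×
low at 24–32 bins.

**Degeneracy guard.** Unconstrained mfpt maximization diverges onto
rare-tail artifacts: a candidate that pushes a handful of frames far from
the bulk acquires a fake "barrier" with vanishing density whose Kramers
integral is enormous (observed: objective growth by 10³ onto a profile with
no real second basin). The optimizer therefore requires an interior barrier
with at least 10% of the equilibrium mass on each side of the transition
state (`min_basin_mass`), implementing the premise that an equilibrium
two-state trajectory populates both states substantially; direct calls to
`objective_mfpt` default to the permissive behavior (barrier-less profiles
get the full-range mfpt, flagged). An optional holdout mode (off by
default) optimizes on the first half of the trajectory and reports the
objective on the second.

## Synthetic generators: what they emulate, and what they do not

`simulate_doublewell`: overdamped Langevin dynamics dy = −D U′(y)dt +
√(2D)dW on U(y) = h[(2y/L)² − 1]² (Euler–Maruyama, numba; drift scaled by D
so exp(−U) is stationary for every D). Defaults h = 4 kT, L = 2, D = 1; a
construction-time check bounds the drift per step at a tenth of the well
scale, and escape beyond 10L raises with the step index (disabled for the
barrier-free case, which has no confining scale). It stands in for a long
equilibrium folding trajectory: two metastable basins and O(10²) barrier
crossings at the default lengths.

`simulate_two_state_atoms`: frames interpolate two packaged 8-atom reference
structures, (1−σ)A + σB with σ = logistic(s/w_s) of a hidden double-well
coordinate s(t), plus per-coordinate Ornstein–Uhlenbeck noise (scipy AR(1)
filtering). The fixture structures were constructed so that all 28 pairwise
distances change by 3.2–11.8 Å between A and B, change *monotonically*
along the interpolation, and no intra-structure distance falls below 2.5 Å;
every pair therefore carries signal and distance-based coordinates are
monotone reporters of the latent state. Defaults: latent saved every
0.002 τ (so the analysis strides sit in the barrier-top diffusive regime;
at 0.01 τ spacing the barrier drift biases α up to ~0.6), noise amplitude
0.5 Å with correlation time 10 frames (at ~2 frames the noise is already
saturated at the analysis strides and drags α down to ~0.43 even for the
ideal linear coordinate), 10⁶ frames, seed 7. What it does *not* emulate:
multi-basin landscapes with parallel pathways, chain connectivity,
excluded volume, or solvent memory — so passing tests show the estimators
and optimizer behave correctly when the ground truth is known, not that any
particular protein's dynamics is diffusive.

`simulate_fbm`: exact fractional Brownian motion by circulant embedding of
the fGn covariance (FFT synthesis; normalization validated against the
closed-form covariance), with a dense Cholesky fallback for n ≤ 4096 and an
explicit error, never a silent approximation, if neither applies. This is
the sub-diffusive reference: the exponent estimator must return α = H.

`scrambled_contact_coordinate` draws random-sign contact coordinates and
keeps the first draw whose profile retains a resolvable barrier with at
least 5% mass in the smaller basin — a fully scrambled coordinate usually
collapses the basins entirely, leaving nothing to analyze.

## Problem sizes

Default study sizes were chosen so every statistic is comfortably resolved:
2×10⁶ frames for the double-well exponent (≈70 barrier events), n = 2¹⁸ for
fBm recovery, 10⁶ frames / 8 atoms / ~60 round trips for the atomistic
system, with the optimizer running 3 sweeps over the 28-pair universe
(~10³ objective evaluations). Halving any of these degrades precision
roughly as √n but changes no conclusion.

## Known limitations

* The α estimator inherits a small upward bias at barrier tops when the
  sampling interval is large enough for the barrier drift to matter; the
  stride defaults keep this within ~0.03 on the packaged generators.
* Kramers event estimates on noisy projected coordinates retain a residual
  ~20% overestimate relative to ground truth even for near-optimal
  coordinates (projection noise both lowers the apparent barrier and
  inflates the apparent D); the directional contrasts (bad ≫ truth,
  optimized ≈ truth) are robust, the last ~20% is not a calibrated
  quantity.
* The natural-coordinate transform assumes D(x) varies slowly over one mean
  absolute displacement; reparametrizations with vanishing derivative
  (e.g. x³ at 0) violate this locally and leave an unsampled sliver in the
  image, which downstream quadrature masks rather than repairs.
* The optimizer is greedy coordinate ascent: it finds near-optimal members
  of the given family, with no claim of global optimality.
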
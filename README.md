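# difftrace

**Is the dynamics projected on your reaction coordinate diffusive — or is the
coordinate just bad?**

Molecular processes such as protein folding are routinely described as
one-dimensional diffusion on a free-energy profile F(x) along a reaction
coordinate x. Yet projections of the very same trajectory frequently look
*sub-diffusive* — the mean absolute displacement grows as Δt^α with
α < 1/2 — which is often taken as evidence that the underlying dynamics has
long memory. `difftrace` implements the alternative explanation: whether the
projection is diffusive or sub-diffusive depends on the *coordinate*. The
package measures the coordinate-dependent exponent α(x), constructs
near-optimal coordinates by maximizing the Kramers mean first passage time,
and provides seeded synthetic generators (overdamped Langevin double well,
two-state atomistic trajectories with a hidden folding coordinate, exact
fractional Brownian motion) so that every claim is testable against known
ground truth.

## The statistics at the core

For a trajectory x(t) sampled every Δt, two partition functions are
estimated along the coordinate:

* **histogram**: Z_H(x) = frames per bin, F_H = −ln Z_H (kT = 1);
* **cut-based**: Z_C(x; Δt) = half the number of sampled transitions through
  the level x, F_C = −ln Z_C. Z_C depends only on the *ordering* of values,
  so cut profiles are exactly invariant under monotone reparametrization.

Their ratio gives the mean absolute displacement ⟨|Δx|⟩(x) = 2 Z_C / Z̃_H and
hence a local diffusion coefficient D(x) = π⟨|Δx|⟩²/(4Δt); integrating
dy = dx/√D(x) maps the coordinate to its *natural* parametrization with
D ≡ 1. Because a fixed-length trajectory has Z_C ∝ Δt^(α−1), the anomalous
exponent follows from two strides:

    α(x) = 1 + [ln Z_C(x; k₂) − ln Z_C(x; k₁)] / ln(k₂/k₁),

with α = 1/2 for diffusion, < 1/2 for sub-diffusion, 1 in the ballistic
limit. At large Δt the barrier is crossed without detected recrossings and
Z_C(TS) saturates at the number of folding events Z_bal; approximating
ln Z_C(ln Δt) by a sloped line meeting that plateau at the ballistic time
t_bal yields the closed form

    α = 1 − [(−F_C(TS)) − ln Z_bal] / ln(t_bal/Δt₀),

so a *lower* barrier (worse coordinate) forces a *smaller* α: bad
coordinates are sub-diffusive. Kinetic consistency is checked through the
Kramers mean first passage time mfpt(a→b) = ∫ Φ/(Dρ) dy and the round-trip
identity n_events = T/(mfpt→ + mfpt←); the coordinate optimizer
(`difftrace.optimize`) maximizes this mfpt over contact-type (Q1) and
distance-combination (Q2) coordinate families by random-pair grid scans,
accepting only strict improvements.

## Worked example

Simulate an overdamped double well (barrier 4 kT, D = 1, 10⁶ saved frames)
and analyze it end to end:

```bash
difftrace simulate-doublewell --barrier 4 --n-steps 2000000 \
    --save-stride 2 --seed 42 --out dw.tsv
difftrace profile --series dw.tsv --stride 4 --out prof.tsv
difftrace alpha   --series dw.tsv --k1 4 --k2 8 --out alpha.tsv
difftrace mfpt    --series dw.tsv --stride 4 --out kin.json
```

`kin.json` then contains

```json
{
 "mfpt_forward": 16.68,
 "mfpt_backward": 17.29,
 "n_events_est": 58.88,
 "x_TS": -0.0136,
 "F_C_TS": -5.449,
 "barrier_height_kT": 4.020
}
```

— the transition state is found at the saddle (x ≈ 0), the cut free-energy
barrier reproduces the 4 kT of the input potential, and the estimated number
of barrier round trips (58.9 over the 2000 τ trajectory, i.e. one per ~34 τ)
agrees with the Kramers rate of this well. The α profile written to
`alpha.tsv` is ≈ 0.54 ± 0.03 at the barrier top: the projection of genuinely
Markovian dynamics onto the exact coordinate is diffusive. Projecting the
two-state atomistic generator onto a scrambled contact coordinate instead
(`difftrace simulate-twostate`, `difftrace project`, `difftrace optimize`)
gives α(TS) ≪ 1/2 and an event count inflated far above the true crossing
count, which mfpt-maximizing optimization repairs.

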
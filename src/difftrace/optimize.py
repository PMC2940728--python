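"""Stochastic coordinate-ascent construction of near-optimal reaction
coordinates.

A bad reaction coordinate overlaps distinct regions of configuration space,
which lowers the apparent folding barrier and makes the projected kinetics
spuriously fast; the optimum coordinate is therefore the one with the
*longest* Kramers mean first passage time.  The optimizer repeatedly picks a
random atom pair, scans that pair's parameter (sign and threshold for the
contact family; weight for the distance family) on a grid while holding the
rest of the coordinate fixed, and accepts the grid point only if it strictly
increases the objective.  Coordinate re-evaluation is incremental: the
contribution of the scanned pair is subtracted once and each grid point adds
its own back.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .coords import (AtomTrajectory, ContactCoordinateSpec,
                     DistanceCoordinateSpec, pair_distances)
from .profiles import (ScalarSeries, LevelGrid, histogram_profile, cut_profile,
                       diffusion_profile, equal_population_edges)
from .kinetics import (kramers_mfpt, locate_transition_state, basin_minima,
                       estimate_event_count)
from .subdiff import alpha_profile

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerConfig", "OptTrace", "AcceptedStep",
    "optimize_coordinate", "objective_mfpt", "diagnose_overfit",
]


@dataclass
class OptimizerConfig:
    family: str = "distances"            # "contacts" | "distances"
    objective: str = "mfpt"              # "mfpt" | "min_crossings"
    n_sweeps: int = 3
    proposals_per_sweep: int | None = None   # default: one per candidate pair
    grid_points: int = 12
    threshold_range: tuple[float, float] = (5.0, 95.0)  # percentiles of d_ij
    weight_range: float = 1.0
    n_bins: int = 32
    stride: int = 4
    seed: int = 0
    stall_limit: int = 200
    min_basin_mass: float = 0.1
    normalize_weights: bool = True
    holdout: bool = False                # optimize on first half, report on second

    def __post_init__(self) -> None:
        if self.family not in ("contacts", "distances"):
            raise ValueError("family must be 'contacts' or 'distances'")
        if self.objective not in ("mfpt", "min_crossings"):
            raise ValueError("objective must be 'mfpt' or 'min_crossings'")
        if self.n_sweeps < 1 or self.grid_points < 2:
            raise ValueError("positive sweep/grid counts required")
        lo, hi = self.threshold_range
        if not (0 < lo < hi < 100):
            raise ValueError("threshold_range must be percentiles in (0, 100)")


@dataclass
class AcceptedStep:
    proposal: int
    pair: tuple[int, int]
    params: dict
    objective: float


@dataclass
class OptTrace:
    steps: list[AcceptedStep]
    best_spec: object
    best_objective: float
    n_proposals: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def objectives(self) -> np.ndarray:
        return np.array([s.objective for s in self.steps])


def objective_mfpt(series: ScalarSeries, n_bins: int = 32, stride: int = 4,
                   objective: str = "mfpt",
                   min_basin_mass: float = 0.0) -> float | None:
    """Coordinate-quality objective from the series alone.

    Pipeline: equal-width histogram -> cut profile at the bin midpoints ->
    diffusion profile -> Kramers mfpt on the raw coordinate (the quadrature
    is reparametrization-invariant, so no explicit natural transform is
    needed; equal-width bins resolve the barrier top, where the Kramers
    integrand peaks, far better than equal-population bins).  The passage
    runs from the lower basin minimum of F_C to the upper one; on a
    barrier-less profile it runs edge to edge (flagged in the log).
    ``objective='min_crossings'`` returns -Z_C at the transition state
    instead.  Degenerate (near-constant) series give None.

    ``min_basin_mass > 0`` additionally demands an interior barrier with at
    least that equilibrium mass fraction on each side of the transition
    state.  Without this guard, unconstrained mfpt maximization can invent
    "barriers" out of rare tail excursions (vanishing density, vanishing
    apparent D) whose Kramers integral diverges — the over-fitting failure
    mode; a genuine two-state trajectory populates both basins substantially.
    """
    v = series.values
    if np.ptp(v) == 0:
        return None
    if np.unique(v[: min(v.size, 5000)]).size < 5:
        return None                     # too few distinct levels: degenerate
    hist = histogram_profile(series, n_bins)
    grid = LevelGrid(hist.midpoints)
    cut = cut_profile(series, grid, stride=stride)
    if (cut.z_cut > 0).sum() < 4:
        return None
    try:
        x_ts, a, b = basin_minima(cut, hist)
        barrier = True
    except ValueError:
        x_ts = None
        barrier = False
    if min_basin_mass > 0.0:
        if not barrier:
            return None
        phi_ts = float(hist.phi(x_ts))
        if min(phi_ts, 1.0 - phi_ts) < min_basin_mass:
            return None

    if objective == "min_crossings":
        if not barrier:
            return None
        zc = cut.z_cut[int(np.argmin(np.abs(grid.levels - x_ts)))]
        return -float(zc)

    diff = diffusion_profile(hist, cut)
    good = ~np.ma.getmaskarray(diff.diffusion)
    x = grid.levels
    if not barrier:
        logger.debug("barrier-less candidate: mfpt over the full range")
        gi = np.flatnonzero(good)
        if gi.size < 2:
            return None
        a, b = float(x[gi[0]]), float(x[gi[-1]])
    try:
        return kramers_mfpt(hist, diff, a, b, start="point")
    except ValueError:
        return None


def _eval_candidate(base: np.ndarray, contrib: np.ndarray, dt: float,
                    cfg: OptimizerConfig) -> float | None:
    cand = ScalarSeries(base + contrib, dt=dt)
    return objective_mfpt(cand, n_bins=cfg.n_bins, stride=cfg.stride,
                          objective=cfg.objective,
                          min_basin_mass=cfg.min_basin_mass)


def optimize_coordinate(traj: AtomTrajectory, init, cfg: OptimizerConfig,
                        candidate_pairs: list[tuple[int, int]] | None = None
                        ) -> OptTrace:
    """Random-pair grid-scan coordinate ascent on the mfpt objective.

    Fully seeded: re-running with the same trajectory, init and config
    reproduces the identical accepted-step sequence.  For the contact family
    the candidate set defaults to the init's own (native) pairs; for the
    distance family to the init's pair universe.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = copy.deepcopy(init)
    if candidate_pairs is None:
        candidate_pairs = list(spec.pairs)
    dmat = pair_distances(traj, candidate_pairs)      # (T, P)
    pair_index = {p: i for i, p in enumerate(candidate_pairs)}
    dt = traj.frame_spacing
    n_frames = traj.n_frames
    fit_slice = slice(0, n_frames // 2) if cfg.holdout else slice(0, n_frames)
    dfit = dmat[fit_slice]

    if cfg.family == "contacts":
        if not isinstance(spec, ContactCoordinateSpec):
            raise TypeError("contacts family needs a ContactCoordinateSpec init")
        params = {p: (int(s), float(r)) for p, s, r
                  in zip(spec.pairs, spec.signs, spec.thresholds)}
        def current_values():
            out = np.zeros(dfit.shape[0])
            for p, (s, r0) in params.items():
                out += s * (dfit[:, pair_index[p]] <= r0)
            return out
    else:
        if not isinstance(spec, DistanceCoordinateSpec):
            raise TypeError("distances family needs a DistanceCoordinateSpec init")
        params = {p: float(c) for p, c in zip(spec.pairs, spec.weights)}
        for p in candidate_pairs:
            params.setdefault(p, 0.0)
        def current_values():
            out = np.zeros(dfit.shape[0])
            for p, c in params.items():
                if c != 0.0:
                    out += c * dfit[:, pair_index[p]]
            return out

    values = current_values()
    incumbent = objective_mfpt(ScalarSeries(values, dt=dt), n_bins=cfg.n_bins,
                               stride=cfg.stride, objective=cfg.objective,
                               min_basin_mass=cfg.min_basin_mass)
    if incumbent is None:
        raise ValueError("initial coordinate is degenerate or barrier-less "
                         "beyond repair; objective undefined")

    steps: list[AcceptedStep] = []
    proposals_per_sweep = cfg.proposals_per_sweep or len(candidate_pairs)
    n_prop = 0
    stall = 0
    for sweep in range(cfg.n_sweeps):
        for _ in range(proposals_per_sweep):
            n_prop += 1
            p = candidate_pairs[int(rng.integers(len(candidate_pairs)))]
            col = dfit[:, pair_index[p]]
            best_obj, best_par = incumbent, None
            if cfg.family == "contacts":
                s_old, r_old = params[p]
                base = values - s_old * (col <= r_old)
                lo, hi = np.percentile(col, cfg.threshold_range)
                r_grid = np.linspace(lo, hi, cfg.grid_points)
                for s in (-1, 1):
                    for r0 in r_grid:
                        obj = _eval_candidate(base, s * (col <= r0), dt, cfg)
                        if obj is None:
                            logger.debug("degenerate candidate skipped "
                                         "(pair %s, s=%d, r0=%.3g)", p, s, r0)
                            continue
                        if obj > best_obj:
                            best_obj, best_par = obj, (s, float(r0))
                if best_par is not None:
                    s, r0 = best_par
                    values = base + s * (col <= r0)
                    params[p] = (s, r0)
            else:
                c_old = params[p]
                base = values - c_old * col
                c_grid = np.linspace(-cfg.weight_range, cfg.weight_range,
                                     cfg.grid_points)
                if 0.0 not in c_grid:
                    c_grid = np.sort(np.append(c_grid, 0.0))
                for c in c_grid:
                    obj = _eval_candidate(base, c * col, dt, cfg)
                    if obj is None:
                        logger.debug("degenerate candidate skipped "
                                     "(pair %s, c=%.3g)", p, c)
                        continue
                    if obj > best_obj:
                        best_obj, best_par = obj, float(c)
                if best_par is not None:
                    c = best_par
                    values = base + c * col
                    params[p] = c
                    if cfg.normalize_weights:
                        norm = math.sqrt(sum(ci * ci for ci in params.values()))
                        if norm > 0:
                            for q in params:
                                params[q] /= norm
                            values = values / norm

            if best_par is not None:
                incumbent = best_obj
                steps.append(AcceptedStep(
                    proposal=n_prop, pair=p,
                    params=({"sign": best_par[0], "threshold": best_par[1]}
                            if cfg.family == "contacts"
                            else {"weight": params[p]}),
                    objective=float(best_obj)))
                stall = 0
            else:
                stall += 1
                if stall >= cfg.stall_limit:
                    break
        if stall >= cfg.stall_limit:
            break

    objs = [s.objective for s in steps]
    assert all(b > a for a, b in zip(objs, objs[1:])), \
        "accepted objectives must be strictly increasing"

    if cfg.family == "contacts":
        plist = sorted(params)
        best_spec = ContactCoordinateSpec(
            pairs=plist,
            signs=np.array([params[p][0] for p in plist]),
            thresholds=np.array([params[p][1] for p in plist]))
    else:
        plist = sorted(p for p in params if params[p] != 0.0)
        if not plist:
            plist = sorted(params)[:1]
        best_spec = DistanceCoordinateSpec(
            pairs=plist, weights=np.array([params[p] for p in plist]))

    diagnostics = {}
    if cfg.holdout:
        hold = dmat[n_frames // 2:]
        if cfg.family == "contacts":
            hv = sum(params[p][0] * (hold[:, pair_index[p]] <= params[p][1])
                     for p in params)
        else:
            hv = sum(params[p] * hold[:, pair_index[p]] for p in params
                     if params[p] != 0.0)
        diagnostics["holdout_objective"] = objective_mfpt(
            ScalarSeries(np.asarray(hv, float), dt=dt), n_bins=cfg.n_bins,
            stride=cfg.stride, objective=cfg.objective)

    return OptTrace(steps=steps, best_spec=best_spec,
                    best_objective=float(incumbent), n_proposals=n_prop,
                    seed=cfg.seed, diagnostics=diagnostics)


def diagnose_overfit(trace: OptTrace, series: ScalarSeries, n_bins: int = 32,
                     strides: tuple[int, int] = (4, 8),
                     kinetics_stride: int | None = None,
                     true_events: float | None = None,
                     seed: int = 0) -> dict:
    """Superdiffusion flags and kinetic consistency for an optimized coordinate.

    alpha > 1/2 beyond two standard errors cannot arise from projecting
    Markovian dynamics and indicates the coordinate has over-fit the finite
    trajectory.  If the true transition count is supplied, the Kramers event
    estimate is compared against it.
    """
    if not trace.steps and trace.best_spec is None:
        return {"flags": [], "alpha_ts": None}
    hist = histogram_profile(series, n_bins)
    grid = LevelGrid(hist.midpoints)
    alpha = alpha_profile(series, grid, *strides, seed=seed)
    flags = []
    a = alpha.alpha
    se = alpha.stderr
    for i, lvl in enumerate(grid.levels):
        if not a.mask[i] and a[i] > 0.5 + 2.0 * se[i]:
            flags.append({"level": float(lvl), "alpha": float(a[i]),
                          "se": float(se[i])})
    report = {"flags": flags, "alpha_ts": None, "barrier_kt": None}
    # D estimation uses the larger stride by default: at sampling intervals
    # beyond any fast-noise correlation time the displacement is dominated
    # by motion along the coordinate, not by projection noise
    cut = cut_profile(series, grid,
                      stride=kinetics_stride or strides[1])
    try:
        x_ts, lo, hi = basin_minima(cut, hist)
        idx = int(np.argmin(np.abs(grid.levels - x_ts)))
        report["alpha_ts"] = None if a.mask[idx] else float(a[idx])
        report["alpha_ts_se"] = None if se.mask[idx] else float(se[idx])
        f = cut.free_energy
        good = ~np.ma.getmaskarray(f)
        report["barrier_kt"] = float(f[idx] - f[good].min())
        diff = diffusion_profile(hist, cut)
        fwd = kramers_mfpt(hist, diff, lo, hi, start="basin_average",
                           x_split=x_ts)
        bwd = kramers_mfpt(hist, diff, hi, lo, start="basin_average",
                           x_split=x_ts)
        report["n_events_est"] = estimate_event_count(fwd, bwd, series.duration)
        if true_events is not None:
            report["true_events"] = float(true_events)
            report["event_ratio"] = report["n_events_est"] / true_events
    except ValueError as exc:
        report["kinetics_error"] = str(exc)
    return report
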
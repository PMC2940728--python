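"""Kramers first-passage kinetics on a binned free-energy profile.

For one-dimensional diffusion with reflecting boundary at the data edge on
the source side and absorbing target b, the mean first passage time is

    mfpt(a -> b) = int_a^b dy Phi(y) / (D(y) rho(y))

with rho the equilibrium density and Phi the cumulative mass accumulated from
the reflecting boundary.  On the natural coordinate D = 1 and the profile
alone determines the kinetics; the round-trip identity
``n_events = duration / (mfpt_fwd + mfpt_bwd)`` turns the two basin-averaged
mfpts into an estimated number of folding events, a direct consistency check
of a putative reaction coordinate against the true transition count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .profiles import HistProfile, CutProfile, DiffusionProfile

__all__ = [
    "BasinSpec", "MfptResult",
    "kramers_mfpt", "mfpt_profile", "estimate_event_count",
    "locate_transition_state", "basin_minima", "first_passage_times",
]


@dataclass
class BasinSpec:
    """Source/target intervals and the transition-state level between them."""
    source: tuple[float, float]
    target: tuple[float, float]
    x_ts: float
    mode: str = "user"

    def __post_init__(self) -> None:
        s_lo, s_hi = self.source
        t_lo, t_hi = self.target
        if s_hi <= s_lo or t_hi <= t_lo:
            raise ValueError("intervals must be non-empty")
        if not (s_hi <= t_lo or t_hi <= s_lo):
            raise ValueError("source and target intervals must be disjoint")
        lo = min(s_hi, t_hi)
        hi = max(s_lo, t_lo)
        if not (lo < self.x_ts < hi):
            raise ValueError("x_ts must lie strictly between the intervals")


@dataclass
class MfptResult:
    mfpt_forward: float
    mfpt_backward: float
    n_events_est: float
    integration_range: tuple[float, float]
    n_masked_bins: int


def _profile_arrays(hist: HistProfile, diffusion) -> tuple[np.ndarray, ...]:
    """Midpoints, widths, density and D per bin; masked bins flagged."""
    x = hist.midpoints
    w = hist.widths
    rho = hist.density
    if isinstance(diffusion, DiffusionProfile):
        if diffusion.levels.size != x.size or not np.allclose(diffusion.levels, x):
            raise ValueError("diffusion profile grid does not match histogram")
        d = diffusion.diffusion.filled(0.0)
        bad = np.ma.getmaskarray(diffusion.diffusion) | (rho <= 0)
    else:
        d = np.full(x.size, float(diffusion))
        if float(diffusion) <= 0:
            raise ValueError("diffusion coefficient must be positive")
        bad = rho <= 0
    return x, w, rho, d, bad


def _bridge_interior(x: np.ndarray, vals: np.ndarray, bad: np.ndarray,
                     max_gap: int) -> np.ndarray:
    """Linear interpolation across interior masked bins; wide gaps error."""
    if not bad.any():
        return vals
    good = ~bad
    idx = np.flatnonzero(good)
    runs = np.split(np.flatnonzero(bad),
                    np.flatnonzero(np.diff(np.flatnonzero(bad)) > 1) + 1)
    for run in runs:
        if run.size == 0:
            continue
        interior = run[0] > idx[0] and run[-1] < idx[-1]
        if interior and run.size > max_gap:
            raise ValueError(
                f"masked gap of {run.size} bins inside the integration range "
                f"(levels {x[run[0]]:.4g}..{x[run[-1]]:.4g})")
    out = vals.copy()
    out[bad] = np.interp(x[bad], x[good], vals[good])
    return out


def mfpt_profile(hist: HistProfile, diffusion, b: float, toward_right: bool = True,
                 max_gap: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """mfpt(y -> b) for every bin midpoint y on the reflecting side of b.

    The reflecting boundary sits at the data edge opposite to b; entries on
    the far side of b are clipped at 0.
    """
    x, w, rho, d, bad = _profile_arrays(hist, diffusion)
    if not (hist.bin_edges[0] <= b <= hist.bin_edges[-1]):
        raise ValueError(f"target {b} outside the profile range")
    knots, T = _mfpt_cumulative(x, w, rho, d, bad, b, max_gap, toward_right)
    tb = np.interp(b, knots, T)
    # the mirrored cumulative is returned re-aligned with ascending x, so
    # mfpt(y -> b) = T(b) - T(y) in both directions
    return x, np.maximum(tb - np.interp(x, knots, T), 0.0)


def _mfpt_cumulative(x, w, rho, d, bad, b, max_gap, toward_right=True):
    """T evaluated at the midpoint grid: cumulative of Phi/(D rho) from the
    reflecting edge, midpoint rule per bin (exact for linear integrands);
    mfpt(y->b) = T(b) - T(y) for y on the reflecting side of b."""
    if not toward_right:
        # mirror the profile, reuse the rightward machinery
        knots, T = _mfpt_cumulative(x[::-1] * -1, w[::-1], rho[::-1], d[::-1],
                                    bad[::-1], -b, max_gap, True)
        return -knots[::-1], T[::-1]
    rho_b = _bridge_interior(x, np.where(bad, 0.0, rho), bad, max_gap)
    d_b = _bridge_interior(x, np.where(bad, 1.0, d), bad, max_gap)
    mass = rho_b * w
    phi = np.cumsum(mass) - 0.5 * mass       # cumulative mass at midpoints
    total = mass.sum()
    phi = phi / total                          # normalize the used range
    rho_n = rho_b / total
    integrand = phi / (d_b * np.maximum(rho_n, 1e-300))
    # accumulate full bins (midpoint rule), report at midpoints and at the
    # two terminal edges so interpolation covers the whole data range
    T_mid = np.concatenate([[0.0], np.cumsum(integrand * w)])[:-1] \
        + 0.5 * integrand * w
    knots = np.concatenate([[x[0] - 0.5 * w[0]], x, [x[-1] + 0.5 * w[-1]]])
    T = np.concatenate([[0.0], T_mid, [np.sum(integrand * w)]])
    return knots, T


def kramers_mfpt(hist: HistProfile, diffusion, a: float, b: float,
                 start: str = "point", x_split: float | None = None,
                 max_gap: int = 3) -> float:
    """Mean first passage time a -> b by quadrature over the binned profile.

    ``diffusion`` is a constant (use 1.0 on the natural coordinate) or a
    DiffusionProfile on the same grid.  ``start='point'`` integrates from the
    single level a; ``start='basin_average'`` averages the start point over
    the equilibrium weight of the source basin (all bins on a's side of
    ``x_split``, default the midpoint between a and b) — the convention under
    which the round-trip identity holds.
    """
    if a == b:
        return 0.0
    x, w, rho, d, bad = _profile_arrays(hist, diffusion)
    lo_edge, hi_edge = hist.bin_edges[0], hist.bin_edges[-1]
    for point, name in ((a, "a"), (b, "b")):
        if not (lo_edge <= point <= hi_edge):
            raise ValueError(f"{name} = {point} outside profile range "
                             f"[{lo_edge:.4g}, {hi_edge:.4g}]")
    toward_right = b > a
    knots, T = _mfpt_cumulative(x, w, rho, d, bad, b, max_gap, toward_right)
    tb = float(np.interp(b, knots, T))

    def tau_from(y: float) -> float:
        # mirrored cumulative is re-aligned with ascending x, so the same
        # T(b) - T(y) holds in both directions
        return tb - float(np.interp(y, knots, T))

    if start == "point":
        return max(tau_from(a), 0.0)
    if start == "basin_average":
        split = x_split if x_split is not None else 0.5 * (a + b)
        if toward_right:
            sel = (x <= split) & ~bad
        else:
            sel = (x >= split) & ~bad
        if not sel.any():
            raise ValueError("empty source basin for basin_average start")
        weights = rho[sel] * w[sel]
        taus = np.array([tau_from(y) for y in x[sel]])
        return float(np.sum(weights * np.maximum(taus, 0.0)) / weights.sum())
    raise ValueError(f"unknown start convention {start!r}")


def estimate_event_count(mfpt_fwd: float, mfpt_bwd: float,
                         duration: float) -> float:
    """Estimated folding events: round trips per trajectory duration."""
    if mfpt_fwd <= 0 or mfpt_bwd <= 0 or duration <= 0:
        raise ValueError("mfpts and duration must be positive")
    return duration / (mfpt_fwd + mfpt_bwd)


def locate_transition_state(cut: CutProfile, basins: BasinSpec | None = None) -> float:
    """Transition state: the F_C maximum (Z_C minimum) between the two
    deepest F_C minima.  Ties resolve to the midpoint of the tied plateau."""
    if basins is not None:
        lo = min(basins.source[1], basins.target[1])
        hi = max(basins.source[0], basins.target[0])
        sel = (cut.levels >= lo) & (cut.levels <= hi) & (cut.z_cut > 0)
        if not sel.any():
            raise ValueError("no supported levels between the basins")
        x = cut.levels[sel]
        f = -np.log(cut.z_cut[sel])
        top = f.max()
        tied = np.flatnonzero(f >= top - 1e-12)
        return float(x[tied[(tied.size - 1) // 2]])

    good = cut.z_cut > 0
    x = cut.levels[good]
    f = -np.log(cut.z_cut[good])
    if x.size < 3:
        raise ValueError("cut profile supported on fewer than 3 levels")
    # basin 1: the global F_C minimum; basin 2: the local minimum whose
    # separating barrier from basin 1 is highest (robust to noise wiggles,
    # which produce adjacent shallow minima with near-zero barriers)
    i1 = int(np.argmin(f))
    minima = [i for i in range(x.size)
              if f[i] <= (f[i - 1] if i > 0 else np.inf)
              and f[i] <= (f[i + 1] if i < x.size - 1 else np.inf)]
    best_barrier, i2 = 0.0, None
    for m in minima:
        lo_i, hi_i = min(i1, m), max(i1, m)
        if hi_i - lo_i < 2:
            continue
        interior_top = f[lo_i + 1:hi_i].max()
        barrier = interior_top - max(f[i1], f[m])
        if barrier > best_barrier + 1e-12:
            best_barrier, i2 = barrier, m
    if i2 is None:
        raise ValueError("barrier-less profile: no interior maximum between "
                         "two basins")
    lo_i, hi_i = min(i1, i2), max(i1, i2)
    fseg = f[lo_i + 1:hi_i]
    top = fseg.max()
    tied = np.flatnonzero(fseg >= top - 1e-12)
    pick = tied[(tied.size - 1) // 2]
    return float(x[lo_i + 1:hi_i][pick])


def basin_minima(cut: CutProfile,
                 hist: HistProfile | None = None) -> tuple[float, float, float]:
    """Transition state and the basin-bottom levels flanking it: (x_ts, a, b).

    With a histogram, basins are the two most populated density peaks and
    the TS is the F_C maximum between them — robust for coordinates (e.g.
    integer-valued contact counts) that concentrate a basin on one or two
    levels, where F_C has no local minimum.  Without a histogram, basins are
    the two deepest F_C minima.  a and b are basin bottoms, the natural
    endpoints for Kramers passage integrals (the rarely-visited extreme data
    edges would inflate the mfpt through the vanishing-density tail).
    """
    if hist is None:
        x_ts = locate_transition_state(cut)
        x = cut.levels
        f = cut.free_energy
        good = ~np.ma.getmaskarray(f)
        fl = np.where(good & (x < x_ts), f.data, np.inf)
        fr = np.where(good & (x > x_ts), f.data, np.inf)
        return x_ts, float(x[np.argmin(fl)]), float(x[np.argmin(fr)])

    x = hist.midpoints
    if x.size != cut.levels.size or not np.allclose(x, cut.levels):
        raise ValueError("cut levels must match the histogram midpoints")
    c = hist.counts.astype(float)
    # local density maxima (plateau-tolerant), candidate basin bottoms
    peaks = [i for i in range(x.size)
             if c[i] > 0
             and c[i] >= (c[i - 1] if i > 0 else -1)
             and c[i] >= (c[i + 1] if i < x.size - 1 else -1)]
    if len(peaks) < 2:
        raise ValueError("barrier-less profile: fewer than two density peaks")
    i1 = max(peaks, key=lambda i: c[i])
    f = cut.free_energy
    good = ~np.ma.getmaskarray(f)
    best, i2 = 0.0, None
    for m in peaks:
        lo_i, hi_i = min(i1, m), max(i1, m)
        if hi_i - lo_i < 2 or c[m] < 0.02 * hist.n_frames:
            continue
        seg = np.flatnonzero(good[lo_i + 1:hi_i])
        if seg.size == 0 or not (good[lo_i] and good[hi_i]):
            continue
        # basin prominence: the density must dip substantially between the
        # two peaks, otherwise histogram noise on a unimodal (or flat)
        # profile would fabricate a transition state
        dip = c[lo_i + 1:hi_i].min()
        if dip > 0.75 * min(c[i1], c[m]):
            continue
        # among prominent second basins, take the most populated
        if c[m] > best:
            best, i2 = c[m], m
    if i2 is None:
        raise ValueError("barrier-less profile: no prominent second basin "
                         "with an interior F_C maximum")
    lo_i, hi_i = min(i1, i2), max(i1, i2)
    seg_idx = np.flatnonzero(good[lo_i + 1:hi_i]) + lo_i + 1
    fseg = f.data[seg_idx]
    tied = np.flatnonzero(fseg >= fseg.max() - 1e-12)
    x_ts = float(x[seg_idx[tied[(tied.size - 1) // 2]]])
    return x_ts, float(x[min(i1, i2)]), float(x[max(i1, i2)])


def first_passage_times(values: np.ndarray, a: float, b: float,
                        dt: float = 1.0) -> np.ndarray:
    """Direct first-passage times from region 'at a' to region 'past b'.

    For a < b: a passage starts when the series first visits <= a after the
    previous completion and ends when it next reaches >= b (mirrored for
    a > b).  Used as the simulation-side oracle for the Kramers quadrature.
    """
    v = np.asarray(values, float)
    if a == b:
        raise ValueError("a and b must differ")
    if a < b:
        at_a = np.flatnonzero(v <= a)
        at_b = np.flatnonzero(v >= b)
    else:
        at_a = np.flatnonzero(v >= a)
        at_b = np.flatnonzero(v <= b)
    times = []
    t = 0
    while True:
        i = np.searchsorted(at_a, t)
        if i >= at_a.size:
            break
        t_start = at_a[i]
        j = np.searchsorted(at_b, t_start)
        if j >= at_b.size:
            break
        t_end = at_b[j]
        times.append(t_end - t_start)
        t = t_end + 1
    return np.asarray(times, float) * dt
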
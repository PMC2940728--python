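"""Histogram and cut-based free-energy profiles along a reaction coordinate.

Two partition functions are estimated from a scalar time series x(t):

* the conventional (histogram) partition function ``Z_H``, the number of
  frames per bin, giving the free energy ``F_H = -ln Z_H`` (kT = 1);
* the cut partition function ``Z_C(x)``, half the number of transitions of
  the sampled series through the level x, giving ``F_C = -ln Z_C``.

``Z_C`` depends only on the *ordering* of the series values relative to the
level, so cut profiles are exactly invariant under strictly monotone
reparametrizations of the coordinate.  Combining the two profiles yields the
mean absolute displacement per sampling interval and hence a
position-dependent diffusion coefficient; integrating ``1/sqrt(D)`` maps the
coordinate to its *natural* parametrization in which D = 1 everywhere.

Units: free energies in kT, time in units of the frame spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ScalarSeries",
    "LevelGrid",
    "HistProfile",
    "CutProfile",
    "DiffusionProfile",
    "MonotoneMap",
    "histogram_profile",
    "equal_population_edges",
    "cut_profile",
    "cut_at_level",
    "diffusion_profile",
    "natural_transform",
    "cumulative_coordinate",
]


@dataclass
class ScalarSeries:
    """A uniformly sampled scalar reaction-coordinate time series.

    Parameters
    ----------
    values : array-like of float
        Coordinate value per saved frame.  Must be finite, length >= 2.
    dt : float
        Time per frame in whatever unit the caller uses (default 1; all
        downstream quantities are reported in these units).
    meta : dict
        Free-form provenance (generator parameters, seed, ...).
    """

    values: np.ndarray
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("series must be 1-D with at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total trajectory duration in time units."""
        return (len(self) - 1) * self.dt

    def transformed(self, func: Callable[[np.ndarray], np.ndarray]) -> "ScalarSeries":
        """Apply a (monotone) map to the values, keeping dt and meta."""
        return ScalarSeries(func(self.values), dt=self.dt, meta=dict(self.meta))


@dataclass
class LevelGrid:
    """Strictly increasing set of levels at which cut profiles are evaluated."""

    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.size < 3:
            raise ValueError("need at least 3 levels")
        if not np.all(np.diff(self.levels) > 0):
            raise ValueError("levels must be strictly increasing")

    @classmethod
    def from_series(cls, series: ScalarSeries, n_levels: int = 50) -> "LevelGrid":
        """Equal-width levels at bin midpoints spanning the series range."""
        edges = np.linspace(series.values.min(), series.values.max(), n_levels + 1)
        return cls(0.5 * (edges[:-1] + edges[1:]))


@dataclass
class HistProfile:
    """Histogram partition function Z_H and free energy F_H = -ln Z_H (kT=1)."""

    bin_edges: np.ndarray
    counts: np.ndarray            # Z_H per bin
    n_frames: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_frames:
            raise ValueError("histogram does not conserve frame count")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def density(self) -> np.ndarray:
        """z_H: probability density per bin (counts / (n_frames * width))."""
        return self.counts / (self.n_frames * self.widths)

    @property
    def frames_per_length(self) -> np.ndarray:
        """Z~_H: frames per unit coordinate length at each bin."""
        return self.counts / self.widths

    @property
    def free_energy(self) -> np.ma.MaskedArray:
        """F_H = -ln(counts), masked (not infinite) on empty bins."""
        with np.errstate(divide="ignore"):
            f = -np.log(self.counts.astype(float))
        return np.ma.masked_array(f, mask=self.counts == 0)

    @property
    def phi_edges(self) -> np.ndarray:
        """Cumulative fraction of frames left of each bin edge."""
        return np.concatenate([[0.0], np.cumsum(self.counts)]) / self.n_frames

    def phi(self, x) -> np.ndarray:
        """Cumulative mass Phi(x): fraction of frames left of x (interpolated
        linearly within bins; 0 / 1 outside the data range)."""
        return np.interp(x, self.bin_edges, self.phi_edges, left=0.0, right=1.0)


@dataclass
class CutProfile:
    """Cut partition function Z_C on a level grid at sampling stride k.

    ``Z_C(x)`` is half the number of index pairs (t, t + k) whose values
    straddle the level x.  In ``offset_mode='average'`` all k phase offsets
    are used and the count is divided by k (per-phase normalization); in
    ``'single'`` only phase 0 is used, without that factor.  A frame exactly
    at the level is assigned to the left side.
    """

    levels: np.ndarray
    z_cut: np.ndarray
    stride: int
    dt_base: float = 1.0
    offset_mode: str = "average"
    n_pairs_used: int = 0
    raw_crossings: np.ndarray | None = None  # un-normalized alternation count

    @property
    def dt_sampling(self) -> float:
        """Effective sampling interval Delta-t = stride * dt."""
        return self.stride * self.dt_base

    @property
    def free_energy(self) -> np.ma.MaskedArray:
        """F_C = -ln Z_C, masked where Z_C = 0."""
        with np.errstate(divide="ignore"):
            f = -np.log(self.z_cut)
        return np.ma.masked_array(f, mask=self.z_cut == 0)


@dataclass
class DiffusionProfile:
    """Position-dependent diffusion coefficient from Z_C / Z~_H.

    The mean absolute displacement over the sampling interval at level x is
    ``<|dx|>(x) = 2 Z_C(x) / Z~_H(x)`` (with Z~_H the frames-per-length of
    the sampled series); for diffusive dynamics ``<|dx|> = sqrt(4 D dt / pi)``
    so ``D(x) = pi <|dx|>^2 / (4 dt)``.
    """

    levels: np.ndarray
    mad: np.ma.MaskedArray        # mean absolute displacement per sampling interval
    diffusion: np.ma.MaskedArray  # D(x)
    dt_sampling: float


class MonotoneMap:
    """A monotone map defined by matching source/image knots, with linear
    interpolation inside the range and linear edge extrapolation outside."""

    def __init__(self, x: np.ndarray, y: np.ndarray, strict: bool = True):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.size != y.size or x.size < 2:
            raise ValueError("need matching knot arrays of length >= 2")
        if not np.all(np.diff(x) > 0):
            raise ValueError("source knots must be strictly increasing")
        dy = np.diff(y)
        if strict and not np.all(dy > 0):
            raise ValueError("image knots not strictly increasing: "
                             "internal-consistency error (non-positive D leaked through)")
        if np.any(dy < 0):
            raise ValueError("image knots must be non-decreasing")
        self.x = x
        self.y = y
        self._strict = bool(np.all(dy > 0))

    def __call__(self, x) -> np.ndarray:
        return self.forward(x)

    def forward(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        out = np.interp(x, self.x, self.y)
        # linear extrapolation with the edge slopes keeps strict monotonicity
        slope_lo = (self.y[1] - self.y[0]) / (self.x[1] - self.x[0])
        slope_hi = (self.y[-1] - self.y[-2]) / (self.x[-1] - self.x[-2])
        out = np.where(x < self.x[0], self.y[0] + (x - self.x[0]) * slope_lo, out)
        out = np.where(x > self.x[-1], self.y[-1] + (x - self.x[-1]) * slope_hi, out)
        return out if out.ndim else float(out)

    def inverse(self, y) -> np.ndarray:
        if not self._strict:
            raise ValueError("map has flat segments; inverse undefined")
        y = np.asarray(y, float)
        out = np.interp(y, self.y, self.x)
        slope_lo = (self.x[1] - self.x[0]) / (self.y[1] - self.y[0])
        slope_hi = (self.x[-1] - self.x[-2]) / (self.y[-1] - self.y[-2])
        out = np.where(y < self.y[0], self.x[0] + (y - self.y[0]) * slope_lo, out)
        out = np.where(y > self.y[-1], self.x[-1] + (y - self.y[-1]) * slope_hi, out)
        return out if out.ndim else float(out)


def histogram_profile(series: ScalarSeries,
                      bins: int | Sequence[float] = 50) -> HistProfile:
    """Histogram partition function of a series.

    ``bins`` is either a bin count (>= 3, equal width over the data range)
    or an explicit edge sequence.
    """
    v = series.values
    if np.isscalar(bins):
        if int(bins) < 3:
            raise ValueError("need at least 3 bins")
        lo, hi = v.min(), v.max()
        if lo == hi:  # constant series: give it a non-degenerate range
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, float)
        if edges.size < 3 or not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing, >= 3 values")
    counts, edges = np.histogram(v, bins=edges)
    # frames outside explicit edges are dropped; conserve the count we used
    return HistProfile(bin_edges=edges, counts=counts, n_frames=int(counts.sum()))


def equal_population_edges(series: ScalarSeries, n_bins: int) -> np.ndarray:
    """Bin edges with (approximately) equal frame counts per bin."""
    qs = np.linspace(0, 100, n_bins + 1)
    edges = np.percentile(series.values, qs)
    edges = np.unique(edges)
    if edges.size < 4:
        raise ValueError("series too degenerate for equal-population binning")
    return edges


def _alternation_counts(values: np.ndarray, levels: np.ndarray, k: int) -> np.ndarray:
    """Number of pairs (t, t+k) straddling each level, all phases.

    A value exactly equal to a level is assigned to the left side, so a pair
    crosses level L iff min(pair) <= L < max(pair).
    """
    a = values[:-k]
    b = values[k:]
    lo = np.sort(np.minimum(a, b))
    hi = np.sort(np.maximum(a, b))
    n_lo = np.searchsorted(lo, levels, side="right")
    n_hi = np.searchsorted(hi, levels, side="right")
    return (n_lo - n_hi).astype(np.int64)


def cut_profile(series: ScalarSeries, grid: LevelGrid, stride: int = 1,
                offset_mode: str = "average") -> CutProfile:
    """Cut partition function Z_C of a series on a level grid.

    For ``offset_mode='average'`` (default) all k phase offsets contribute and
    Z_C = (1/2)(1/k) * (number of straddling pairs (t, t+k)); ``'single'``
    uses phase 0 only (frames 0, k, 2k, ...) without the 1/k factor.
    Levels outside the data range get Z_C = 0 (the profile is simply zero
    there, no error).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(series)
    if stride >= n // 4 + 1 and n >= 8:
        raise ValueError(f"stride {stride} too large for series of length {n}")
    v = series.values
    levels = grid.levels
    if offset_mode == "average":
        raw = _alternation_counts(v, levels, stride)
        z = raw / (2.0 * stride)
        n_pairs = n - stride
    elif offset_mode == "single":
        sub = v[::stride]
        if sub.size < 2:
            raise ValueError("stride leaves fewer than 2 frames")
        raw = _alternation_counts(sub, levels, 1)
        z = raw / 2.0
        n_pairs = sub.size - 1
    else:
        raise ValueError(f"unknown offset_mode {offset_mode!r}")
    return CutProfile(levels=levels, z_cut=z, stride=stride, dt_base=series.dt,
                      offset_mode=offset_mode, n_pairs_used=n_pairs,
                      raw_crossings=raw)


def cut_at_level(series: ScalarSeries, level: float, stride: int = 1) -> float:
    """Offset-averaged Z_C at a single level (convenience for scans)."""
    v = series.values
    a, b = v[:-stride], v[stride:]
    lvl = float(level)
    raw = int(np.count_nonzero((np.minimum(a, b) <= lvl) & (np.maximum(a, b) > lvl)))
    return raw / (2.0 * stride)


def diffusion_profile(hist: HistProfile, cut: CutProfile) -> DiffusionProfile:
    """Position-dependent diffusion coefficient from matched hist/cut profiles.

    Requires the cut levels to be the histogram bin midpoints (same series,
    same frame set).  Masked where either profile is unsupported.
    """
    mids = hist.midpoints
    if mids.size != cut.levels.size or not np.allclose(mids, cut.levels):
        raise ValueError("cut levels must be the histogram bin midpoints")
    # frames-per-length of the series sampled at the cut's stride: the
    # offset-averaged Z_C is already per-phase, so divide the full-series
    # count by the stride to stay consistent.
    z_tilde = hist.frames_per_length / cut.stride
    bad = (hist.counts == 0) | (cut.z_cut <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mad = 2.0 * cut.z_cut / z_tilde
        diff = math.pi * mad ** 2 / (4.0 * cut.dt_sampling)
    mad = np.ma.masked_array(np.where(bad, 0.0, mad), mask=bad)
    diff = np.ma.masked_array(np.where(bad, 0.0, diff), mask=bad)
    return DiffusionProfile(levels=mids, mad=mad, diffusion=diff,
                            dt_sampling=cut.dt_sampling)


def natural_transform(series: ScalarSeries, hist: HistProfile,
                      cut: CutProfile) -> tuple[MonotoneMap, ScalarSeries]:
    """Map the coordinate to its natural parametrization, where D(y) = 1.

    The image levels are ``y(x) = integral dx' / sqrt(D(x'))`` (trapezoidal
    over the level midpoints).  Interior levels with masked D are bridged by
    linear interpolation of 1/sqrt(D); terminal masked levels are truncated.
    Returns the map and the mapped series.
    """
    dp = diffusion_profile(hist, cut)
    d = dp.diffusion
    good = ~np.ma.getmaskarray(d)
    if good.sum() < 2:
        raise ValueError("diffusion profile supported on fewer than 2 levels")
    idx = np.flatnonzero(good)
    first, last = idx[0], idx[-1]
    x = dp.levels[first:last + 1]
    inv_sqrt = np.empty_like(x)
    seg_good = good[first:last + 1]
    inv_sqrt[seg_good] = 1.0 / np.sqrt(d.data[first:last + 1][seg_good])
    if not seg_good.all():  # bridge interior gaps
        inv_sqrt[~seg_good] = np.interp(x[~seg_good], x[seg_good],
                                        inv_sqrt[seg_good])
    mid_inv = 0.5 * (inv_sqrt[:-1] + inv_sqrt[1:])
    y = np.concatenate([[0.0], np.cumsum(mid_inv * np.diff(x))])
    nat_map = MonotoneMap(x, y, strict=True)
    mapped = ScalarSeries(nat_map.forward(series.values), dt=series.dt,
                          meta={**series.meta, "coordinate": "natural"})
    return nat_map, mapped


def cumulative_coordinate(hist: HistProfile) -> MonotoneMap:
    """The invariant cumulative coordinate z(x) = Phi(x).

    z measures the fraction of the equilibrium partition function to the left
    of x, so a profile plotted against z is invariant under any monotone
    reparametrization of the original coordinate.  The map may contain flat
    segments over empty bins (its inverse is then undefined).
    """
    return MonotoneMap(hist.bin_edges, hist.phi_edges, strict=False)
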
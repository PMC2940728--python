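"""Synthetic trajectory generators with known ground truth.

Three processes, each fully seeded:

* overdamped Langevin dynamics in a quartic double well (the diffusive
  reference, and the latent "folding" coordinate of the atomistic generator);
* a two-state atomistic trajectory whose frames interpolate between two
  reference structures under a hidden double-well coordinate, with
  Ornstein-Uhlenbeck positional noise — so that projections onto bad
  coordinates acquire memory while the latent coordinate stays diffusive;
* exact fractional Brownian motion (circulant embedding), the sub-diffusive
  reference with a known Hurst exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .coords import AtomTrajectory
from .profiles import ScalarSeries

__all__ = [
    "DoubleWellConfig",
    "TwoStateAtomsConfig",
    "FbmConfig",
    "simulate_doublewell",
    "simulate_two_state_atoms",
    "simulate_fbm",
    "quartic_potential",
    "hysteresis_transition_count",
    "toy_structures",
]


def quartic_potential(y, barrier_height: float, well_separation: float):
    """U(y) = h * ((2y/L)^2 - 1)^2: minima at +-L/2, barrier h at y = 0 (kT)."""
    u = 2.0 * np.asarray(y, float) / well_separation
    return barrier_height * (u * u - 1.0) ** 2


@dataclass
class DoubleWellConfig:
    """Overdamped Langevin dynamics on a symmetric quartic double well.

    ``n_steps`` counts Euler-Maruyama integration steps of size
    ``dt_integrate``; every ``save_stride``-th position is kept, so the saved
    frame spacing is ``dt_integrate * save_stride`` (recorded on the series).
    ``barrier_height`` is in kT; ``diffusion_coeff`` in length^2/time.
    """

    barrier_height: float = 4.0
    well_separation: float = 2.0
    diffusion_coeff: float = 1.0
    n_steps: int = 1_000_000
    dt_integrate: float = 1e-3
    save_stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        if self.well_separation <= 0:
            raise ValueError("well_separation must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")
        if self.dt_integrate <= 0 or self.diffusion_coeff <= 0:
            raise ValueError("dt_integrate and diffusion_coeff must be positive")
        # stability: drift per step must stay well below the well scale,
        # checked over |y| <= well_separation (u in [-2, 2], max|U'| there)
        h, L = self.barrier_height, self.well_separation
        max_force = (8.0 * h / L) * 2.0 * 3.0 if h > 0 else 0.0
        if self.dt_integrate * self.diffusion_coeff * max_force >= L / 10.0:
            raise ValueError(
                "dt_integrate too large for this barrier: "
                f"dt * D * max|U'| = {self.dt_integrate * self.diffusion_coeff * max_force:.3g}"
                f" >= well_separation/10 = {L / 10.0:.3g}")

    @property
    def dt_frame(self) -> float:
        return self.dt_integrate * self.save_stride


@njit(cache=True)
def _euler_doublewell(y0, n_steps, save_stride, dt, h, L, d_coeff, seed):
    np.random.seed(seed)
    n_saved = n_steps // save_stride
    out = np.empty(n_saved + 1)
    out[0] = y0
    y = y0
    pref = 8.0 * h / L          # -U'(y) = -(8h/L) u (u^2 - 1), u = 2y/L
    sig = math.sqrt(2.0 * d_coeff * dt)
    # free diffusion (h = 0) has no confining scale: no escape check
    limit = 10.0 * L if h > 0.0 else np.inf
    isave = 1
    for step in range(1, n_steps + 1):
        u = 2.0 * y / L
        force = -pref * u * (u * u - 1.0)
        y = y + d_coeff * force * dt + sig * np.random.standard_normal()
        if abs(y) > limit:
            return out[:isave], step   # caller raises
        if step % save_stride == 0:
            out[isave] = y
            isave += 1
    return out[:isave], 0


class IntegrationInstabilityError(RuntimeError):
    pass


def simulate_doublewell(config: DoubleWellConfig) -> ScalarSeries:
    """Simulate the double well; returns the saved-frame series.

    The Boltzmann density exp(-U(y)) (kT = 1) is stationary for any
    diffusion coefficient: the drift is D * (-U'(y)) and the noise variance
    2 D dt (Einstein relation with unit kT).
    """
    y0 = -config.well_separation / 2.0  # start in the left minimum
    values, bad_step = _euler_doublewell(
        y0, config.n_steps, config.save_stride, config.dt_integrate,
        config.barrier_height, config.well_separation,
        config.diffusion_coeff, config.seed)
    if bad_step:
        raise IntegrationInstabilityError(
            f"|y| exceeded 10 * well_separation at integration step {bad_step}")
    meta = {"generator": "doublewell", "seed": config.seed,
            "barrier_height": config.barrier_height,
            "well_separation": config.well_separation,
            "diffusion_coeff": config.diffusion_coeff,
            "dt_integrate": config.dt_integrate,
            "save_stride": config.save_stride}
    return ScalarSeries(values, dt=config.dt_frame, meta=meta)


@dataclass
class FbmConfig:
    """Exact fractional Brownian motion at unit time spacing.

    Cov(B_s, B_t) = scale^2 * (s^{2H} + t^{2H} - |t-s|^{2H}) / 2.
    """

    hurst: float
    n_steps: int = 4096
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must lie strictly in (0, 1)")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def _fgn_circulant(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies-Harte)."""
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    # fGn autocovariance r(k) = ((k+1)^2H - 2 k^2H + (k-1)^2H)/2
    r = 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([r, r[-2:0:-1]])       # length 2n
    eig = np.fft.fft(row).real
    if eig.min() < -1e-8 * eig.max():
        raise FloatingPointError("circulant embedding not nonnegative definite")
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # real part of the synthesized circulant field carries the exact fGn
    # covariance with this normalization (the imaginary part is an
    # independent second sample, discarded)
    w = np.fft.fft(np.sqrt(eig / m) * z)
    return w[:n].real


def _fgn_cholesky(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Dense-covariance fallback: exact but O(n^3), for small n only."""
    if n > 4096:
        raise FloatingPointError(
            "circulant embedding failed and n is too large for the dense fallback")
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    lag = np.abs(k[:, None] - k[None, :])
    cov = 0.5 * ((lag + 1) ** h2 - 2 * lag ** h2 + np.abs(lag - 1) ** h2)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return chol @ rng.standard_normal(n)


def simulate_fbm(config: FbmConfig) -> ScalarSeries:
    """Exact fBm path B_0 = 0, B_1, ..., B_n at unit spacing (n + 1 values)."""
    rng = np.random.default_rng(config.seed)
    try:
        fgn = _fgn_circulant(config.n_steps, config.hurst, rng)
    except FloatingPointError:
        fgn = _fgn_cholesky(config.n_steps, config.hurst, rng)
    values = np.concatenate([[0.0], np.cumsum(fgn)]) * config.scale
    meta = {"generator": "fbm", "seed": config.seed, "hurst": config.hurst,
            "scale": config.scale}
    return ScalarSeries(values, dt=1.0, meta=meta)


@dataclass
class TwoStateAtomsConfig:
    """Atomistic two-state trajectory driven by a hidden folding coordinate.

    Frame t is ``(1 - sigma_t) * struct_a + sigma_t * struct_b + eta(t)``
    where ``sigma_t = logistic(s(t) / switch_width)`` for the latent
    double-well coordinate s(t), and eta is per-atom, per-dimension
    Ornstein-Uhlenbeck noise with stationary amplitude ``noise_amp`` (A) and
    correlation time ``noise_corr_time`` (in saved-frame time units).
    """

    struct_a: np.ndarray = None
    struct_b: np.ndarray = None
    latent: DoubleWellConfig = field(default_factory=lambda: DoubleWellConfig(
        barrier_height=4.0, well_separation=2.0, n_steps=2_000_000,
        dt_integrate=1e-3, save_stride=2))
    switch_width: float = 0.5
    noise_amp: float = 0.5
    noise_corr_time: float = 10.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.struct_a is None or self.struct_b is None:
            a, b = toy_structures()
            if self.struct_a is None:
                self.struct_a = a
            if self.struct_b is None:
                self.struct_b = b
        self.struct_a = np.asarray(self.struct_a, float)
        self.struct_b = np.asarray(self.struct_b, float)
        if self.struct_a.shape != self.struct_b.shape:
            raise ValueError("struct_a and struct_b must have identical shape")
        if self.struct_a.ndim != 2 or self.struct_a.shape[1] != 3:
            raise ValueError("structures must have shape (n_atoms, 3)")
        if self.noise_amp < 0:
            raise ValueError("noise_amp must be >= 0")
        if self.switch_width <= 0:
            raise ValueError("switch_width must be positive")
        if self.noise_corr_time <= 0:
            raise ValueError("noise_corr_time must be positive")


def _ou_noise(n_frames: int, n_channels: int, amp: float, corr_frames: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary OU noise, shape (n_frames, n_channels), via AR(1) filtering."""
    a = math.exp(-1.0 / corr_frames)
    w = rng.standard_normal((n_frames, n_channels)) * (amp * math.sqrt(1 - a * a))
    w[0] = rng.standard_normal(n_channels) * amp   # stationary start
    return lfilter([1.0], [1.0, -a], w, axis=0)


def simulate_two_state_atoms(config: TwoStateAtomsConfig
                             ) -> tuple[AtomTrajectory, ScalarSeries]:
    """Simulate the atomistic two-state trajectory.

    Returns the trajectory and the latent folding-coordinate series (the
    ground truth).  Frame spacing of the trajectory is 1 (frame units); the
    latent series carries the underlying physical dt in its metadata.
    """
    latent_cfg = config.latent
    from scipy.special import expit
    latent = simulate_doublewell(latent_cfg)
    s = latent.values
    sigma = expit(s / config.switch_width)
    n_frames = s.size
    a, b = config.struct_a, config.struct_b
    pos = a[None, :, :] + sigma[:, None, None] * (b - a)[None, :, :]
    if config.noise_amp > 0:
        rng = np.random.default_rng(config.seed)
        eta = _ou_noise(n_frames, a.size, config.noise_amp,
                        config.noise_corr_time, rng)
        pos += eta.reshape(n_frames, a.shape[0], 3)
    traj = AtomTrajectory(pos, frame_spacing=1.0)
    # downstream time unit is the saved frame; normalize the latent to match
    latent_frames = ScalarSeries(s, dt=1.0, meta={**latent.meta,
                                                  "dt_physical": latent.dt,
                                                  "role": "latent"})
    return traj, latent_frames


def hysteresis_transition_count(values: np.ndarray, lo: float, hi: float) -> int:
    """Transitions between the regions below lo and above hi (two-threshold
    counting, immune to recrossing noise at a single level).

    A fold + unfold round trip counts as 2 transitions.
    """
    if hi <= lo:
        raise ValueError("need lo < hi")
    v = np.asarray(values, float)
    state = np.where(v >= hi, 1, np.where(v <= lo, -1, 0))
    nz = state[state != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(nz) != 0))


def scrambled_contact_coordinate(traj, seed: int = 0,
                                 min_basin_mass: float = 0.05,
                                 n_bins: int = 32, stride: int = 8,
                                 max_tries: int = 50):
    """A deliberately bad contact coordinate that still shows two basins.

    Signs are drawn at random (thresholds at each pair's median distance);
    draws whose cut free-energy profile has no resolvable interior barrier,
    or whose smaller basin holds less than ``min_basin_mass`` of the frames,
    are redrawn (a fully scrambled coordinate often collapses the two states
    entirely, leaving nothing to analyze).  Deterministic in ``seed``.

    Returns (spec, projected series).
    """
    from .coords import (all_pairs, pair_distances, ContactCoordinateSpec,
                         eval_contact_coordinate)
    from .profiles import histogram_profile, LevelGrid, cut_profile
    from .kinetics import locate_transition_state
    pairs = all_pairs(traj.n_atoms)
    d = pair_distances(traj, pairs)
    thresholds = np.median(d, axis=0)
    for attempt in range(max_tries):
        rng = np.random.default_rng([int(seed), attempt])
        spec = ContactCoordinateSpec(pairs=pairs,
                                     signs=rng.choice([-1, 1], len(pairs)),
                                     thresholds=thresholds)
        series = eval_contact_coordinate(traj, spec)
        if np.unique(series.values).size < 8:
            continue
        hist = histogram_profile(series, n_bins)
        cut = cut_profile(series, LevelGrid(hist.midpoints), stride=stride)
        try:
            x_ts = locate_transition_state(cut)
        except ValueError:
            continue
        phi = float(hist.phi(x_ts))
        if min(phi, 1.0 - phi) >= min_basin_mass:
            return spec, series
    raise RuntimeError("no scrambled coordinate with a resolvable barrier "
                       f"found in {max_tries} draws")


def toy_structures() -> tuple[np.ndarray, np.ndarray]:
    """Two 8-atom reference structures ("unfolded" A, "compact" B).

    Pairwise distance changes |d_A - d_B| span roughly 3-12 A so that
    contact- and distance-based coordinates have signal on every pair.
    """
    from .io import read_xyz_frames
    from importlib.resources import files
    data = files("difftrace").joinpath("data")
    a = read_xyz_frames(str(data / "toy_open.xyz"))[0]
    b = read_xyz_frames(str(data / "toy_compact.xyz"))[0]
    return a, b
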
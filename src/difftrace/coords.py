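"""Parametric reaction-coordinate families evaluated on atom trajectories.

Two families are supported, both functions of inter-atom distances only
(hence invariant to rigid rotation/translation of each frame):

* a generalized native-contact coordinate ("contacts", Q1-style):
  ``R(t) = sum_p s_p * step(r0_p - d_p(t))`` with per-pair sign s in {-1, +1}
  and distance threshold r0 in Angstrom; the Heaviside step is taken as 1 at
  exactly r0 (a boundary contact counts as formed);
* a linear combination of inter-atom distances ("distances", Q2-style):
  ``R(t) = sum_p c_p * d_p(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import ScalarSeries

__all__ = [
    "AtomTrajectory",
    "ContactCoordinateSpec",
    "DistanceCoordinateSpec",
    "pairwise_distance",
    "pair_distances",
    "eval_contact_coordinate",
    "eval_distance_coordinate",
    "native_contact_init",
    "all_pairs",
]


@dataclass
class AtomTrajectory:
    """Multi-frame atom coordinates in Angstrom, shape (n_frames, M, 3)."""

    coords: np.ndarray
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory contains non-finite coordinates")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _check_pairs(pairs: Sequence[tuple[int, int]], n_atoms: int | None) -> list[tuple[int, int]]:
    out = []
    seen = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"degenerate pair ({i}, {i})")
        if i > j:
            i, j = j, i
        if (i, j) in seen:
            raise ValueError(f"duplicate pair ({i}, {j})")
        if i < 0 or (n_atoms is not None and j >= n_atoms):
            raise IndexError(f"pair ({i}, {j}) out of range for {n_atoms} atoms")
        seen.add((i, j))
        out.append((i, j))
    return out


@dataclass
class ContactCoordinateSpec:
    """Generalized native-contact coordinate: per-pair sign and threshold."""

    pairs: list[tuple[int, int]]
    signs: np.ndarray
    thresholds: np.ndarray
    native_distances: np.ndarray | None = None
    lambda_scale: float | None = None

    family = "contacts"

    def __post_init__(self) -> None:
        self.pairs = _check_pairs(self.pairs, None)
        if len(self.pairs) == 0:
            raise ValueError("contact coordinate needs at least one pair")
        self.signs = np.asarray(self.signs, dtype=int)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.signs.shape != (len(self.pairs),) or self.thresholds.shape != (len(self.pairs),):
            raise ValueError("signs/thresholds must match the pair list")
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("signs must be -1 or +1")
        if np.any(self.thresholds <= 0):
            raise ValueError("thresholds must be positive")
        if self.native_distances is not None:
            self.native_distances = np.asarray(self.native_distances, dtype=float)
            if self.native_distances.shape != (len(self.pairs),):
                raise ValueError("native_distances must match the pair list")
        if self.lambda_scale is not None:
            if self.native_distances is None:
                raise ValueError("lambda_scale requires native_distances")
            if not np.allclose(self.thresholds,
                               self.lambda_scale * self.native_distances):
                raise ValueError("thresholds inconsistent with lambda * d_native")

    def to_dict(self) -> dict:
        d = {"family": "contacts",
             "pairs": [list(p) for p in self.pairs],
             "signs": self.signs.tolist(),
             "thresholds": self.thresholds.tolist()}
        if self.native_distances is not None:
            d["native_distances"] = self.native_distances.tolist()
        if self.lambda_scale is not None:
            d["lambda"] = self.lambda_scale
        return d


@dataclass
class DistanceCoordinateSpec:
    """Linear combination of inter-atom distances with per-pair weights."""

    pairs: list[tuple[int, int]]
    weights: np.ndarray

    family = "distances"

    def __post_init__(self) -> None:
        self.pairs = _check_pairs(self.pairs, None)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.pairs),):
            raise ValueError("weights must match the pair list")
        if not np.any(self.weights != 0):
            raise ValueError("at least one weight must be nonzero")

    def to_dict(self) -> dict:
        return {"family": "distances",
                "pairs": [list(p) for p in self.pairs],
                "weights": self.weights.tolist()}


def spec_from_dict(d: dict):
    """Rebuild a coordinate spec from its JSON dict form."""
    fam = d.get("family")
    if fam == "contacts":
        return ContactCoordinateSpec(
            pairs=[tuple(p) for p in d["pairs"]],
            signs=np.asarray(d["signs"]),
            thresholds=np.asarray(d["thresholds"]),
            native_distances=(np.asarray(d["native_distances"])
                              if "native_distances" in d else None),
            lambda_scale=d.get("lambda"))
    if fam == "distances":
        return DistanceCoordinateSpec(pairs=[tuple(p) for p in d["pairs"]],
                                      weights=np.asarray(d["weights"]))
    raise ValueError(f"unknown coordinate family {fam!r}")


def all_pairs(n_atoms: int, min_separation: int = 0) -> list[tuple[int, int]]:
    """All (i, j) with j - i > min_separation (the Q2 default pair universe)."""
    return [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)
            if j - i > min_separation]


def pairwise_distance(traj: AtomTrajectory, pair: tuple[int, int]) -> ScalarSeries:
    """Euclidean distance between two atoms, per frame, in Angstrom."""
    i, j = int(pair[0]), int(pair[1])
    if i == j:
        raise ValueError(f"degenerate pair ({i}, {i})")
    if not (0 <= i < traj.n_atoms and 0 <= j < traj.n_atoms):
        raise IndexError(f"pair ({i}, {j}) out of range for {traj.n_atoms} atoms")
    d = np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :], axis=1)
    return ScalarSeries(d, dt=traj.frame_spacing, meta={"pair": (i, j)})


def pair_distances(traj: AtomTrajectory,
                   pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """Distance matrix (n_frames, n_pairs) for a list of atom pairs."""
    pairs = _check_pairs(pairs, traj.n_atoms)
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    diff = traj.coords[:, ii, :] - traj.coords[:, jj, :]
    return np.linalg.norm(diff, axis=2)


def eval_contact_coordinate(traj: AtomTrajectory,
                            spec: ContactCoordinateSpec) -> ScalarSeries:
    """R(t) = sum_p s_p * step(r0_p - d_p(t)); integer-valued.

    step(0) = 1: a pair exactly at its threshold counts as formed.
    """
    d = pair_distances(traj, spec.pairs)
    formed = d <= spec.thresholds[None, :]
    r = formed @ spec.signs.astype(float)
    return ScalarSeries(r, dt=traj.frame_spacing,
                        meta={"coordinate": "contacts", "n_pairs": len(spec.pairs)})


def eval_distance_coordinate(traj: AtomTrajectory,
                             spec: DistanceCoordinateSpec) -> ScalarSeries:
    """R(t) = sum_p c_p * d_p(t)."""
    d = pair_distances(traj, spec.pairs)
    r = d @ spec.weights
    return ScalarSeries(r, dt=traj.frame_spacing,
                        meta={"coordinate": "distances", "n_pairs": len(spec.pairs)})


def native_contact_init(native: np.ndarray, cutoff: float,
                        mode: str = "constant_r0",
                        lambda_scale: float = 1.2,
                        min_separation: int = 0) -> ContactCoordinateSpec:
    """Initialize a contact coordinate from a native structure.

    Pairs are all (i, j) with j - i > min_separation whose native distance is
    <= cutoff; all signs +1.  ``mode='constant_r0'`` sets every threshold to
    the cutoff; ``mode='proportional'`` sets r0 = lambda_scale * d_native.
    """
    native = np.asarray(native, dtype=float)
    if native.ndim != 2 or native.shape[1] != 3:
        raise ValueError("native structure must have shape (n_atoms, 3)")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = native.shape[0]
    pairs, dnat = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if j - i <= min_separation:
                continue
            d = float(np.linalg.norm(native[i] - native[j]))
            if d <= cutoff:
                pairs.append((i, j))
                dnat.append(d)
    if not pairs:
        raise ValueError(f"no native contacts within cutoff {cutoff} A")
    dnat = np.asarray(dnat)
    if mode == "constant_r0":
        return ContactCoordinateSpec(pairs=pairs, signs=np.ones(len(pairs), int),
                                     thresholds=np.full(len(pairs), cutoff),
                                     native_distances=dnat)
    if mode == "proportional":
        return ContactCoordinateSpec(pairs=pairs, signs=np.ones(len(pairs), int),
                                     thresholds=lambda_scale * dnat,
                                     native_distances=dnat,
                                     lambda_scale=lambda_scale)
    raise ValueError(f"unknown mode {mode!r}")
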
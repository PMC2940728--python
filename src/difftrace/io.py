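"""File formats and the end-to-end analysis pipeline.

Formats are deliberately text-only: 2-column TSV for scalar series (with a
``#``-comment header carrying dt, seed and generator parameters), TSV for
profiles, JSON for coordinate specs / kinetics reports / run manifests,
multi-model PDB and plain XYZ for atom trajectories.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .coords import AtomTrajectory
from .profiles import (ScalarSeries, LevelGrid, histogram_profile, cut_profile,
                       diffusion_profile, natural_transform, cumulative_coordinate)

__all__ = [
    "write_series", "read_series",
    "write_xyz", "read_xyz_frames", "read_atom_trajectory", "write_atom_trajectory",
    "write_profile_tsv", "RunConfig", "run_pipeline",
]


# ---------------------------------------------------------------- series TSV

def write_series(path: str, series: ScalarSeries) -> None:
    """Write a series as 2-column TSV (frame_index, value) with a # header."""
    with open(path, "w") as fh:
        fh.write(f"# dt = {series.dt!r}\n")
        for key, val in series.meta.items():
            fh.write(f"# {key} = {json.dumps(val, default=str)}\n")
        fh.write("# frame\tvalue\n")
        for i, v in enumerate(series.values):
            fh.write(f"{i}\t{v:.17g}\n")


def read_series(path: str) -> ScalarSeries:
    """Read a 2-column TSV series; header metadata restored, defaults warned."""
    import warnings
    dt = None
    meta: dict = {}
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key == "dt":
                        dt = float(val)
                    else:
                        try:
                            meta[key] = json.loads(val)
                        except json.JSONDecodeError:
                            meta[key] = val
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split()
            try:
                values.append(float(parts[1]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not values:
        raise ValueError(f"{path}: empty series file")
    if dt is None:
        warnings.warn(f"{path}: no dt in header, assuming dt = 1")
        dt = 1.0
    return ScalarSeries(np.asarray(values), dt=dt, meta=meta)


# ------------------------------------------------------------- trajectories

def write_xyz(path: str, frames: np.ndarray, comment: str = "",
              element: str = "C") -> None:
    """Write frames (n_frames, M, 3) as concatenated XYZ blocks."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for t, frame in enumerate(frames):
            fh.write(f"{frame.shape[0]}\n{comment} frame={t}\n")
            for x, y, z in frame:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(path: str) -> np.ndarray:
    """Read concatenated XYZ blocks -> (n_frames, M, 3) in Angstrom."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_atoms_ref = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {i + 1}") from exc
        if n_atoms_ref is None:
            n_atoms_ref = n
        elif n != n_atoms_ref:
            raise ValueError(f"{path}: frame {len(frames)} has {n} atoms, "
                             f"expected {n_atoms_ref}")
        if i + 1 + n >= len(lines) + 1 or len(lines) < i + 2 + n:
            raise ValueError(f"{path}: truncated frame {len(frames)}")
        block = lines[i + 2: i + 2 + n]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if coords.shape != (n, 3):
            raise ValueError(f"{path}: malformed frame {len(frames)}")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.asarray(frames)


def _read_pdb_models(path: str) -> np.ndarray:
    """Multi-model PDB -> (n_models, M, 3); via biotite."""
    from biotite.structure.io.pdb import PDBFile
    pdb = PDBFile.read(path)
    stack = pdb.get_structure()  # AtomArrayStack
    coords = np.asarray(stack.coord, float)
    if coords.ndim == 2:
        coords = coords[None]
    return coords


def _write_pdb_models(path: str, frames: np.ndarray) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    arr = struc.AtomArrayStack(frames.shape[0], n_atoms)
    arr.coord = frames
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = np.arange(1, n_atoms + 1)
    arr.res_name = np.full(n_atoms, "GLY")
    arr.atom_name = np.full(n_atoms, "CA")
    arr.element = np.full(n_atoms, "C")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


def read_atom_trajectory(path: str, fmt: str | None = None,
                         frame_spacing: float = 1.0) -> AtomTrajectory:
    """Read a multi-frame trajectory from multi-model PDB or XYZ."""
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"  ": None, ".pdb": "pdb_multimodel", ".xyz": "xyz"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path!r}; pass fmt=")
    if fmt == "pdb_multimodel":
        coords = _read_pdb_models(path)
    elif fmt == "xyz":
        coords = read_xyz_frames(path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    return AtomTrajectory(coords, frame_spacing=frame_spacing)


def write_atom_trajectory(path: str, traj: AtomTrajectory,
                          fmt: str | None = None) -> None:
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".pdb": "pdb_multimodel", ".xyz": "xyz"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path!r}; pass fmt=")
    if fmt == "pdb_multimodel":
        _write_pdb_models(path, traj.coords)
    elif fmt == "xyz":
        write_xyz(path, traj.coords)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------- profiles

def write_profile_tsv(path: str, hist, cut=None, diff=None, nat_map=None,
                      header_extra: dict | None = None) -> None:
    """Write aligned profile columns at the histogram bin midpoints."""
    mids = hist.midpoints
    cols = {"level": mids,
            "Z_H": hist.counts.astype(float),
            "F_H": hist.free_energy.filled(np.nan)}
    if cut is not None:
        cols["Z_C"] = cut.z_cut
        cols["F_C"] = cut.free_energy.filled(np.nan)
    if diff is not None:
        cols["D"] = diff.diffusion.filled(np.nan)
    if nat_map is not None:
        cols["y"] = nat_map.forward(mids)
    cols["z"] = cumulative_coordinate(hist).forward(mids)
    with open(path, "w") as fh:
        fh.write(f"# n_frames = {hist.n_frames}\n")
        if cut is not None:
            fh.write(f"# stride = {cut.stride}\n# offset_mode = {cut.offset_mode}\n")
        fh.write("# tie_rule = left\n")
        for key, val in (header_extra or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# " + "\t".join(cols) + "\n")
        for row in zip(*cols.values()):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    """Configuration of the end-to-end profile/diffusivity analysis."""

    series_path: str | None = None
    traj_path: str | None = None
    spec_path: str | None = None
    n_bins: int = 40
    binning: str = "equal_width"        # or equal_population
    strides: tuple[int, int] = (4, 8)
    ts_half_width: float | None = None  # defaults to one grid spacing
    max_lag: int = 200
    out_dir: str = "difftrace_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.series_path is None and (self.traj_path is None
                                         or self.spec_path is None):
            raise ValueError("need series_path, or traj_path + spec_path")
        for p in (self.series_path, self.traj_path, self.spec_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)


def run_pipeline(cfg: RunConfig) -> dict:
    """Project -> histogram/cut profiles -> natural coordinate -> alpha ->
    MSD -> Kramers kinetics.  Writes TSV/JSON artifacts and a manifest;
    returns the manifest dict."""
    from . import coords as _coords
    from .subdiff import alpha_profile, msd_from_window
    from .kinetics import (locate_transition_state, basin_minima, kramers_mfpt,
                           estimate_event_count)
    from .profiles import equal_population_edges

    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)

    if cfg.series_path is not None:
        series = read_series(cfg.series_path)
    else:
        traj = read_atom_trajectory(cfg.traj_path)
        with open(cfg.spec_path) as fh:
            spec = _coords.spec_from_dict(json.load(fh))
        if spec.family == "contacts":
            series = _coords.eval_contact_coordinate(traj, spec)
        else:
            series = _coords.eval_distance_coordinate(traj, spec)
        write_series(os.path.join(cfg.out_dir, "projection.tsv"), series)

    if cfg.binning == "equal_population":
        edges = equal_population_edges(series, cfg.n_bins)
        hist = histogram_profile(series, edges)
    else:
        hist = histogram_profile(series, cfg.n_bins)
    grid = LevelGrid(hist.midpoints)
    k1, k2 = cfg.strides
    cut1 = cut_profile(series, grid, stride=k1)
    cut2 = cut_profile(series, grid, stride=k2)
    diff = diffusion_profile(hist, cut1)
    nat_map, nat_series = natural_transform(series, hist, cut1)

    write_profile_tsv(os.path.join(cfg.out_dir, "profiles.tsv"), hist, cut1,
                      diff, nat_map, header_extra={"seed": cfg.seed})

    alpha = alpha_profile(series, grid, k1, k2)
    with open(os.path.join(cfg.out_dir, "alpha.tsv"), "w") as fh:
        fh.write(f"# strides = {k1},{k2}\n# level\talpha\tse\n")
        for lvl, al, se in zip(alpha.levels, alpha.alpha.filled(np.nan),
                               alpha.stderr.filled(np.nan)):
            fh.write(f"{lvl:.10g}\t{al:.10g}\t{se:.10g}\n")

    report: dict = {"seed": cfg.seed, "n_frames": len(series)}
    try:
        x_ts = locate_transition_state(cut1)
        nat_hist = histogram_profile(nat_series, cfg.n_bins)
        nat_grid = LevelGrid(nat_hist.midpoints)
        nat_cut = cut_profile(nat_series, nat_grid, stride=k2)
        y_ts, a, b = basin_minima(nat_cut, nat_hist)
        fwd = kramers_mfpt(nat_hist, 1.0, a, b, start="basin_average", x_split=y_ts)
        bwd = kramers_mfpt(nat_hist, 1.0, b, a, start="basin_average", x_split=y_ts)
        idx = int(np.argmin(np.abs(alpha.levels - x_ts)))
        half = cfg.ts_half_width or float(np.diff(nat_grid.levels).mean())
        msd = msd_from_window(nat_series, y_ts, half, cfg.max_lag)
        report.update({
            "x_TS": float(x_ts),
            "F_C_TS": float(-np.log(cut_profile(series, grid, k1).z_cut[
                int(np.argmin(np.abs(grid.levels - x_ts)))])),
            "alpha_TS": (None if alpha.alpha.mask[idx] else float(alpha.alpha[idx])),
            "mfpt_forward": fwd, "mfpt_backward": bwd,
            "n_events_est": estimate_event_count(fwd, bwd, series.duration),
            "msd_gamma": msd.gamma, "msd_alpha": msd.alpha_mad,
        })
    except ValueError as exc:       # barrier-less profile etc.
        report["kinetics_error"] = str(exc)
    with open(os.path.join(cfg.out_dir, "kinetics.json"), "w") as fh:
        json.dump(report, fh, indent=1)

    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "artifacts": sorted(os.listdir(cfg.out_dir)),
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
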
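"""Readers and writers for trajectories, panels, and profiles.

The native exchange format is a plain tab-separated table with columns
``frame  residue  x  y  z`` (Å); frame 0 is the reference structure
(frame0) and frames 1..F are the sampled trajectory.  Multi-model PDB
files are read through MDAnalysis (Cα atoms by atom name, first model as
the reference), as are standard binary trajectory formats (XTC/DCD plus
a topology) when MDAnalysis is installed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import Trajectory
from .maxent import DensityEstimate

__all__ = [
    "read_trajectory_table",
    "write_trajectory_table",
    "read_pdb",
    "read_md_trajectory",
    "write_density_json",
    "read_density_json",
    "write_table",
]


def write_trajectory_table(traj: Trajectory, path, header_extra: str = "") -> None:
    """Write the frame/residue/x/y/z table; frame 0 carries frame0."""
    path = Path(path)
    n_f, n_r = traj.n_frames, traj.n_residues
    frames = np.repeat(np.arange(0, n_f + 1), n_r)
    residues = np.tile(traj.ids, n_f + 1)
    xyz = np.concatenate([traj.frame0[None], traj.coords]).reshape(-1, 3)
    with path.open("w") as fh:
        fh.write(f"# mdfluct trajectory: frame 0 is the reference structure (frame0)\n")
        fh.write(f"# frame_interval_ps={traj.frame_interval} label={traj.label}\n")
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write("frame\tresidue\tx\ty\tz\n")
        np.savetxt(
            fh,
            np.column_stack([frames, residues, xyz]),
            fmt=["%d", "%d", "%.6f", "%.6f", "%.6f"],
            delimiter="\t",
        )


def read_trajectory_table(path) -> Trajectory:
    """Read the native tabular format (whitespace or comma separated)."""
    path = Path(path)
    frame_interval = 50.0
    label = path.stem
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith("frame_interval_ps="):
                    frame_interval = float(tok.split("=", 1)[1])
                elif tok.startswith("label=") and tok.split("=", 1)[1]:
                    label = tok.split("=", 1)[1]
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"frame", "residue", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"trajectory table needs columns {sorted(required)}")
    df = df.sort_values(["frame", "residue"], kind="stable")
    ids = np.sort(df["residue"].unique())
    n_r = ids.size
    frames = np.sort(df["frame"].unique())
    xyz = df[["x", "y", "z"]].to_numpy(float).reshape(frames.size, n_r, 3)
    if frames[0] == 0:
        frame0, coords = xyz[0], xyz[1:]
    else:
        frame0, coords = None, xyz
    return Trajectory(
        coords=coords, frame0=frame0, frame_interval=frame_interval,
        ids=ids.astype(int), label=label,
    )


def read_pdb(path, label: str = "") -> Trajectory:
    """Cα trajectory from a multi-model PDB; model 1 is the reference."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    ca = u.select_atoms("name CA")
    if len(ca) == 0:
        raise ValueError("no Cα atoms found in PDB")
    frames = np.array([ca.positions.copy() for _ in u.trajectory])
    if frames.shape[0] < 3:
        raise ValueError("multi-model PDB must hold a reference model plus >= 2 frames")
    return Trajectory(
        coords=frames[1:], frame0=frames[0],
        ids=np.asarray(ca.resids, int), label=label or Path(path).stem,
    )


def read_md_trajectory(topology, trajectory, label: str = "") -> Trajectory:
    """Cα trajectory from standard MD formats (XTC/DCD/...) via MDAnalysis.

    The first frame is taken as the reference structure.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    ca = u.select_atoms("name CA")
    frames = np.array([ca.positions.copy() for _ in u.trajectory])
    dt = float(getattr(u.trajectory, "dt", 50.0))
    return Trajectory(
        coords=frames[1:], frame0=frames[0], frame_interval=dt,
        ids=np.asarray(ca.resids, int), label=label or Path(trajectory).stem,
    )


def write_density_json(estimate: DensityEstimate, path) -> None:
    Path(path).write_text(estimate.to_json() + "\n")


def read_density_json(path) -> DensityEstimate:
    return DensityEstimate.from_json(Path(path).read_text())


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable run configuration."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed: int | None = None, config: dict | None = None) -> None:
    """TSV with a provenance header (master seed + config hash)."""
    path = Path(path)
    with path.open("w") as fh:
        parts = []
        if seed is not None:
            parts.append(f"seed={seed}")
        if config is not None:
            parts.append(f"config_hash={config_hash(config)}")
        if parts:
            fh.write("# " + " ".join(parts) + "\n")
        df.to_csv(fh, sep="\t", index=False)
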
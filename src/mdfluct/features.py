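"""From Cα coordinate trajectories to scalar fluctuation samples.

Two residue-level descriptions are produced.  The on-residue (1R)
description is the magnitude of a residue's displacement from its average
position, which requires every frame to be superposed onto a common
reference first.  The residue-pair (2R) description is the distance
between two Cα atoms, which is rotationally invariant and needs no
alignment; pairs are restricted to nearest neighbors, defined as residue
pairs that come within a cutoff distance in at least one frame of the
full trajectory.

Trajectories are split into two equal contiguous halves (time blocks);
every sample belongs to one block.  The reference structure (frame0, the
final equilibration structure) is never an observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .maxent import DensityEstimate, FluctuationSample

__all__ = [
    "Trajectory",
    "ReferenceStructure",
    "AveragingConfig",
    "NeighborSet",
    "superpose",
    "superpose_trajectory",
    "kabsch_rmsd",
    "make_mean_reference",
    "split_halves",
    "displacement_magnitudes",
    "fluctuation_samples_1r",
    "pair_distances",
    "shift_distribution",
    "rmsd_trace",
]


@dataclass
class Trajectory:
    """Cα coordinate time series: ``coords[frame, residue, xyz]`` in Å.

    ``frame0`` is the reference structure (last equilibration frame); it
    is used for alignment only and is not part of any sample.  ``ids``
    are 1-based residue indices, assumed perfectly sequence-aligned
    across trajectories being compared.
    """

    coords: np.ndarray
    frame0: np.ndarray | None = None
    frame_interval: float = 50.0  # ps
    ids: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, residues, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.frame0 is None:
            self.frame0 = self.coords[0].copy()
        self.frame0 = np.asarray(self.frame0, dtype=float)
        if self.frame0.shape != self.coords.shape[1:]:
            raise ValueError("frame0 shape does not match trajectory residues")
        if self.ids is None:
            self.ids = np.arange(1, self.coords.shape[1] + 1)
        self.ids = np.asarray(self.ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass
class ReferenceStructure:
    """Coordinates frames are superposed onto: a frame0 or a mean of frame0s."""

    coords: np.ndarray
    kind: str = "self"  # "self" or "mean"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class AveragingConfig:
    """Local (per-block means) vs global (shared cross-block mean) averaging."""

    mode: str = "local"

    def __post_init__(self) -> None:
        if self.mode not in ("local", "global"):
            raise ValueError("averaging mode must be 'local' or 'global'")


@dataclass
class NeighborSet:
    """Residue pairs (k, j), k < j, within ``cutoff`` Å in at least one frame."""

    pairs: set = field(default_factory=set)
    cutoff: float = 12.0

    def neighbors_of(self, k: int) -> list[int]:
        out = [j for (i, j) in self.pairs if i == k]
        out += [i for (i, j) in self.pairs if j == k]
        return sorted(out)

    def intersection(self, other: "NeighborSet") -> "NeighborSet":
        return NeighborSet(pairs=self.pairs & other.pairs, cutoff=self.cutoff)


# ----------------------------------------------------------------------
# rigid-body superposition

def superpose(mobile: np.ndarray, reference: ReferenceStructure | np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of ``mobile`` onto the reference.

    Equal-weight Cα superposition; reflections are never produced (the
    rotation is proper).  Returns the transformed coordinates.
    """
    ref = reference.coords if isinstance(reference, ReferenceStructure) else np.asarray(reference, float)
    mob = np.asarray(mobile, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(f"coordinate shape mismatch: {mob.shape} vs {ref.shape}")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + ref.mean(axis=0)


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD (Å) after optimal rigid superposition."""
    fitted = superpose(mobile, reference)
    ref = reference.coords if isinstance(reference, ReferenceStructure) else reference
    return float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))


def superpose_trajectory(traj: Trajectory, reference: ReferenceStructure | None = None) -> Trajectory:
    """Superpose every frame (and frame0) onto the reference.

    Default reference is the trajectory's own frame0 (self-alignment).
    """
    if reference is None:
        reference = ReferenceStructure(traj.frame0, kind="self")
    fitted = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        fitted[i] = superpose(traj.coords[i], reference)
    return Trajectory(
        coords=fitted,
        frame0=superpose(traj.frame0, reference),
        frame_interval=traj.frame_interval,
        ids=traj.ids.copy(),
        label=traj.label,
    )


def make_mean_reference(frame0_structures: Sequence[np.ndarray], tol: float = 1e-6,
                        max_iter: int = 100) -> ReferenceStructure:
    """Iterative mean of several frame0 structures under rigid superposition.

    All structures are superposed onto the running mean and re-averaged
    until the mean moves by less than ``tol`` Å per coordinate.  The fixed
    point is independent of input order (up to the tolerance).
    """
    structs = [np.asarray(s, dtype=float) for s in frame0_structures]
    if len(structs) == 0:
        raise ValueError("need at least one structure")
    shape = structs[0].shape
    if any(s.shape != shape for s in structs):
        raise ValueError("all structures must have the same residue count")
    mean = structs[0] - structs[0].mean(axis=0)
    for _ in range(max_iter):
        fitted = np.array([superpose(s, mean) for s in structs])
        new_mean = fitted.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        # orient the new mean onto the old so convergence is measured in a
        # common frame
        new_mean = superpose(new_mean, mean)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return ReferenceStructure(coords=mean, kind="mean")


# ----------------------------------------------------------------------
# block splitting and 1R samples

def split_halves(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Two equal contiguous halves of the frames (frame0 is not a frame).

    Odd frame counts drop the final frame with a warning.
    """
    n = traj.n_frames
    if n % 2 == 1:
        warnings.warn(f"odd frame count {n}: dropping the final frame", stacklevel=2)
        n -= 1
    half = n // 2
    return traj.coords[:half], traj.coords[half:n]


def displacement_magnitudes(block: np.ndarray, mean_positions: np.ndarray) -> np.ndarray:
    """|r_k(t) − μ_k| for every frame t and residue k; shape (frames, residues)."""
    return np.linalg.norm(block - mean_positions[None, :, :], axis=2)


def fluctuation_samples_1r(
    traj: Trajectory,
    averaging: AveragingConfig | str = "local",
    reference: ReferenceStructure | None = None,
) -> dict[int, tuple[FluctuationSample, FluctuationSample]]:
    """On-residue displacement-magnitude samples for both time blocks.

    The trajectory is superposed onto ``reference`` (its own frame0 by
    default), split into halves, and per-residue displacement magnitudes
    are taken about the block mean position (local averaging) or the
    cross-block mean (global averaging).  Returns
    ``{residue_id: (block-1 sample, block-2 sample)}``.
    """
    if isinstance(averaging, str):
        averaging = AveragingConfig(averaging)
    aligned = superpose_trajectory(traj, reference)
    b1, b2 = split_halves(aligned)
    mu1 = b1.mean(axis=0)
    mu2 = b2.mean(axis=0)
    if averaging.mode == "global":
        mu = 0.5 * (mu1 + mu2)
        mu1 = mu2 = mu
    v1 = displacement_magnitudes(b1, mu1)
    v2 = displacement_magnitudes(b2, mu2)
    out = {}
    for col, rid in enumerate(aligned.ids):
        out[int(rid)] = (
            FluctuationSample(v1[:, col], block_id=1, label=int(rid)),
            FluctuationSample(v2[:, col], block_id=2, label=int(rid)),
        )
    return out


# ----------------------------------------------------------------------
# 2R samples

def _min_pair_distances(coords: np.ndarray, chunk: int = 200) -> np.ndarray:
    """Minimum over frames of all pairwise Cα distances; shape (R, R)."""
    n_res = coords.shape[1]
    dmin = np.full((n_res, n_res), np.inf)
    for start in range(0, coords.shape[0], chunk):
        c = coords[start : start + chunk]
        d = np.linalg.norm(c[:, :, None, :] - c[:, None, :, :], axis=3)
        np.minimum(dmin, d.min(axis=0), out=dmin)
    return dmin


def pair_distances(
    traj: Trajectory,
    cutoff: float = 12.0,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> tuple[NeighborSet, dict[tuple[int, int], tuple[FluctuationSample, FluctuationSample]]]:
    """Nearest-neighbor residue pairs and their distance samples per block.

    Neighbor membership is decided over *all* frames of the trajectory
    (a pair qualifies if it comes within ``cutoff`` in at least one
    frame); distance samples are then emitted per time block for member
    pairs.  No alignment is involved — distances are rotationally
    invariant.  ``pairs`` restricts the computation to a given pair set
    (e.g. an intersection with another trajectory's neighbors).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff < 8.0:
        warnings.warn(
            f"cutoff {cutoff} Å gives sparse neighbor sets; values below 8 Å "
            "are not robust",
            stacklevel=2,
        )
    ids = traj.ids
    dmin = _min_pair_distances(traj.coords)
    members = []
    n_res = traj.n_residues
    for a in range(n_res):
        for b in range(a + 1, n_res):
            pid = (int(ids[a]), int(ids[b]))
            if dmin[a, b] <= cutoff and (pairs is None or pid in pairs):
                members.append((a, b, pid))
    nbrs = NeighborSet(pairs={pid for (_, _, pid) in members}, cutoff=cutoff)
    b1, b2 = split_halves(traj)
    samples = {}
    for a, b, pid in members:
        d1 = np.linalg.norm(b1[:, a] - b1[:, b], axis=1)
        d2 = np.linalg.norm(b2[:, a] - b2[:, b], axis=1)
        samples[pid] = (
            FluctuationSample(d1, block_id=1, label=pid),
            FluctuationSample(d2, block_id=2, label=pid),
        )
    return nbrs, samples


def shift_distribution(
    sample: FluctuationSample, estimate: DensityEstimate
) -> tuple[FluctuationSample, DensityEstimate]:
    """Translate a sample and its fitted density so the density mean is 0.

    The density's first moment (by quadrature) is subtracted from the
    sample values and from the estimate's support, discarding the average
    structural information and keeping pure fluctuations.
    """
    m = estimate.mean()
    shifted_sample = FluctuationSample(
        sample.values - m, block_id=sample.block_id, label=sample.label
    )
    return shifted_sample, estimate.shifted(-m)


def rmsd_trace(traj: Trajectory) -> np.ndarray:
    """Per-frame least-squares-fitted RMSD (Å) to frame0, for convergence plots."""
    ref = ReferenceStructure(traj.frame0, kind="self")
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        fitted = superpose(traj.coords[i], ref)
        out[i] = np.sqrt(np.mean(np.sum((fitted - ref.coords) ** 2, axis=1)))
    return out
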
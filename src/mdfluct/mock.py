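"""Synthetic mock trajectories for validation and control experiments.

The generator emulates the validation design used to probe extreme
p-values: each residue's Cα position is drawn from three independent
Gaussians (x, y, z), i.i.d. across frames by default, with the structure
of a real dataset (263 residues, 2000 frames per trajectory, two time
blocks of 1000).  A second trajectory is produced from the same
parameters perturbed by a mean shift (in units of the local sd) and an
sd scale factor; zero perturbation gives an identically-distributed null
pair.  Optionally an AR(1) coefficient adds frame-to-frame time
correlation, emulating the residual correlations of real MD data;
uniform frame shuffling destroys such correlations, which is the paper's
control for whether they drive low p-values.

Default Gaussian means lie on an ideal α-helix so that alignment and
neighbor machinery behave protein-like; per-axis sds are drawn once per
spec seed, uniform in [0.3, 1.0] Å, a realistic range of per-residue
Cα fluctuation amplitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import Trajectory

__all__ = ["MockSpec", "gaussian_mock_pair", "make_mock_trajectory", "shuffle_frames", "toy_structure"]


def toy_structure(n_residues: int, geometry: str = "helix", spacing: float = 3.8) -> np.ndarray:
    """Deterministic Cα reference coordinates for fixtures.

    ``line`` places residue k at (k·spacing, 0, 0), so pair (k, j) is
    exactly |k−j|·spacing apart.  ``helix`` uses ideal α-helix geometry
    (2.3 Å radius, 1.5 Å rise and 100° twist per residue), giving a
    sequential Cα-Cα distance of ≈3.8 Å.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    k = np.arange(n_residues, dtype=float)
    if geometry == "line":
        return np.column_stack([k * spacing, np.zeros_like(k), np.zeros_like(k)])
    if geometry == "helix":
        theta = np.deg2rad(100.0) * k
        return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k])
    raise ValueError(f"unknown geometry {geometry!r}")


@dataclass
class MockSpec:
    """Parameters of a mock Gaussian trajectory pair.

    ``mean_shift`` (in multiples of the per-axis sd) and ``sd_scale``
    perturb the second trajectory's Gaussians; both default to the
    identity (null pair).  ``ar1`` in [0, 1) adds stationary AR(1) time
    correlation per axis; 0 means i.i.d. frames.  When
    ``random_perturbation`` is true the perturbations vary randomly per
    residue (mean shifts ~ N(0, mean_shift·sd), log sd factors ~
    N(ln sd_scale, |ln sd_scale|/2)) instead of being identical
    everywhere.
    """

    n_residues: int = 263
    n_frames: int = 2000
    frame_interval: float = 50.0
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    mean_shift: float = 0.0
    sd_scale: float = 1.0
    ar1: float = 0.0
    random_perturbation: bool = False
    seed: int = 0
    sd_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5EED]))
        if self.means is None:
            self.means = toy_structure(self.n_residues, "helix")
        self.means = np.asarray(self.means, dtype=float)
        if self.sds is None:
            lo, hi = self.sd_range
            self.sds = rng.uniform(lo, hi, size=(self.n_residues, 3))
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds <= 0):
            raise ValueError("sds must be positive")
        if self.means.shape != (self.n_residues, 3) or self.sds.shape != (self.n_residues, 3):
            raise ValueError("means and sds must have shape (n_residues, 3)")

    def perturbed_parameters(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Mean/sd arrays for the second trajectory of the pair."""
        if self.random_perturbation:
            means_b = self.means + rng.normal(0.0, 1.0, self.means.shape) * (
                self.mean_shift * self.sds
            )
            log_factor = np.log(self.sd_scale) if self.sd_scale > 0 else 0.0
            factors = np.exp(rng.normal(log_factor, abs(log_factor) / 2.0, self.sds.shape))
            sds_b = self.sds * factors
        else:
            means_b = self.means + self.mean_shift * self.sds
            sds_b = self.sds * self.sd_scale
        return means_b, sds_b

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_residues": self.n_residues,
                "n_frames": self.n_frames,
                "frame_interval": self.frame_interval,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "mean_shift": self.mean_shift,
                "sd_scale": self.sd_scale,
                "ar1": self.ar1,
                "random_perturbation": self.random_perturbation,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MockSpec":
        obj = json.loads(text)
        obj["means"] = np.asarray(obj["means"], dtype=float)
        obj["sds"] = np.asarray(obj["sds"], dtype=float)
        return cls(**obj)


def _gaussian_frames(
    means: np.ndarray,
    sds: np.ndarray,
    n_frames: int,
    ar1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(frames, residues, 3) draws; stationary AR(1) per axis when ar1 > 0."""
    eps = rng.standard_normal((n_frames, *means.shape))
    if ar1 > 0.0:
        x = np.empty_like(eps)
        x[0] = eps[0]
        scale = np.sqrt(1.0 - ar1 * ar1)
        for t in range(1, n_frames):
            x[t] = ar1 * x[t - 1] + scale * eps[t]
        eps = x
    return means[None] + sds[None] * eps


def make_mock_trajectory(
    means: np.ndarray,
    sds: np.ndarray,
    n_frames: int,
    ar1: float,
    rng: np.random.Generator,
    frame_interval: float = 50.0,
    label: str = "",
) -> Trajectory:
    coords = _gaussian_frames(np.asarray(means, float), np.asarray(sds, float), n_frames, ar1, rng)
    return Trajectory(
        coords=coords,
        frame0=np.asarray(means, float).copy(),
        frame_interval=frame_interval,
        label=label,
    )


def gaussian_mock_pair(spec: MockSpec) -> tuple[Trajectory, Trajectory]:
    """Trajectory A from the base Gaussians, B from the perturbed ones.

    With ``mean_shift=0`` and ``sd_scale=1`` the two trajectories are
    identically distributed (the null control).  Deterministic for a
    given spec (including its seed).
    """
    ss = np.random.SeedSequence([spec.seed, 0xA, 0xB])
    rng_a, rng_b, rng_p = [np.random.default_rng(s) for s in ss.spawn(3)]
    means_b, sds_b = spec.perturbed_parameters(rng_p)
    a = make_mock_trajectory(
        spec.means, spec.sds, spec.n_frames, spec.ar1, rng_a, spec.frame_interval, label="A"
    )
    b = make_mock_trajectory(
        means_b, sds_b, spec.n_frames, spec.ar1, rng_b, spec.frame_interval, label="B"
    )
    return a, b


def shuffle_frames(traj: Trajectory, seed: int = 0) -> Trajectory:
    """Uniformly random permutation of the frame order (same frame multiset)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(traj.n_frames)
    return Trajectory(
        coords=traj.coords[perm],
        frame0=traj.frame0.copy(),
        frame_interval=traj.frame_interval,
        ids=traj.ids.copy(),
        label=traj.label,
    )
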
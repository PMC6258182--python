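"""Comparison orchestration: groups, data collapse, and significance profiles.

A comparison group names a set of trajectory pairs analyzed the same way
(on-residue ``1R`` or residue-pair ``2R`` description; self- or
mean-reference alignment; local, global, or shifting averaging).  Each
trajectory is split into two half-trajectory time blocks; a
self-comparison tests block 1 against block 2 of the same trajectory,
while a cross-comparison tests the four block pairings
{A1&B1, A2&B1, A1&B2, A2&B2} and averages the four results.

For the 2R description, pair measures M_kj are collapsed onto residues by
an arithmetic mean over the nearest neighbors j of residue k; a pair
contributes only if it is a nearest neighbor in *both* trajectories (the
intersection rule).  p-values are averaged on the log10 scale (geometric
mean), matching how significance profiles are plotted.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    AveragingConfig,
    NeighborSet,
    ReferenceStructure,
    Trajectory,
    fluctuation_samples_1r,
    make_mean_reference,
    pair_distances,
    shift_distribution,
)
from .maxent import DensityEstimate, EstimationConfig, FluctuationSample, estimate_density
from .measures import MeasurePanel, measure_panel

__all__ = [
    "ComparisonGroup",
    "CollapsedProfile",
    "SignificanceProfile",
    "PairResult",
    "GroupResult",
    "TABLE1_GROUPS",
    "table1_group",
    "enumerate_comparisons",
    "neighbor_collapse",
    "block_average",
    "run_pair",
    "run_group",
    "panels_to_frame",
]

# measures averaged on the linear scale; log10 p-values on the log scale
LINEAR_MEASURES = ("delta_rmsf", "js", "delta_p", "kl_min", "kl_ave", "kl_max", "ks1", "ks0")


@dataclass
class ComparisonGroup:
    """A named family of trajectory comparisons analyzed identically."""

    name: str
    mode: str  # "1R" or "2R"
    alignment: str | None  # "self", "mean", or None (2R only)
    averaging: str  # "local", "global", or "shifting"
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("1R", "2R"):
            raise ValueError("mode must be '1R' or '2R'")
        if (self.alignment is None) != (self.mode == "2R"):
            raise ValueError("alignment is omitted exactly for the 2R description")
        if self.averaging == "shifting" and self.mode != "2R":
            raise ValueError("shifting averaging applies only to the 2R description")
        if self.mode == "1R" and self.averaging not in ("local", "global"):
            raise ValueError("1R averaging must be 'local' or 'global'")
        if self.mode == "2R" and self.averaging not in ("local", "shifting"):
            raise ValueError("2R averaging must be 'local' or 'shifting'")


_WT = ["A", "B", "C"]
_MT = ["X", "Y", "Z"]
_WT_WT = [("A", "B"), ("A", "C"), ("B", "C")]
_MT_WT = [(m, w) for m in _MT for w in _WT]
_SELF = [(t, t) for t in _WT + _MT]

TABLE1_GROUPS: dict[str, ComparisonGroup] = {
    g.name: g
    for g in [
        ComparisonGroup("1R-self-1", "1R", "self", "local", list(_SELF)),
        ComparisonGroup("1R-self-2", "1R", "self", "global", list(_SELF)),
        ComparisonGroup("1R-wt-wt-1", "1R", "self", "local", list(_WT_WT)),
        ComparisonGroup("1R-wt-wt-2", "1R", "mean", "local", list(_WT_WT)),
        ComparisonGroup("1R-mt-wt-1", "1R", "self", "local", list(_MT_WT)),
        ComparisonGroup("1R-mt-wt-2", "1R", "mean", "local", list(_MT_WT)),
        ComparisonGroup("2R-wt-wt-1", "2R", None, "local", list(_WT_WT)),
        ComparisonGroup("2R-mt-wt-1", "2R", None, "local", list(_MT_WT)),
        ComparisonGroup("2R-wt-wt-2", "2R", None, "shifting", list(_WT_WT)),
        ComparisonGroup("2R-mt-wt-2", "2R", None, "shifting", list(_MT_WT)),
    ]
}


def table1_group(name: str) -> ComparisonGroup:
    try:
        return TABLE1_GROUPS[name]
    except KeyError:
        raise ValueError(f"unknown comparison group {name!r}") from None


def enumerate_comparisons(group: ComparisonGroup) -> list[tuple[str, int, str, int]]:
    """Block-pairing tasks ``(label_a, block_a, label_b, block_b)``.

    A self pair (A, A) yields the single convergence task A1&A2; a cross
    pair yields the four block pairings.
    """
    tasks = []
    for la, lb in group.pairs:
        if la == lb:
            tasks.append((la, 1, la, 2))
        else:
            tasks += [(la, 1, lb, 1), (la, 2, lb, 1), (la, 1, lb, 2), (la, 2, lb, 2)]
    return tasks


@dataclass
class CollapsedProfile:
    """Per-residue values of one measure, averaged over block pairings."""

    measure: str
    group: str
    residue_ids: np.ndarray
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.residue_ids, name=self.measure)


@dataclass
class SignificanceProfile:
    """Per-residue KS1 significance: log10 p-value (block-averaged) and p-value."""

    group: str
    mode: str
    residue_ids: np.ndarray
    log10_pv: np.ndarray

    @property
    def pv(self) -> np.ndarray:
        return np.power(10.0, self.log10_pv)


@dataclass
class PairResult:
    """Panels and profiles for one trajectory pair within a group."""

    pair: tuple[str, str]
    panels: dict  # (pairing, variable id) -> MeasurePanel
    profiles: dict  # measure name -> CollapsedProfile
    significance: SignificanceProfile


@dataclass
class GroupResult:
    group: ComparisonGroup
    pairs: dict  # (label_a, label_b) -> PairResult

    def frame(self) -> pd.DataFrame:
        return panels_to_frame(self)


def neighbor_collapse(
    pair_measures: Mapping[tuple[int, int], float], neighbors: NeighborSet
) -> dict[int, float]:
    """Arithmetic mean of M_kj over all neighbors j of each residue k.

    Pairs must come from the intersection neighbor set when two
    trajectories are compared.  Residues without any neighbor are
    omitted (with a warning), not reported as zero.
    """
    acc: dict[int, list[float]] = {}
    for (k, j) in neighbors.pairs:
        if (k, j) not in pair_measures:
            continue
        m = pair_measures[(k, j)]
        acc.setdefault(k, []).append(m)
        acc.setdefault(j, []).append(m)
    residues = {k for pair in neighbors.pairs for k in pair}
    missing = residues - set(acc)
    if missing:
        warnings.warn(f"{len(missing)} residues have no neighbor measures; omitted", stacklevel=2)
    return {k: float(np.mean(v)) for k, v in sorted(acc.items())}


def block_average(profiles: Sequence[Mapping[int, float]]) -> dict[int, float]:
    """Elementwise mean of per-residue profiles over block pairings.

    Profiles are intersected onto their common residue set; a single
    profile (self-comparison) passes through unchanged.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to average")
    common = set(profiles[0])
    for p in profiles[1:]:
        common &= set(p)
    return {k: float(np.mean([p[k] for p in profiles])) for k in sorted(common)}


# ----------------------------------------------------------------------
# pipeline internals

def _fit_seed(master: int, label: str, block: int, var) -> int:
    tag = zlib.crc32(repr((label, block, var)).encode())
    return int(np.random.SeedSequence([master & 0x7FFFFFFF, tag]).generate_state(1)[0])


def _fit_1r(
    traj: Trajectory,
    averaging: str,
    reference: ReferenceStructure | None,
    master_seed: int,
    config: EstimationConfig,
) -> dict[tuple[int, int], tuple[FluctuationSample, DensityEstimate]]:
    """{(residue, block): (sample, estimate)} for one trajectory."""
    samples = fluctuation_samples_1r(traj, AveragingConfig(averaging), reference)
    fits = {}
    for rid, pair in samples.items():
        for s in pair:
            seed = _fit_seed(master_seed, traj.label or "?", s.block_id, rid)
            fits[(rid, s.block_id)] = (s, estimate_density(s, config, seed=seed))
    return fits


def _fit_2r(
    traj: Trajectory,
    pair_ids: set[tuple[int, int]],
    cutoff: float,
    shifting: bool,
    master_seed: int,
    config: EstimationConfig,
) -> dict[tuple[tuple[int, int], int], tuple[FluctuationSample, DensityEstimate]]:
    """{(pair, block): (sample, estimate)}, shifted to zero mean if requested."""
    _, samples = pair_distances(traj, cutoff, pairs=pair_ids)
    fits = {}
    for pid, pair in samples.items():
        for s in pair:
            seed = _fit_seed(master_seed, traj.label or "?", s.block_id, pid)
            est = estimate_density(s, config, seed=seed)
            if shifting:
                s, est = shift_distribution(s, est)
            fits[(pid, s.block_id)] = (s, est)
    return fits


def _panel_profiles(
    panels_by_pairing: Mapping[int, Mapping],
    group: ComparisonGroup,
    collapse_neighbors: NeighborSet | None,
) -> tuple[dict[str, CollapsedProfile], SignificanceProfile]:
    """Collapse panels to per-residue profiles and block-average pairings."""
    per_measure: dict[str, list[Mapping[int, float]]] = {m: [] for m in LINEAR_MEASURES}
    log_pv: list[Mapping[int, float]] = []
    for pairing, panels in panels_by_pairing.items():
        for m in LINEAR_MEASURES:
            vals = {vid: getattr(p, m) for vid, p in panels.items()}
            if collapse_neighbors is not None:
                vals = neighbor_collapse(vals, collapse_neighbors)
            per_measure[m].append(vals)
        lp = {vid: p.log10_pv_ks1 for vid, p in panels.items()}
        if collapse_neighbors is not None:
            lp = neighbor_collapse(lp, collapse_neighbors)
        log_pv.append(lp)
    profiles = {}
    for m, plist in per_measure.items():
        avg = block_average(plist)
        rids = np.array(sorted(avg))
        profiles[m] = CollapsedProfile(
            measure=m, group=group.name, residue_ids=rids,
            values=np.array([avg[k] for k in rids]),
        )
    avg_lp = block_average(log_pv)
    rids = np.array(sorted(avg_lp))
    sig = SignificanceProfile(
        group=group.name, mode=group.mode, residue_ids=rids,
        log10_pv=np.array([avg_lp[k] for k in rids]),
    )
    return profiles, sig


def run_pair(
    traj_a: Trajectory,
    traj_b: Trajectory,
    group: ComparisonGroup,
    reference: ReferenceStructure | None = None,
    cutoff: float = 12.0,
    seed: int = 0,
    config: EstimationConfig | None = None,
) -> PairResult:
    """Full pipeline for one trajectory pair (or a self-comparison).

    Features are extracted per the group's description mode, densities
    fitted per sample, the eight-measure panel computed for every block
    pairing, pair measures collapsed onto residues (2R), and the
    pairings averaged.  Deterministic for a given master seed.
    """
    if traj_a.n_residues != traj_b.n_residues:
        raise ValueError("trajectories have different residue counts")
    config = config or EstimationConfig(nonnegative=True)
    self_cmp = traj_a is traj_b or (
        traj_a.label and traj_a.label == traj_b.label
    )
    if self_cmp:
        pairings = [(1, 2)]
    else:
        pairings = [(1, 1), (2, 1), (1, 2), (2, 2)]

    collapse_neighbors = None
    if group.mode == "1R":
        fits_a = _fit_1r(traj_a, group.averaging, reference, seed, config)
        fits_b = fits_a if traj_a is traj_b else _fit_1r(
            traj_b, group.averaging, reference, seed, config
        )
        var_ids = sorted({rid for rid, _ in fits_a})
    else:
        nbrs_a, _ = pair_distances(traj_a, cutoff)
        if traj_a is traj_b:
            inter = nbrs_a
        else:
            nbrs_b, _ = pair_distances(traj_b, cutoff)
            inter = nbrs_a.intersection(nbrs_b)
        shifting = group.averaging == "shifting"
        fits_a = _fit_2r(traj_a, inter.pairs, cutoff, shifting, seed, config)
        fits_b = fits_a if traj_a is traj_b else _fit_2r(
            traj_b, inter.pairs, cutoff, shifting, seed, config
        )
        var_ids = sorted(inter.pairs)
        collapse_neighbors = inter

    panels_by_pairing: dict[int, dict] = {}
    for idx, (ba, bb) in enumerate(pairings):
        panels = {}
        for vid in var_ids:
            sa, pa = fits_a[(vid, ba)]
            sb, pb = fits_b[(vid, bb)]
            panels[vid] = measure_panel(sa, pa, sb, pb)
        panels_by_pairing[idx] = panels

    profiles, sig = _panel_profiles(panels_by_pairing, group, collapse_neighbors)
    return PairResult(
        pair=(traj_a.label or "a", traj_b.label or "b"),
        panels={(pairings[i], vid): p for i, ps in panels_by_pairing.items() for vid, p in ps.items()},
        profiles=profiles,
        significance=sig,
    )


def run_group(
    group: ComparisonGroup | str,
    trajectories: Mapping[str, Trajectory],
    cutoff: float = 12.0,
    seed: int = 0,
    config: EstimationConfig | None = None,
) -> GroupResult:
    """Run every comparison of a group over a labeled trajectory set."""
    if isinstance(group, str):
        group = table1_group(group)
    missing = {l for pair in group.pairs for l in pair} - set(trajectories)
    if missing:
        raise ValueError(f"group {group.name} needs trajectories {sorted(missing)}")
    reference = None
    if group.mode == "1R" and group.alignment == "mean":
        reference = make_mean_reference([trajectories[l].frame0 for l in sorted(trajectories)])
    results = {}
    for la, lb in group.pairs:
        ta, tb = trajectories[la], trajectories[lb]
        if la == lb:
            tb = ta
        results[(la, lb)] = run_pair(
            ta, tb, group, reference=reference, cutoff=cutoff, seed=seed, config=config
        )
    return GroupResult(group=group, pairs=results)


def panels_to_frame(result: GroupResult) -> pd.DataFrame:
    """All panels of a group as tidy rows (one row per pairing and variable)."""
    rows = []
    for (la, lb), pr in result.pairs.items():
        for (pairing, vid), panel in pr.panels.items():
            rows.append(
                {
                    "group": result.group.name,
                    "comparison": f"{la}-{lb}",
                    "block_a": pairing[0],
                    "block_b": pairing[1],
                    "variable": str(vid),
                    **panel.as_dict(),
                }
            )
    return pd.DataFrame(rows)
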
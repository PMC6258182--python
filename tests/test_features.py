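"""Trajectory feature extraction: superposition, blocks, 1R/2R samples."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdfluct import (
    AveragingConfig,
    FluctuationSample,
    ReferenceStructure,
    Trajectory,
    displacement_magnitudes,
    estimate_density,
    fluctuation_samples_1r,
    js_divergence,
    kabsch_rmsd,
    make_mean_reference,
    pair_distances,
    rmsd_trace,
    shift_distribution,
    split_halves,
    superpose,
    superpose_trajectory,
)

from conftest import gaussian_estimate, uniform_estimate


def rigid(coords, angles=(0.3, -0.7, 1.1), shift=(5.0, -2.0, 3.0)):
    rot = Rotation.from_euler("xyz", angles)
    return rot.apply(coords) + np.asarray(shift)


def grid_min_rmsd(mobile, reference, n=24, zooms=4):
    """Brute-force RMSD minimum over a zooming Euler-angle grid.

    Optimal translation is centroid matching; rotations are searched on a
    coarse grid that is repeatedly refined around the running best.
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def rmsd_batch(eulers):
        rots = Rotation.from_euler("zyz", eulers)
        moved = np.einsum("rij,kj->rki", rots.as_matrix(), mob_c)
        return np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=2), axis=1))

    center = np.zeros(3)
    width = np.array([2 * np.pi, np.pi, 2 * np.pi])
    best = np.inf
    for _ in range(zooms):
        axes = [np.linspace(center[i] - width[i] / 2, center[i] + width[i] / 2, n) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = rmsd_batch(grid)
        k = int(np.argmin(vals))
        best = min(best, float(vals[k]))
        center = grid[k]
        width = width * (3.0 / n)
    return best


class TestSuperpose:
    def test_exact_recovery_of_rigid_transform(self, rng):
        ref = rng.normal(0, 3, (20, 3))
        mob = rigid(ref)
        fitted = superpose(mob, ReferenceStructure(ref))
        assert np.max(np.abs(fitted - ref)) <= 1e-8

    def test_identity_transform(self, rng):
        ref = rng.normal(0, 3, (10, 3))
        assert np.max(np.abs(superpose(ref, ref) - ref)) <= 1e-10
        assert kabsch_rmsd(ref, ref) <= 1e-12

    def test_mismatched_counts_raise(self, rng):
        with pytest.raises(ValueError):
            superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_three_point_toy_matches_grid_oracle(self):
        ref = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [3.8, 3.8, 0.0]])
        mob = ref.copy()
        mob[1, 1] += 0.9  # perturb one coordinate
        mob = rigid(mob, (0.5, 0.2, -0.4), (1.0, 2.0, 3.0))
        fitted = kabsch_rmsd(mob, ref)
        oracle = grid_min_rmsd(mob, ref)
        assert fitted <= oracle + 1e-9
        assert abs(fitted - oracle) <= 2e-3

    def test_alignment_idempotence(self, rng):
        traj = Trajectory(coords=rng.normal(0, 2, (6, 8, 3)))
        once = superpose_trajectory(traj)
        twice = superpose_trajectory(once, ReferenceStructure(once.frame0))
        assert np.max(np.abs(twice.coords - once.coords)) <= 1e-8


class TestMeanReference:
    def test_single_structure(self, rng):
        s = rng.normal(0, 3, (7, 3))
        ref = make_mean_reference([s])
        assert ref.kind == "mean"
        assert kabsch_rmsd(ref.coords, s) <= 1e-8

    def test_rigid_copies_give_same_structure(self, rng):
        s = rng.normal(0, 3, (9, 3))
        ref = make_mean_reference([s, rigid(s)])
        fitted = superpose(ref.coords, s - s.mean(axis=0))
        assert np.max(np.abs(fitted - (s - s.mean(axis=0)))) <= 1e-6

    def test_order_independence(self, rng):
        import itertools

        structs = [rng.normal(0, 3, (6, 3)) for _ in range(3)]
        refs = []
        for perm in itertools.permutations(range(3)):
            refs.append(make_mean_reference([structs[i] for i in perm]).coords)
        base = refs[0]
        for other in refs[1:]:
            fitted = superpose(other, base)
            assert np.max(np.abs(fitted - base)) <= 1e-5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            make_mean_reference([])


class TestSplitHalves:
    @pytest.mark.parametrize("n,expected", [(2000, 1000), (4, 2)])
    def test_even_split(self, rng, n, expected):
        traj = Trajectory(coords=rng.normal(size=(n, 3, 3)))
        b1, b2 = split_halves(traj)
        assert b1.shape[0] == b2.shape[0] == expected
        assert np.array_equal(np.concatenate([b1, b2]), traj.coords[: 2 * expected])

    def test_odd_count_drops_final_frame_with_warning(self, rng):
        traj = Trajectory(coords=rng.normal(size=(5, 2, 3)))
        with pytest.warns(UserWarning, match="odd frame count"):
            b1, b2 = split_halves(traj)
        assert np.array_equal(b1, traj.coords[:2])
        assert np.array_equal(b2, traj.coords[2:4])


class TestDisplacements:
    def test_static_frames_give_zero(self):
        block = np.ones((5, 3, 3))
        mags = displacement_magnitudes(block, block[0])
        assert np.all(mags == 0.0)

    def test_two_frame_toy(self):
        block = np.array([[[0.0, 0, 0]], [[2.0, 0, 0]]])
        mags = displacement_magnitudes(block, block.mean(axis=0))
        assert mags.tolist() == [[1.0], [1.0]]

    def test_hand_enumerated_table(self):
        # 2 residues x 4 frames; block mean subtracted per residue
        block = np.zeros((4, 2, 3))
        block[:, 0, 0] = [0.0, 2.0, 0.0, 2.0]  # mean 1 -> |d| = 1 each frame
        block[:, 1, 1] = [1.0, 1.0, 3.0, 3.0]  # mean 2 -> |d| = 1 each frame
        block[:, 1, 2] = [0.0, 4.0, 0.0, 4.0]  # mean 2 -> combined sqrt(1+4)
        mags = displacement_magnitudes(block, block.mean(axis=0))
        assert np.allclose(mags[:, 0], 1.0)
        assert np.allclose(mags[:, 1], math.sqrt(5.0))

    def test_local_equals_global_when_block_means_agree(self, rng):
        base = rng.normal(0, 1, (10, 4, 3))
        coords = np.concatenate([base, base + 0.0])  # identical halves
        traj = Trajectory(coords=coords)
        # skip alignment so means stay exactly equal
        ref = ReferenceStructure(traj.frame0)
        local = fluctuation_samples_1r(traj, "local", ref)
        glob = fluctuation_samples_1r(traj, "global", ref)
        for rid in local:
            for s_l, s_g in zip(local[rid], glob[rid]):
                assert np.allclose(s_l.values, s_g.values, atol=1e-12)


class TestPairDistances:
    def _static_traj(self, positions, n_frames=4):
        coords = np.repeat(np.asarray(positions, float)[None], n_frames, axis=0)
        return Trajectory(coords=coords)

    def test_345_triangle_distance(self):
        traj = self._static_traj([[0, 0, 0], [3, 4, 0]])
        nbrs, samples = pair_distances(traj, cutoff=12.0)
        assert nbrs.pairs == {(1, 2)}
        s1, s2 = samples[(1, 2)]
        assert np.allclose(s1.values, 5.0) and np.allclose(s2.values, 5.0)

    def test_far_pair_excluded(self):
        traj = self._static_traj([[0, 0, 0], [13.5, 0, 0]])
        nbrs, samples = pair_distances(traj, cutoff=12.0)
        assert nbrs.pairs == set()

    def test_single_frame_within_cutoff_includes_pair(self):
        coords = np.repeat(np.array([[[0.0, 0, 0], [14.0, 0, 0]]]), 6, axis=0)
        coords[3, 1, 0] = 11.0  # inside the cutoff for exactly one frame
        traj = Trajectory(coords=coords)
        nbrs, _ = pair_distances(traj, cutoff=12.0)
        assert (1, 2) in nbrs.pairs

    def test_low_cutoff_warns(self):
        traj = self._static_traj([[0, 0, 0], [3, 0, 0]])
        with pytest.warns(UserWarning, match="cutoff"):
            pair_distances(traj, cutoff=6.0)

    def test_nonpositive_cutoff_raises(self):
        traj = self._static_traj([[0, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            pair_distances(traj, cutoff=0.0)

    def test_rotational_invariance_exact_transforms(self, rng):
        # the proper rotation diag(-1, 1, -1) is exact in floating point
        # (sign flips commute with squaring): distances match bitwise
        coords = rng.normal(0, 3, (8, 5, 3))
        traj = Trajectory(coords=coords.copy())
        flipped = coords * np.array([-1.0, 1.0, -1.0])
        traj2 = Trajectory(coords=flipped)
        _, s_a = pair_distances(traj, cutoff=50.0)
        _, s_b = pair_distances(traj2, cutoff=50.0)
        for pid in s_a:
            for block in (0, 1):
                assert np.array_equal(
                    np.sort(s_a[pid][block].values), np.sort(s_b[pid][block].values)
                )

    def test_rotational_invariance_random_rotations(self, rng):
        coords = rng.normal(0, 3, (8, 5, 3))
        rots = Rotation.random(8, rng=rng)
        rotated = np.array([rots[i].apply(coords[i]) for i in range(8)])
        _, s_a = pair_distances(Trajectory(coords=coords), cutoff=50.0)
        _, s_b = pair_distances(Trajectory(coords=rotated), cutoff=50.0)
        for pid in s_a:
            assert np.allclose(s_a[pid][0].values, s_b[pid][0].values, atol=1e-9)


class TestShiftDistribution:
    def test_uniform_support_shifts_to_zero_mean(self):
        est = uniform_estimate(2.0, 4.0)
        s = FluctuationSample([2.5, 3.5])
        shifted_s, shifted_e = shift_distribution(s, est)
        assert shifted_e.support == pytest.approx((-1.0, 1.0), abs=1e-9)
        assert np.allclose(shifted_s.values, [-0.5, 0.5])
        assert abs(shifted_e.mean()) <= 1e-8

    def test_zero_mean_estimate_unchanged(self):
        est = gaussian_estimate(0.0, 1.0, (-5.0, 5.0))
        s = FluctuationSample([-1.0, 1.0])
        shifted_s, shifted_e = shift_distribution(s, est)
        assert shifted_e.support == pytest.approx(est.support, abs=1e-9)
        assert np.allclose(shifted_s.values, s.values, atol=1e-9)

    def test_shifted_estimate_mean_is_zero(self, rng):
        s = FluctuationSample(rng.normal(8.0, 0.7, 500))
        est = estimate_density(s, seed=1)
        _, shifted_e = shift_distribution(s, est)
        assert abs(shifted_e.mean()) <= 1e-8

    def test_shifting_removes_location_offset(self):
        # two Gaussians differing only in location become identical after
        # shifting, so density measures can only improve
        pa = gaussian_estimate(0.0, 1.0, (-5.0, 5.0))
        pb = gaussian_estimate(1.0, 1.0, (-4.0, 6.0))
        before = js_divergence(pa, pb)
        sa, pa_s = shift_distribution(FluctuationSample([0.0]), pa)
        sb, pb_s = shift_distribution(FluctuationSample([1.0]), pb)
        after = js_divergence(pa_s, pb_s)
        assert after <= before
        assert after == pytest.approx(0.0, abs=1e-6)


class TestRmsdTrace:
    def test_static_trajectory_gives_zeros(self, rng):
        frame = rng.normal(0, 2, (6, 3))
        traj = Trajectory(coords=np.repeat(frame[None], 5, axis=0), frame0=frame)
        assert np.allclose(rmsd_trace(traj), 0.0, atol=1e-10)

    def test_rigidly_transformed_frames_give_zero(self, rng):
        frame = rng.normal(0, 2, (6, 3))
        coords = np.array([rigid(frame, (0.1 * i, 0.2, -0.3), (i, 0, 1)) for i in range(4)])
        traj = Trajectory(coords=coords, frame0=frame)
        assert np.max(rmsd_trace(traj)) <= 1e-8

    def test_displaced_atom_matches_grid_oracle(self):
        frame0 = np.array([[0.0, 0, 0], [3.8, 0, 0], [0.0, 3.8, 0]])
        moved = frame0.copy()
        moved[0, 2] += 2.0
        traj = Trajectory(coords=np.array([moved, frame0]), frame0=frame0)
        trace = rmsd_trace(traj)
        oracle = grid_min_rmsd(moved, frame0)
        assert trace[0] <= oracle + 1e-9
        assert abs(trace[0] - oracle) <= 2e-3
        assert trace[1] <= 1e-10


class TestValidation:
    def test_bad_shapes_raise(self, rng):
        with pytest.raises(ValueError):
            Trajectory(coords=rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            Trajectory(coords=rng.normal(size=(1, 3, 3)))
        with pytest.raises(ValueError):
            Trajectory(coords=np.full((4, 2, 3), np.nan))

    def test_bad_averaging_mode(self):
        with pytest.raises(ValueError):
            AveragingConfig("weird")
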
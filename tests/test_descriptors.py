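from itertools import product

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allonet import descriptors as dsc
from allonet.io import Ensemble

from conftest import static_ensemble


def _random_coords(rng, n=6):
    return rng.standard_normal((n, 3)) * 4.0


class TestSuperpose:
    def test_identical_coordinates_give_zero(self, rng):
        x = _random_coords(rng)
        _, r = dsc.superpose(x, x)
        assert r < 1e-12

    def test_rigid_motion_removed(self, rng):
        x = _random_coords(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = x @ rot.T + np.array([5.0, -3.0, 2.0])
        fitted, r = dsc.superpose(moved, x)
        assert r < 1e-10
        np.testing.assert_allclose(fitted, x, atol=1e-9)

    def test_proper_rotation_not_reflection(self, rng):
        # mirrored coordinates cannot be fitted to zero by a proper rotation
        x = _random_coords(rng)
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        _, r = dsc.superpose(mirrored, x)
        assert r > 0.1

    def test_optimality_against_random_rotations(self, rng):
        a, b = _random_coords(rng), _random_coords(rng)
        _, best = dsc.superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rots = Rotation.random(200, rng=rng).as_matrix()
        trial = np.einsum("kij,nj->kni", rots, ac)
        rmsds = np.sqrt(np.mean(np.sum((trial - bc) ** 2, axis=2), axis=1))
        assert best <= rmsds.min() + 1e-9

    def test_collinear_fit_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            dsc.superpose(line, line)


class TestRMSD:
    def test_static_ensemble_all_zero(self):
        ens = static_ensemble()
        series = dsc.rmsd_series(ens, ens.coords[0])
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_translation_removed_by_fit(self):
        ens = static_ensemble()
        coords = ens.coords.copy()
        coords[2] += np.array([1.0, 0.0, 0.0])
        series = dsc.rmsd_series(Ensemble(coords, ens.res_ids), ens.coords[0])
        assert series.values[2] < 1e-10

    def test_two_frame_toy_matches_hand_value(self):
        # after centring/fit, frame deviates by d on one atom pair axis;
        # use a symmetric stretch that Kabsch cannot remove
        ref = np.array([[-1.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        stretched = ref * np.array([2.0, 1.0, 1.0])
        ens = Ensemble(np.stack([ref, stretched]), np.arange(4))
        series = dsc.rmsd_series(ens, ref)
        # deviations: atoms 1,2 move by 1 along x -> sqrt((1+1)/4)
        assert abs(series.values[1] - np.sqrt(0.5)) < 1e-10


class TestRMSF:
    def test_static_ensemble_zero(self):
        prof = dsc.rmsf_profile(static_ensemble())
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_delta_with_itself_zero(self, small_ensemble):
        p = dsc.rmsf_profile(small_ensemble)
        np.testing.assert_allclose(dsc.delta_rmsf(p, p), 0.0)

    def test_planted_high_variance_residue_has_largest_rmsf(self, rng):
        base = static_ensemble(400).coords.copy()
        noise = 0.2 * rng.standard_normal(base.shape)
        noise[:, 2, :] *= 3.0
        ens = Ensemble(base + noise, np.arange(1, 5))
        prof = dsc.rmsf_profile(ens)
        assert prof.rmsf.argmax() == 2

    def test_misaligned_profiles_rejected(self, small_ensemble):
        p = dsc.rmsf_profile(small_ensemble)
        q = dsc.FlexProfile(p.rmsf, p.res_ids + 1)
        with pytest.raises(ValueError):
            dsc.delta_rmsf(p, q)


class TestGeometry:
    def test_static_distance_constant(self):
        ens = static_ensemble()
        df = dsc.geometry_series(ens, [{"kind": "distance", "residues": (1, 2)}])
        np.testing.assert_allclose(df.iloc[:, 0], 3.8)

    def test_collinear_angle_180(self):
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2.5, 0, 0]]], dtype=float)
        ens = Ensemble(np.repeat(coords, 2, axis=0), np.arange(3))
        df = dsc.geometry_series(ens, [{"kind": "angle", "residues": (0, 1, 2)}])
        np.testing.assert_allclose(df.iloc[:, 0], 180.0)

    def test_centroid_distance_matches_hand_value(self):
        coords = np.array([[[0, 0, 0], [2, 0, 0], [10, 0, 0], [12, 0, 0]]],
                          dtype=float)
        ens = Ensemble(np.repeat(coords, 3, axis=0), np.arange(4))
        df = dsc.geometry_series(
            ens, [{"kind": "centroid_distance", "groups": ([0, 1], [2, 3])}])
        np.testing.assert_allclose(df.iloc[:, 0], 10.0)  # |1 - 11|

    def test_unknown_residue_raises(self, small_ensemble):
        with pytest.raises(KeyError):
            dsc.geometry_series(small_ensemble,
                                [{"kind": "distance", "residues": (1, 99)}])


class TestRepresentative:
    def _two_conformer(self, rng, n_a=12, n_b=8):
        a = static_ensemble(1).coords[0]
        b = a + np.array([4.0, 1.0, -2.0]) * np.array([[1], [2], [-1], [0.5]])
        frames = [a + 0.05 * rng.standard_normal(a.shape) for _ in range(n_a)]
        frames += [b + 0.05 * rng.standard_normal(a.shape) for _ in range(n_b)]
        return Ensemble(np.stack(frames), np.arange(1, 5)), n_a

    def test_identical_frames_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = dsc.representative_structure(static_ensemble(6))
        assert res.frame_index == 0 and res.degenerate

    def test_medoid_comes_from_majority_conformer(self, rng):
        ens, n_a = self._two_conformer(rng)
        res = dsc.representative_structure(ens, k_candidates=range(2, 5))
        assert res.frame_index < n_a
        assert res.k == 2

    def test_medoid_matches_exhaustive_k2_minimiser(self, rng):
        ens, _ = self._two_conformer(rng, 3, 1)
        dmat, _ = dsc.pairwise_rmsd_matrix(ens)
        best = None
        for assign in product([0, 1], repeat=4):
            if len(set(assign)) < 2:
                continue
            cost = 0.0
            meds = {}
            for c in (0, 1):
                members = [i for i in range(4) if assign[i] == c]
                sub = dmat[np.ix_(members, members)]
                j = int(np.argmin(sub.sum(axis=1)))
                cost += sub.sum(axis=1)[j]
                meds[c] = (members, members[j])
            if best is None or cost < best[0] - 1e-12:
                best = (cost, meds, assign)
        _, meds, assign = best
        sizes = {c: assign.count(c) for c in (0, 1)}
        top = max(sizes, key=lambda c: sizes[c])
        expected_medoid = meds[top][1]
        medoids, labels = dsc.pam_kmedoids(dmat, 2)
        res = dsc.representative_structure(ens, k_candidates=[2])
        assert res.frame_index == expected_medoid

    def test_frame_order_permutation_invariant(self, rng):
        ens, _ = self._two_conformer(rng)
        perm = rng.permutation(ens.n_frames)
        shuffled = Ensemble(ens.coords[perm], ens.res_ids)
        a = dsc.representative_structure(ens, k_candidates=[2])
        b = dsc.representative_structure(shuffled, k_candidates=[2])
        np.testing.assert_allclose(ens.coords[a.frame_index],
                                   shuffled.coords[b.frame_index])


class TestCompareDistributions:
    def test_identical_paired_samples_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            dsc.compare_distributions(x, x, paired=True)

    def test_strong_shift_is_significant(self, rng):
        a = rng.standard_normal(50)
        b = a + 5.0
        _, p = dsc.compare_distributions(a, b, paired=True)
        assert p < 0.001

    def test_unequal_sizes_fall_back_to_rank_sum(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(20) + 3
        with pytest.warns(UserWarning, match="rank-sum"):
            _, p = dsc.compare_distributions(a, b, paired=True)
        assert p < 0.01

    def test_small_n_matches_signed_rank_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a + np.array([0.5, -0.7, 1.1, 0.9, -0.2, 1.4])
        stat, p = dsc.compare_distributions(a, b, paired=True)
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        t_plus_obs = ranks[d > 0].sum()
        n = len(d)
        # exhaustive null distribution of T+
        t_counts = {}
        for signs in product([0, 1], repeat=n):
            t = sum(r for r, s in zip(ranks, signs) if s)
            t_counts[t] = t_counts.get(t, 0) + 1
        total = 2 ** n
        t_minus_obs = n * (n + 1) / 2 - t_plus_obs
        t_obs = min(t_plus_obs, t_minus_obs)
        assert stat == t_obs
        p_tail = sum(c for t, c in t_counts.items() if t <= t_obs) / total
        np.testing.assert_allclose(p, min(1.0, 2 * p_tail))
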
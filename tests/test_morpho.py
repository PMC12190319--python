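"""Morphometry: LJD closed forms, volumetry, cluster inference, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from danioquant import morpho as mp
from danioquant import synthgen as sg
from danioquant.morpho import ChannelMap, LJDMap


VOX = (1.0, 1.0, 2.0)


def uniform_scaling_displacement(grid, scale, vox=VOX):
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * v for n, v in zip(grid, vox)], indexing="ij"),
        axis=-1,
    )
    return (scale - 1.0) * coords


def brute_force_ljd(u, vox):
    """Independent oracle: per-voxel finite differences assembled in Python
    loops with an explicit cofactor determinant."""
    nx, ny, nz = u.shape[:3]
    out = np.empty((nx, ny, nz))

    def deriv(comp, axis, i, j, k):
        idx = [i, j, k]
        n = u.shape[axis]
        h = vox[axis]
        if 0 < idx[axis] < n - 1:
            hi, lo = list(idx), list(idx)
            hi[axis] += 1
            lo[axis] -= 1
            return (u[hi[0], hi[1], hi[2], comp] - u[lo[0], lo[1], lo[2], comp]) / (2 * h)
        if idx[axis] == 0:
            hi = list(idx)
            hi[axis] += 1
            return (u[hi[0], hi[1], hi[2], comp] - u[i, j, k, comp]) / h
        lo = list(idx)
        lo[axis] -= 1
        return (u[i, j, k, comp] - u[lo[0], lo[1], lo[2], comp]) / h

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                J = [[(1.0 if a == b else 0.0) + deriv(a, b, i, j, k)
                      for b in range(3)] for a in range(3)]
                det = (
                    J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
                    - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
                    + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0])
                )
                out[i, j, k] = np.log(det)
    return out


class TestLogJacobian:
    def test_identity_field_gives_zero(self):
        u = np.zeros((6, 6, 6, 3))
        assert np.allclose(mp.log_jacobian(u, VOX).values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("scale", [0.9, 1.05, 1.2])
    def test_uniform_scaling_closed_form(self, scale):
        u = uniform_scaling_displacement((8, 8, 8), scale)
        lj = mp.log_jacobian(u, VOX)
        assert np.allclose(lj.values, 3.0 * np.log(scale), atol=1e-6)

    def test_composed_scalings_add(self):
        s1, s2 = 1.1, 0.95
        u = uniform_scaling_displacement((6, 6, 6), s1 * s2)
        lj = mp.log_jacobian(u, VOX)
        assert np.allclose(lj.values, 3.0 * np.log(s1 * s2), atol=1e-6)

    def test_random_smooth_field_matches_brute_force(self):
        from scipy import ndimage

        rng = np.random.default_rng(11)
        u = ndimage.gaussian_filter(rng.normal(0, 0.3, (6, 6, 6, 3)),
                                    (1.5, 1.5, 1.5, 0))
        got = mp.log_jacobian(u, VOX).values
        want = brute_force_ljd(u, VOX)
        assert np.allclose(got, want, atol=1e-6)

    def test_non_invertible_voxels_flagged(self):
        u = np.zeros((5, 5, 5, 3))
        # fold the field: strong negative gradient collapses local volume
        u[:, :, :, 0] = -2.0 * np.arange(5)[:, None, None]
        with pytest.warns(UserWarning, match="non-invertible"):
            lj = mp.log_jacobian(u, VOX)
        assert np.isnan(lj.values).all()


class TestMaskVolume:
    def test_zero_ljd_reproduces_reference_volume(self, noiseless_volume_cohort):
        cohort = noiseless_volume_cohort
        mhb = cohort.region_masks["MHB"]
        s = cohort.group("wt")[0]
        res = mp.mask_volume(s.ljd, mhb, cohort.brain_mask, "MHB")
        assert res.absolute_volume_um3 == pytest.approx(
            mhb.sum() * np.prod(VOX := cohort.voxel_size_um), rel=1e-12
        )

    def test_planted_contraction_gives_92_percent(self, noiseless_volume_cohort):
        cohort = noiseless_volume_cohort
        mhb = cohort.region_masks["MHB"]
        ref = mhb.sum() * np.prod(cohort.voxel_size_um)
        for s in cohort.group("mut"):
            res = mp.mask_volume(s.ljd, mhb, cohort.brain_mask, "MHB")
            assert res.absolute_volume_um3 == pytest.approx(0.92 * ref, rel=1e-9)

    def test_group_mean_reduction_of_planted_effect(self, noiseless_volume_cohort):
        cohort = noiseless_volume_cohort
        mhb = cohort.region_masks["MHB"]
        vols = {
            g: np.mean([
                mp.mask_volume(s.ljd, mhb, cohort.brain_mask).absolute_volume_um3
                for s in cohort.group(g)
            ])
            for g in ("wt", "mut")
        }
        assert 100 * (1 - vols["mut"] / vols["wt"]) == pytest.approx(8.0, abs=1e-9)

    def test_whole_grid_volume_conservation(self):
        # a planted whole-brain factor integrates to exactly that volume
        params = sg.VolumeSimParams(
            n_subjects_per_group=1, planted_contraction={"mut": {"brain": 0.939}},
            noise_sd=0.0, seed=2,
        )
        cohort = sg.simulate_volumes(params)
        s = cohort.group("mut")[0]
        voxvol = np.prod(cohort.voxel_size_um)
        got = np.exp(s.ljd.values[cohort.brain_mask]).sum() * voxvol
        want = 0.939 * cohort.brain_mask.sum() * voxvol
        assert got == pytest.approx(want, rel=1e-9)

    def test_segmentation_input_counts_voxels(self):
        seg = np.zeros((4, 4, 4), bool)
        seg[:2] = True
        mask = np.ones((4, 4, 4), bool)
        res = mp.mask_volume(seg, mask, mask, voxel_size_um=(2.0, 2.0, 2.0))
        assert res.absolute_volume_um3 == 32 * 8.0
        assert res.percent_of_brain == pytest.approx(100.0)

    def test_empty_mask_rejected(self):
        lj = LJDMap(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            mp.mask_volume(lj, np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestVoxelwiseGroupStat:
    def test_null_fraction_near_alpha(self):
        rng = np.random.default_rng(13)
        maps = [ChannelMap(rng.standard_normal((16, 16, 8)), "ljd")
                for _ in range(20)]
        t, p = mp.voxelwise_group_stat(maps, ["a"] * 10 + ["b"] * 10)
        assert abs(np.nanmean(p < 0.05) - 0.05) < 0.015
        assert abs(np.nanmean(t)) < 0.05

    def test_planted_shift_dominates_stat_map(self):
        rng = np.random.default_rng(14)
        region = np.zeros((12, 12, 6), bool)
        region[4:8, 4:8, 2:4] = True
        maps = []
        for i in range(16):
            v = rng.standard_normal((12, 12, 6))
            if i < 8:
                v[region] += 3.0  # 3 pooled SD
            maps.append(ChannelMap(v, "ljd"))
        t, _ = mp.voxelwise_group_stat(maps, ["a"] * 8 + ["b"] * 8)
        top = np.argsort(np.abs(t).ravel())[-region.sum():]
        frac_in_region = region.ravel()[top].mean()
        assert frac_in_region > 0.8

    def test_single_subject_per_group_rejected(self):
        maps = [ChannelMap(np.zeros((3, 3, 3)), "ljd") for _ in range(2)]
        with pytest.raises(ValueError):
            mp.voxelwise_group_stat(maps, ["a", "b"])


class TestPermutationCluster:
    def test_planted_contraction_cluster_recovered(self):
        params = sg.VolumeSimParams(
            n_subjects_per_group=8, planted_contraction={"mut": {"MHB": 0.80}},
            noise_sd=0.05, seed=5,
        )
        cohort = sg.simulate_volumes(params)
        res = mp.permutation_cluster(
            [s.ljd for s in cohort.subjects],
            [s.group for s in cohort.subjects],
            n_perm=300, seed=1,
        )
        mhb = cohort.region_masks["MHB"]
        sig = res.cluster_labels > 0
        assert (sig & mhb).sum() / mhb.sum() >= 0.8
        assert res.cluster_table["significant"].any()

    def test_exhaustive_mode_for_small_cohorts(self):
        params = sg.VolumeSimParams(
            grid_shape=(10, 10, 6), n_subjects_per_group=3, noise_sd=0.05, seed=6
        )
        cohort = sg.simulate_volumes(params)
        with pytest.warns(UserWarning, match="exhaustively"):
            res = mp.permutation_cluster(
                [s.ljd for s in cohort.subjects],
                [s.group for s in cohort.subjects],
                n_perm=500, seed=1,
            )
        assert res.exhaustive
        assert res.n_permutations == 20  # C(6, 3)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(15)
        maps = [ChannelMap(rng.standard_normal((8, 8, 4)), "ljd") for _ in range(12)]
        groups = ["a"] * 6 + ["b"] * 6
        r1 = mp.permutation_cluster(maps, groups, n_perm=120, seed=7)
        r2 = mp.permutation_cluster(maps, groups, n_perm=120, seed=7)
        assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)
        pd.testing.assert_frame_equal(r1.cluster_table, r2.cluster_table)

    def test_too_few_subjects_rejected(self):
        maps = [ChannelMap(np.zeros((4, 4, 4)), "ljd") for _ in range(4)]
        with pytest.raises(ValueError):
            mp.permutation_cluster(maps, ["a", "a", "b", "b"], n_perm=100)


class TestSymmetrize:
    def test_max_rule_on_mirror_pair(self):
        p = np.full((4, 3, 3), 0.5)
        p[0, 1, 1] = 0.01
        p[3, 1, 1] = 0.04
        out = mp.symmetrize(p, axis=0)
        assert out[0, 1, 1] == out[3, 1, 1] == 0.04

    def test_idempotent(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(0, 1, (7, 5, 5))
        once = mp.symmetrize(p, axis=0)
        twice = mp.symmetrize(once, axis=0)
        assert np.array_equal(once, twice)

    def test_never_decreases_p(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0, 1, (8, 4, 4))
        assert (mp.symmetrize(p, axis=0) >= p).all()

    def test_symmetric_map_unchanged(self):
        p = np.random.default_rng(18).uniform(0, 1, (3, 6, 6))
        p_sym = np.maximum(p, p[::-1])
        assert np.array_equal(mp.symmetrize(p_sym, axis=0), p_sym)

    def test_inconsistent_plane_rejected(self):
        with pytest.raises(ValueError, match="mirror plane"):
            mp.symmetrize(np.zeros((6, 3, 3)), axis=0, center=1.0)


class TestVoxelwiseAnova:
    @staticmethod
    def _two_cohorts(rng, effect=0.0, offset=0.0, n=6, grid=(8, 8, 4)):
        maps, groups, cohorts = [], [], []
        region = np.zeros(grid, bool)
        region[2:6, 2:6, 1:3] = True
        for c, coh in enumerate(("c1", "c2")):
            for g in ("wt", "mut"):
                for _ in range(n):
                    v = rng.standard_normal(grid) + c * offset
                    if g == "mut":
                        v[region] += effect
                    maps.append(ChannelMap(v, "gad1b"))
                    groups.append(g)
                    cohorts.append(coh)
        return maps, groups, cohorts, region

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(19)
        maps, groups, cohorts, _ = self._two_cohorts(rng)
        _, p = mp.voxelwise_anova(maps, groups, cohorts)
        assert abs(np.nanmean(p < 0.05) - 0.05) < 0.02

    def test_cohort_offset_absorbed_effect_detected(self):
        rng = np.random.default_rng(20)
        maps, groups, cohorts, region = self._two_cohorts(
            rng, effect=2.0, offset=10.0
        )
        F, p = mp.voxelwise_anova(maps, groups, cohorts)
        assert np.nanmedian(p[region]) < 0.001
        assert np.nanmean(p[~region] < 0.05) < 0.15  # offset did not leak

    def test_single_cohort_rejected_with_hint(self):
        maps = [ChannelMap(np.zeros((3, 3, 3)), "ljd") for _ in range(4)]
        with pytest.raises(ValueError, match="voxelwise_group_stat"):
            mp.voxelwise_anova(maps, ["a", "a", "b", "b"], ["c1"] * 4)

    def test_empty_cell_rejected(self):
        maps = [ChannelMap(np.zeros((3, 3, 3)), "ljd") for _ in range(6)]
        with pytest.raises(ValueError, match="empty design cell"):
            mp.voxelwise_anova(
                maps, ["a", "a", "b", "a", "a", "a"],
                ["c1", "c1", "c1", "c2", "c2", "c2"],
            )


class TestRegionIntensity:
    def test_equal_groups_zero_difference(self):
        maps = [ChannelMap(np.full((4, 4, 4), 50.0), "gad1b") for _ in range(6)]
        out = mp.region_intensity_summary(
            maps, np.ones((4, 4, 4), bool), ["wt"] * 3 + ["mut"] * 3,
            reference_group="wt",
        )
        assert out.percent_difference == pytest.approx(0.0)

    def test_planted_five_percent_dimming(self, noiseless_volume_cohort):
        cohort = noiseless_volume_cohort
        out = mp.region_intensity_summary(
            [s.channels["gad1b"] for s in cohort.subjects],
            cohort.region_masks["subpallium"],
            [s.group for s in cohort.subjects],
            reference_group="wt",
        )
        assert out.percent_difference == pytest.approx(5.0, abs=1e-9)

    def test_ci_covers_truth_under_noise(self):
        covered = 0
        n_rep = 30
        for r in range(n_rep):
            params = sg.VolumeSimParams(
                grid_shape=(16, 16, 8), n_subjects_per_group=15,
                planted_intensity_scale={"mut": {("gad1b", "subpallium"): 0.95}},
                noise_sd=3.0, seed=3000 + r,
            )
            cohort = sg.simulate_volumes(params)
            out = mp.region_intensity_summary(
                [s.channels["gad1b"] for s in cohort.subjects],
                cohort.region_masks["subpallium"],
                [s.group for s in cohort.subjects],
                reference_group="wt",
            )
            lo, hi = out.ci95
            covered += lo <= 5.0 <= hi
        assert covered / n_rep >= 0.9


class TestNiftiRoundtrip:
    def test_values_and_voxel_size_preserved(self, tmp_path):
        rng = np.random.default_rng(22)
        vals = rng.normal(0, 1, (6, 5, 4)).astype(np.float32)
        path = tmp_path / "m.nii.gz"
        mp.save_volume_nifti(vals, path, (1.0, 1.0, 2.0))
        back, zooms = mp.load_volume_nifti(path)
        assert np.allclose(back, vals, atol=1e-6)
        assert zooms == (1.0, 1.0, 2.0)
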